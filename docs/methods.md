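# Methods

This note documents the models, estimators and numerical choices behind
`alchemycle`, and what the synthetic validation does and does not establish.

## Thermodynamic conventions

Energies are in kcal/mol, lengths in Å, times in ns. kT uses
k_B = 0.0019872041 kcal/mol/K. Two default temperatures are exposed:
298.15 K (`EXPERIMENTAL`) for converting measured dissociation constants,
and 300 K (`SIMULATION`) for simulated ensembles; the printed experimental
binding free energies of picomolar channel blockers reproduce at 298.15 K,
which is why that is the conversion default. The standard concentration
C0 = 1 M equals 6.02214076×10⁻⁴ molecules/Å³.

## Alchemical estimators

A stage interpolates a hybrid Hamiltonian H(λ) = (1−λ)H0 + λH1.

**FEP.** Each window [λ_i, λ_{i+1}] contributes
ΔG_i = −kT·ln⟨exp(−ΔU_i/kT)⟩ evaluated with a log-sum-exp shift (mandatory:
window gaps of a few kT overflow naive exponentials). The stage value is the
window sum. The per-window standard error is the block error of the shifted
Boltzmann weights divided by their mean (delta method); window errors
combine in quadrature. A *backward* stage samples the reverse transformation
and estimates −ΔG; `hysteresis = forward + backward` is the convergence
diagnostic, flagged in reports above 1 kcal/mol, and the symmetrised
estimate is (forward − backward)/2.

**TI.** ΔG = Σ_j w_j ⟨∂H/∂λ⟩_j on seven-point Gauss–Legendre nodes mapped to
[0,1] (exact for polynomial mean-force curves through degree 13). Per-node
block errors propagate through the weights. Other node sets are accepted but
flagged, since the quadrature guarantee is what justifies so few windows.

**Window schedules.** `build_schedule` provides uniform edges, the
Gauss–Legendre nodes, and exponentially spaced edges
λ_k = (e^{αk/n}−1)/(e^{α}−1) with α fitted by minimising the maximum
per-window |ΔG| on a probe model (default: the linear-response quadratic
charging free energy G(λ) = −a·λ², a = 131 kT, the magnitude of a full
side-chain charging leg). The per-window target defaults to 2 kT, the usual
convergence rule of thumb for exponential averaging. With that probe,
uniform spacing needs 131 windows; the fitted geometric family meets the
bound with 81 (a ≈40% saving). The ideal equal-ΔG ladder λ_k = √(k/n) would
need 66, but it is not a member of the geometric family — for a quadratic
probe the geometric form's best possible saving is ≈38%, so the scheduler
reports the achievable window count rather than the equal-ΔG optimum. When a
target is unsatisfiable at the requested window count the error carries the
required count.

**Block errors.** Standard errors of correlated series use block averaging
on a block-count grid {4, 8, 16, 32, 64}, scanned from coarse to fine; the
plateau is the first adjacent pair differing by <10% (the coarser member is
returned), and without a plateau the maximum over the grid is returned,
which is conservative for strongly correlated data. Constant series return
zero; fewer than 8 samples is an error. Calibration on iid Gaussians
reproduces σ/√n within a few percent on average (the 4-block estimate is
χ²-noisy per series), and AR(1) series with φ = 0.9 inflate the error by
the expected ≈√(19) ≈ 4.4 over the naive iid formula.

## Umbrella sampling and WHAM

Windows carry harmonic restraints u_k(z) = k/2·(z−c_k)², one force constant
for all windows (default 30 kcal/mol/Å², a good stiffness for toxin-sized
ligands at 0.5 Å spacing). The coupled WHAM equations for the unbiased
density and per-window shifts f_k are iterated in log space until
max|Δf_k| < 10⁻⁷ kcal/mol (gauge-fixed to f_1 = 0), up to 10⁵ iterations;
non-convergence raises with the residual attached. The grid is uniform
(default 0.1 Å) spanning the samples padded by one bin; W = −kT·ln ρ is
reported only on bins with at least one count, and empty bins interior to
the sampled range are masked with a warning. The profile is anchored by
subtracting its mean over the outermost 2 Å of the sampled range (the bulk
side), where a correct PMF is flat.

**Overlap rule.** Adjacent windows must share at least 5% of their sampling,
measured as the histogram intersection of their normalised position
histograms on a shared grid — a simple symmetric operationalisation of
"overlap" matching the visual criterion. Deficient pairs get a proposed
extra window at the midpoint of the two centers; `wham_solve` warns (or the
CLI fails) until the ladder passes.

**Convergence.** `pmf_block_convergence` re-solves WHAM on successive time
blocks of every window and reports the maximum pairwise well-depth
deviation; stationary sampling must show block profiles agreeing within
noise.

## Binding free energies

K_b = C0·πR²·∫_{z1}^{z2} exp(−W/kT) dz integrated trapezoidally on the PMF
grid (dense enough that higher-order rules gain nothing), and
G_b = −kT·ln K_b. R is the transverse RMS radius of the ligand's
center-of-mass fluctuations in the bound state, R = √(⟨δx²⟩+⟨δy²⟩) over
restraint-free samples — the published widths (≈0.7 Å for a bound toxin)
are reproduced by that operational definition. z1 defaults to 2 Å below the
PMF minimum (clipped to the grid) and z2 to the start of the bulk anchor
span; if W at z2 deviates from zero by more than 0.5 kcal/mol the anchor is
rejected rather than silently integrated. ΔW_well is the profile minimum
(bulk = 0). IC50 values are treated as dissociation constants (complete
block at a single saturable site) — the only reading under which the printed
experimental free energies follow from the printed affinities — giving
G_b = kT·ln(IC50/C0).

## Cycle accounting and reports

`combine_cycle` requires exactly the three legs (coulomb_discharge,
lj_transform, coulomb_charge) for one channel; ΔΔG_b is their sum and the
uncertainty the quadrature sum, the combination rule that also reproduces
the published per-method selectivity errors from their stage errors (up to
±0.1 rounding of unrounded intermediates). Selectivity is the plain
difference with quadrature error; PMF-derived and experimental ΔΔG_b enter
through the same interface. Display rounding is half-away-from-zero to one
decimal; the machine report (`report.tsv`) keeps full precision and re-reads
losslessly. Configs are flat `key = value` text with `[section]` headers —
bit-exact and diffable.

## The synthetic layer

**Harmonic alchemy.** H(λ,x) = (1−λ)k0/2(x−mu0)² + λ[k1/2(x−mu1)² + c],
with closed-form free energy at every λ (ΔG = (kT/2)ln(k1/k0) + c for equal
centers). The offset c models the mean interaction energy a charging leg
gains or loses; without it a ~2 kcal/mol leg would need a spring ratio of
e⁷, whose ∂H/∂λ is too peaked for a 7-point quadrature — real charging legs
are offset-dominated and smooth, and the toy mirrors that. Samples are drawn
from the exact λ-ensemble (Gaussian) as an AR(1) chain with
φ = exp(−Δt/τ) so block-error behaviour under autocorrelation is testable;
ΔU gaps are evaluated as (λ′−λ)·∂H/∂λ, exact for the linear coupling.

**Soft-core LJ.** U(r,λ) = λ·4ε[(σ²/(r²+δ(1−λ)))⁶ − (σ²/(r²+δ(1−λ)))³],
separation-shifted with δ = 7.0 Å² by default (configurable). It is zero at
λ = 0, plain LJ at λ = 1, and finite at r = 0 for λ < 1. Note that for
δ > σ² the λ = 0 end starts on the attractive branch at every r, so the
coupling curve at fixed r < σ first dips (bounded below by −ε) before
rising into the repulsive wall — it is not globally monotone in λ.

**Langevin sampler.** Overdamped dynamics, dz = −(D/kT)∇U·dt + √(2D·dt)·ξ̄,
using the Leimkuhler–Matthews step (ξ̄ averages two consecutive unit
normals). Plain Euler–Maruyama was rejected because its O(θΔt)
stationary-variance bias (~1% at usable timesteps) would consume most of the
2% calibration budget the sampler is held to; LM cancels the leading
configurational bias for one extra normal draw. Defaults D = 50 Å²/ns and
Δt = 10⁻⁴ ns resolve a 30 kcal/mol/Å² restraint (relaxation time
kT/(Dk) ≈ 4×10⁻⁴ ns). Only equilibrium sampling matters here, not transport,
so D is a convergence knob, not a physical diffusivity.

**Steered window generation.** Windows are laid from the well center to
bulk_onset + margin at the configured spacing (default 0.5 Å). Between
windows the restraint center moves at the pull speed (default 5 Å/ns); after
each pulling step the system relaxes for 0.4 ns under the fixed restraint
(discarded) before production.

**Two-channel benchmark.** Two toy "channels" bind a ligand in a Gaussian
well (depth −6 kcal/mol, width 1.5 Å); the mutation removes a charge
coupling worth 2.0 kcal/mol of well depth on channel A and 0.3 kcal/mol on
channel B — the magnitude of selectivity gain a single salt bridge is worth.
For each channel, three harmonic stages are constructed whose *exact* ΔG sum
equals the *exact* PMF-route ΔΔG_b (dense quadrature of the generating
wells, dominant Coulomb leg +0.25, LJ leg −0.2, recharging leg −0.05
relative corrections). FEP cycles, TI cycles and PMF differences are then
three independent estimators of the same number and must agree within
sampling noise; PMF-route errors come from the scatter of 4 time-block
profiles.

## Problem sizes

The default validation sizes are 10⁴ samples per alchemical window (12
uniform windows per stage, 7 TI nodes), 2 ns of production per umbrella
window (20 000 positions at Δt = 10⁻⁴ ns) on ladders of ~17–22 windows, and
4 time blocks for PMF uncertainties. At these sizes the harmonic-toy
estimates carry ~0.003 kcal/mol errors and the PMF-route selectivity
~0.3–0.5 kcal/mol, comfortably resolving the ~1.6 kcal/mol toy selectivity.

## What the validation shows — and does not

Passing tests establish that the estimators are unbiased and correctly
calibrated on systems whose statistics they were designed for: Gaussian
window ensembles with exponential autocorrelation, smooth 1-D landscapes,
harmonic restraints. They do not establish robustness to the pathologies of
real MD data — slow conformational degrees of freedom orthogonal to λ or z,
non-stationary drift, force-field artefacts, or anisotropic binding-pocket
geometry beyond the πR² disc approximation. The toy reaction coordinate is
a genuine 1-D coordinate; real center-of-mass separations hide orthogonal
relaxation that shows up as hysteresis and delayed PMF convergence, which is
why the hysteresis flag and block-convergence reports exist.

## Known limitations

* No BAR/MBAR estimators; plain FEP/TI only (BAR-family estimators would be
  a natural extension).
* 1-D WHAM only; no multidimensional reaction coordinates or reweighting.
* The square-well potential is an analytic fixture; its force field is not
  usable for dynamics (zero force almost everywhere).
* IC50 → G_b assumes full block at a single site; partial block or multiple
  binding modes would need a Hill-equation treatment upstream.
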