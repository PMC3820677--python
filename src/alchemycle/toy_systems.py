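"""Synthetic systems with analytic free energies for validating estimators.

Real alchemical and umbrella-sampling data come from MD of a solvated
channel–toxin complex; none of that is tractable at desk scale. This module
emulates the *statistical structure* of those outputs — per-window ΔU and
∂H/∂λ streams with tunable autocorrelation, and biased position time-series
from harmonic restraints on a known 1-D landscape — from toy Hamiltonians
whose free energies are known in closed form, so every downstream estimator
can be checked against an exact answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, SampleSizeError, ScheduleError
from .estimators import EnergySeries, LambdaSchedule
from .thermo import ThermoContext
from .wham import UmbrellaWindow

__all__ = [
    "HarmonicAlchemySpec",
    "SoftCoreLJSpec",
    "BindingPotential1D",
    "PullProtocol",
    "LangevinParams",
    "sample_fep_windows",
    "sample_ti_nodes",
    "softcore_potential",
    "run_umbrella_protocol",
    "langevin_trajectory",
    "sample_transverse_fluctuations",
    "write_fep_window",
    "write_ti_node",
    "write_umbrella_window",
    "write_fixture_files",
    "ChannelToy",
    "two_channel_benchmark",
]


# ---------------------------------------------------------------------------
# toy Hamiltonians
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicAlchemySpec:
    """Linear alchemy between two 1-D harmonic wells.

    H(λ, x) = (1−λ)·k0/2·(x−mu0)² + λ·[k1/2·(x−mu1)² + offset]. The
    configurational free energy is known in closed form at every λ, so
    FEP/TI estimates can be compared to an exact ΔG; with equal well centers
    it reduces to (kT/2)·ln(k1/k0) + offset. Stands in for the charging legs
    of a real mutation: the spring change models the fluctuation response
    and ``offset`` the mean interaction energy gained or lost.
    """

    k0: float
    k1: float
    mu0: float = 0.0
    mu1: float = 0.0
    offset: float = 0.0
    coupling: str = "linear"
    seed: int = 0

    def __post_init__(self):
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("spring constants must be positive")
        if self.coupling != "linear":
            raise ValueError(f"unsupported coupling {self.coupling!r}")

    def k_eff(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def mean(self, lam: float) -> float:
        """Equilibrium mean of x in the λ ensemble."""
        b = (1.0 - lam) * self.k0 * self.mu0 + lam * self.k1 * self.mu1
        return b / self.k_eff(lam)

    def dhdl(self, x: np.ndarray) -> np.ndarray:
        """∂H/∂λ = k1/2·(x−mu1)² − k0/2·(x−mu0)² + offset, independent of λ."""
        x = np.asarray(x, dtype=float)
        return (0.5 * self.k1 * (x - self.mu1) ** 2
                - 0.5 * self.k0 * (x - self.mu0) ** 2 + self.offset)

    def free_energy(self, lam: float, ctx: ThermoContext) -> float:
        """Exact configurational free energy −kT·ln Z(λ), kcal/mol."""
        kT = ctx.kT
        keff = self.k_eff(lam)
        b = (1.0 - lam) * self.k0 * self.mu0 + lam * self.k1 * self.mu1
        c = 0.5 * ((1.0 - lam) * self.k0 * self.mu0 ** 2 + lam * self.k1 * self.mu1 ** 2)
        u_min = c - 0.5 * b * b / keff + lam * self.offset
        return u_min - 0.5 * kT * math.log(2.0 * math.pi * kT / keff)

    def analytic_delta_G(self, ctx: ThermoContext) -> float:
        """Exact ΔG = G(1) − G(0); (kT/2)·ln(k1/k0) when mu0 = mu1."""
        return self.free_energy(1.0, ctx) - self.free_energy(0.0, ctx)

    def probe_kT(self, ctx: ThermoContext) -> Callable[[np.ndarray], np.ndarray]:
        """G(λ)/kT on an array of λ, for fitting window schedules."""

        def probe(lam: np.ndarray) -> np.ndarray:
            lam = np.asarray(lam, dtype=float)
            return np.array([self.free_energy(l, ctx) for l in np.atleast_1d(lam)]) / ctx.kT

        return probe


@dataclass(frozen=True)
class SoftCoreLJSpec:
    """Separation-shifted soft-core Lennard-Jones transformation.

    U(r, λ) = λ^p · 4ε[(σ²/(r²+δ(1−λ)))⁶ − (σ²/(r²+δ(1−λ)))³] with the shift
    coefficient δ in Å². The shift removes the r→0 singularity at every
    λ < 1, so the decoupled end point can be sampled without instabilities;
    at λ = 1 the plain LJ potential is recovered exactly.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    shift_coeff: float = 7.0
    lambda_power: int = 1

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.shift_coeff <= 0:
            raise ValueError("shift coefficient must be positive")
        if self.lambda_power < 1:
            raise ValueError("lambda_power must be a positive integer")


def softcore_potential(r, lam: float, spec: SoftCoreLJSpec):
    """Soft-core LJ energy at separation ``r`` and coupling ``lam``, kcal/mol.

    Finite at r = 0 for all λ < 1, identically zero at λ = 0, and equal to
    plain LJ at λ = 1. Scalar in, scalar out; arrays broadcast.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"λ must lie in [0,1], got {lam}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    if lam == 0.0:
        out = np.zeros_like(r)
        return float(out) if out.ndim == 0 else out
    denom = r ** 2 + spec.shift_coeff * (1.0 - lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        s3 = (spec.sigma ** 2 / denom) ** 3
        out = lam ** spec.lambda_power * 4.0 * spec.epsilon * (s3 * s3 - s3)
    # at λ=1, r=0 the plain LJ core diverges: the repulsive r^-12 term wins
    out = np.where(np.isinf(s3), np.inf, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# 1-D binding landscapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingPotential1D:
    """A model PMF W(z) along the channel axis.

    ``form`` is ``gaussian_well`` (smooth, usable in dynamics),
    ``square_well`` (analytic fixture only: its force is zero almost
    everywhere so it is rejected by the sampler), or ``tabulated``
    (interpolated from a grid). W → 0 beyond ``bulk_onset``; ``depth`` is
    negative for a binding well.
    """

    form: str
    depth: float = 0.0
    center: float = 0.0
    width: float = 1.0
    z_grid: np.ndarray | None = None
    values: np.ndarray | None = None
    bulk_onset: float | None = None

    def __post_init__(self):
        if self.form not in ("square_well", "gaussian_well", "tabulated", "flat"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form in ("square_well", "gaussian_well"):
            if self.depth >= 0:
                raise ValueError("a binding well needs depth < 0")
            if self.width <= 0:
                raise ValueError("width must be positive")
        if self.form == "tabulated":
            if self.z_grid is None or self.values is None:
                raise ValueError("tabulated potential needs z_grid and values")
            object.__setattr__(self, "z_grid", np.asarray(self.z_grid, dtype=float))
            object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
            object.__setattr__(self, "_grad", np.gradient(self.values, self.z_grid))
        if self.bulk_onset is None:
            object.__setattr__(self, "bulk_onset", self._default_bulk_onset())
        w_bulk = float(np.max(np.abs(self.energy(
            np.linspace(self.bulk_onset + 1e-9, self.bulk_onset + 5.0, 11)))))
        if w_bulk > 0.05:
            raise ValueError(
                f"W does not vanish beyond bulk_onset={self.bulk_onset}: |W| up to {w_bulk:.3g}")

    def _default_bulk_onset(self) -> float:
        if self.form == "gaussian_well":
            return self.center + 4.5 * self.width
        if self.form == "square_well":
            return self.center + 0.5 * self.width
        if self.form == "tabulated":
            return float(self.z_grid[-1])
        return self.center

    def energy(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "gaussian_well":
            return self.depth * np.exp(-0.5 * ((z - self.center) / self.width) ** 2)
        if self.form == "square_well":
            return np.where(np.abs(z - self.center) <= 0.5 * self.width, self.depth, 0.0)
        return np.interp(z, self.z_grid, self.values)

    def force(self, z) -> np.ndarray:
        """−dW/dz. Analytic for the gaussian well, interpolated for tables."""
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "gaussian_well":
            return self.energy(z) * (z - self.center) / self.width ** 2
        if self.form == "tabulated":
            return -np.interp(z, self.z_grid, self._grad)
        raise ValueError(f"{self.form} potential has no usable force field")

    @property
    def well_position(self) -> float:
        if self.form == "tabulated":
            return float(self.z_grid[np.argmin(self.values)])
        return self.center

    def boltzmann_integral(self, z1: float, z2: float, ctx: ThermoContext,
                           n: int = 20_001) -> float:
        """∫ exp(−W/kT) dz on [z1, z2] by dense trapezoid (oracle use)."""
        z = np.linspace(z1, z2, n)
        return float(np.trapezoid(np.exp(-self.energy(z) / ctx.kT), z))


@dataclass(frozen=True)
class PullProtocol:
    """Steered window generation: moving harmonic restraint, then relaxation."""

    k: float = 30.0              # restraint, kcal/mol/Å²
    speed: float = 5.0           # pull speed, Å/ns
    window_spacing: float = 0.5  # Å
    relax_time: float = 0.4      # ns discarded after each pulling step

    def __post_init__(self):
        if self.k <= 0 or self.speed <= 0 or self.window_spacing <= 0:
            raise ValueError("k, speed and window_spacing must be positive")
        if self.relax_time < 0:
            raise ValueError("relax_time must be non-negative")


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped (inertia-free) integrator settings.

    Only equilibrium sampling matters for free-energy estimation, so inertia
    is dropped: dz = −(D/kT)·∇U·dt + √(2D·dt)·ξ̄, where ξ̄ averages two
    consecutive unit normals (the Leimkuhler–Matthews step), which cancels
    the leading-order timestep bias in configurational averages. The
    timestep must still resolve the stiffest restraint (relaxation time
    kT/(D·k)).
    """

    diffusion: float = 50.0      # Å²/ns
    timestep: float = 1e-4       # ns
    n_steps: int = 10_000        # production steps per window
    seed: int = 0

    def __post_init__(self):
        if self.diffusion <= 0 or self.timestep <= 0:
            raise ValueError("diffusion and timestep must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")


# ---------------------------------------------------------------------------
# alchemical sample streams
# ---------------------------------------------------------------------------

def _ar1_positions(spec: HarmonicAlchemySpec, lam: float, ctx: ThermoContext,
                   n_samples: int, autocorr_time: float,
                   sample_interval_ps: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) draw from the λ-ensemble of the harmonic toy.

    The harmonic equilibrium density is Gaussian, so an AR(1) chain with the
    matching mean/variance and φ = exp(−Δt/τ) reproduces both the ensemble
    and an exponential autocorrelation of time ``autocorr_time`` (ns).
    """
    mu = spec.mean(lam)
    sigma = math.sqrt(ctx.kT / spec.k_eff(lam))
    eps = rng.standard_normal(n_samples)
    if autocorr_time <= 0.0:
        return mu + sigma * eps
    phi = math.exp(-(sample_interval_ps * 1e-3) / autocorr_time)
    x = np.empty(n_samples)
    x[0] = mu + sigma * eps[0]
    scale = sigma * math.sqrt(1.0 - phi * phi)
    for i in range(1, n_samples):
        x[i] = mu + phi * (x[i - 1] - mu) + scale * eps[i]
    return x


def _check_fep_schedule(schedule: LambdaSchedule) -> np.ndarray:
    values = schedule.values
    if schedule.kind == "gauss_legendre_7":
        raise ScheduleError("FEP sampling needs window edges, not quadrature nodes")
    if np.any(np.diff(values) <= 0):
        raise ScheduleError("λ schedule must be strictly increasing")
    return values


def sample_fep_windows(spec: HarmonicAlchemySpec, schedule: LambdaSchedule,
                       ctx: ThermoContext, n_samples: int,
                       autocorr_time: float = 0.0,
                       direction: str = "forward",
                       stage: str = "stage",
                       sample_interval_ps: float = 1.0,
                       equilibration_ps: float = 0.0,
                       seed: int | None = None) -> list[EnergySeries]:
    """Per-subinterval ΔU streams from the toy's λ ensembles.

    For each window [λ_i, λ_{i+1}] the forward stream samples configurations
    at λ_i and records ΔU = H(λ_{i+1}) − H(λ_i) = (λ_{i+1}−λ_i)·∂H/∂λ (the
    coupling is linear in λ, so the gap is evaluated exactly); the backward
    stream samples at λ_{i+1} and records the negated gap. Reproducible under
    a fixed seed.
    """
    if n_samples < 10:
        raise SampleSizeError("n_samples must be at least 10")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    values = _check_fep_schedule(schedule)
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    out = []
    for i, (children, (lo, hi)) in enumerate(
            zip(root.spawn(len(values) - 1), zip(values, values[1:]))):
        rng = np.random.default_rng(children)
        lam_s, lam_t = (lo, hi) if direction == "forward" else (hi, lo)
        x = _ar1_positions(spec, lam_s, ctx, n_samples, autocorr_time,
                           sample_interval_ps, rng)
        du = (lam_t - lam_s) * spec.dhdl(x)
        out.append(EnergySeries(
            samples=du, lam=float(lam_s), lam_target=float(lam_t),
            kind="delta_u", stage=stage, direction=direction, window=i,
            sample_interval_ps=sample_interval_ps,
            equilibration_ps=equilibration_ps))
    return out


def sample_ti_nodes(spec: HarmonicAlchemySpec, nodes: LambdaSchedule,
                    ctx: ThermoContext, n_samples: int,
                    autocorr_time: float = 0.0,
                    direction: str = "forward",
                    stage: str = "stage",
                    sample_interval_ps: float = 1.0,
                    seed: int | None = None) -> list[EnergySeries]:
    """∂H/∂λ streams at quadrature nodes of the toy's λ ensembles.

    Backward streams sample the reverse transformation H(1−λ) and therefore
    integrate to −ΔG.
    """
    if n_samples < 10:
        raise SampleSizeError("n_samples must be at least 10")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    values = nodes.values
    weights = (nodes.weights if nodes.weights.size
               else np.full(values.shape, np.nan))
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    out = []
    for i, (children, lam, w) in enumerate(zip(root.spawn(len(values)), values, weights)):
        rng = np.random.default_rng(children)
        lam_sample = float(lam) if direction == "forward" else float(1.0 - lam)
        x = _ar1_positions(spec, lam_sample, ctx, n_samples, autocorr_time,
                           sample_interval_ps, rng)
        dhdl = spec.dhdl(x) if direction == "forward" else -spec.dhdl(x)
        out.append(EnergySeries(
            samples=dhdl, lam=float(lam), weight=None if math.isnan(w) else float(w),
            kind="dhdl", stage=stage, direction=direction, window=i,
            sample_interval_ps=sample_interval_ps))
    return out


# ---------------------------------------------------------------------------
# Langevin dynamics and the umbrella protocol
# ---------------------------------------------------------------------------

def langevin_trajectory(potential: BindingPotential1D, lang: LangevinParams,
                        ctx: ThermoContext, z0: float, n_steps: int,
                        rng: np.random.Generator,
                        bias_k: float = 0.0,
                        bias_center: float | np.ndarray = 0.0) -> np.ndarray:
    """Overdamped Langevin trajectory on W(z) plus an optional bias.

    Uses the Leimkuhler–Matthews discretisation (Euler drift with averaged
    consecutive noises). ``bias_center`` may be an array of length
    ``n_steps`` for a moving (steered) restraint. Returns the positions
    after each step.
    """
    kT = ctx.kT
    dt = lang.timestep
    mob = lang.diffusion / kT * dt
    xi = rng.standard_normal(n_steps + 1)
    noise = (math.sqrt(2.0 * lang.diffusion * dt) * 0.5 * (xi[:-1] + xi[1:])).tolist()
    centers = np.broadcast_to(np.asarray(bias_center, dtype=float), (n_steps,)).tolist()

    # scalar fast path: the inner loop is sequential, so avoid ndarray overhead
    if potential.form == "gaussian_well":
        d, c, w2 = potential.depth, potential.center, potential.width ** 2

        def force(z: float) -> float:
            u = z - c
            return d * math.exp(-0.5 * u * u / w2) * u / w2
    elif potential.form == "flat":
        def force(z: float) -> float:
            return 0.0
    else:
        def force(z: float) -> float:
            return float(potential.force(z))

    out = np.empty(n_steps)
    z = z0
    for i in range(n_steps):
        f = force(z)
        if bias_k:
            f -= bias_k * (z - centers[i])
        z = z + mob * f + noise[i]
        out[i] = z
    return out


def run_umbrella_protocol(potential: BindingPotential1D, pull: PullProtocol,
                          lang: LangevinParams, ctx: ThermoContext,
                          margin: float = 1.0,
                          seed: int | None = None) -> list[UmbrellaWindow]:
    """Generate an umbrella-window ladder by steered pulling on the toy PMF.

    Windows are laid at ``pull.window_spacing`` intervals from the well
    center out to ``bulk_onset + margin``. Between windows the restraint
    center moves at the pull speed; after each pulling step the system
    relaxes for ``pull.relax_time`` under the fixed restraint (discarded),
    then ``lang.n_steps`` production positions are recorded. The same force
    constant is used in every window.
    """
    z_start = potential.well_position
    z_end = potential.bulk_onset + margin
    if z_end <= z_start:
        raise ConfigurationError(
            f"window span [{z_start}, {z_end}] does not cover well → bulk")
    n_windows = int(round((z_end - z_start) / pull.window_spacing)) + 1
    centers = z_start + pull.window_spacing * np.arange(n_windows)

    root = np.random.SeedSequence(lang.seed if seed is None else seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(n_windows + 1)]
    relax_steps = max(int(round(pull.relax_time / lang.timestep)), 1)
    pull_steps = max(int(round(pull.window_spacing / pull.speed / lang.timestep)), 1)

    windows = []
    z = float(z_start)
    for i, c in enumerate(centers):
        if i > 0:
            moving = np.linspace(centers[i - 1], c, pull_steps)
            z = float(langevin_trajectory(potential, lang, ctx, z, pull_steps,
                                          rngs[-1], pull.k, moving)[-1])
        relax = langevin_trajectory(potential, lang, ctx, z, relax_steps,
                                    rngs[i], pull.k, c)
        z = float(relax[-1])
        prod = langevin_trajectory(potential, lang, ctx, z, lang.n_steps,
                                   rngs[i], pull.k, c)
        z = float(prod[-1])
        windows.append(UmbrellaWindow(
            center=float(c), force_constant=pull.k, samples=prod,
            discard_ns=pull.relax_time,
            time_ns=pull.relax_time + lang.timestep * np.arange(1, lang.n_steps + 1)))
    return windows


def sample_transverse_fluctuations(sigma_x: float, sigma_y: float, n: int,
                                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian center-of-mass fluctuation series for the two transverse axes."""
    rng = np.random.default_rng(seed)
    return sigma_x * rng.standard_normal(n), sigma_y * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def _write_headed_tsv(path: Path, header: dict, columns: str,
                      rows) -> None:
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}\t{val}\n")
        fh.write(f"# columns\t{columns}\n")
        for row in rows:
            fh.write(row)


def write_fep_window(series: EnergySeries, path: str | Path,
                     ctx: ThermoContext | None = None) -> None:
    """Write one FEP window as fepout-like TSV (``step<TAB>deltaU_kcal_mol``)."""
    if series.samples.size == 0:
        raise SampleSizeError("refusing to write an empty sample set")
    header = {
        "stage": series.stage, "direction": series.direction,
        "window": series.window,
        "lambda0": repr(series.lam), "lambda1": repr(series.lam_target),
        "temperature_K": repr(ctx.temperature) if ctx else repr(300.0),
        "sample_interval_ps": repr(series.sample_interval_ps),
        "equilibration_ps": repr(series.equilibration_ps),
    }
    _write_headed_tsv(Path(path), header, "step\tdeltaU_kcal_mol",
                      (f"{i}\t{float(v)!r}\n" for i, v in enumerate(series.samples)))


def write_ti_node(series: EnergySeries, path: str | Path,
                  ctx: ThermoContext | None = None) -> None:
    """Write one TI node as TSV (``step<TAB>dHdlambda_kcal_mol``)."""
    if series.samples.size == 0:
        raise SampleSizeError("refusing to write an empty sample set")
    if series.weight is None:
        raise ValueError("TI node series needs a quadrature weight")
    header = {
        "stage": series.stage, "direction": series.direction,
        "window": series.window,
        "lambda": repr(series.lam), "weight": repr(series.weight),
        "temperature_K": repr(ctx.temperature) if ctx else repr(300.0),
        "sample_interval_ps": repr(series.sample_interval_ps),
    }
    _write_headed_tsv(Path(path), header, "step\tdHdlambda_kcal_mol",
                      (f"{i}\t{float(v)!r}\n" for i, v in enumerate(series.samples)))


def write_umbrella_window(window: UmbrellaWindow, path: str | Path) -> None:
    """Write one umbrella window as TSV (``time_ns<TAB>z_angstrom``)."""
    if window.samples.size == 0:
        raise SampleSizeError("refusing to write an empty sample set")
    times = (window.time_ns if window.time_ns is not None
             else np.arange(1, window.n + 1, dtype=float))
    header = {
        "center_angstrom": repr(window.center),
        "force_constant_kcal_mol_A2": repr(window.force_constant),
        "discard_ns": repr(window.discard_ns),
    }
    _write_headed_tsv(Path(path), header, "time_ns\tz_angstrom",
                      (f"{float(t)!r}\t{float(z)!r}\n"
                       for t, z in zip(times, window.samples)))


def write_fixture_files(directory: str | Path,
                        fep_windows: Sequence[EnergySeries] = (),
                        ti_nodes: Sequence[EnergySeries] = (),
                        umbrella_windows: Sequence[UmbrellaWindow] = (),
                        ctx: ThermoContext | None = None) -> dict[str, list[Path]]:
    """Emit a full fixture set under ``directory``; returns the paths written.

    Window files carry zero-padded indices so lexical order equals window
    order; everything round-trips bit-exactly through the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {"fep": [], "ti": [], "umbrella": []}
    for s in fep_windows:
        p = directory / f"fep_{s.stage}_{s.direction}_{s.window:03d}.tsv"
        write_fep_window(s, p, ctx)
        written["fep"].append(p)
    for s in ti_nodes:
        p = directory / f"ti_{s.stage}_{s.direction}_{s.window:03d}.tsv"
        write_ti_node(s, p, ctx)
        written["ti"].append(p)
    for i, w in enumerate(umbrella_windows):
        p = directory / f"umbrella_{i:03d}.tsv"
        write_umbrella_window(w, p)
        written["umbrella"].append(p)
    return written


# ---------------------------------------------------------------------------
# the two-channel selectivity benchmark
# ---------------------------------------------------------------------------

#: Stage labels of the charge-neutral mutation cycle, in order.
CYCLE_STAGES = ("coulomb_discharge", "lj_transform", "coulomb_charge")


@dataclass(frozen=True)
class ChannelToy:
    """One toy channel: bound-state wells for wild-type and mutant ligands
    plus three alchemical stages whose exact ΔG's sum to the PMF-route ΔΔG_b.
    """

    name: str
    coupling_kcal: float
    wild: BindingPotential1D
    mutant: BindingPotential1D
    stages: dict[str, HarmonicAlchemySpec]
    R: float
    z1: float
    z2: float
    ddG_analytic: float

    def stage_targets(self, ctx: ThermoContext) -> dict[str, float]:
        return {name: spec.analytic_delta_G(ctx)
                for name, spec in self.stages.items()}


def _stage_spec(dG: float, ctx: ThermoContext, seed: int,
                k_ratio: float = 2.0) -> HarmonicAlchemySpec:
    """A harmonic alchemy leg with exact free energy ``dG`` (kcal/mol).

    The spring ratio stays mild (smooth ∂H/∂λ, well resolved by a 7-point
    quadrature) and the mean-field offset carries the remainder of the
    target, as in a real charging leg where the mean coupling energy
    dominates over the fluctuation response.
    """
    return HarmonicAlchemySpec(
        k0=1.0, k1=k_ratio,
        offset=dG - 0.5 * ctx.kT * math.log(k_ratio), seed=seed)


def two_channel_benchmark(ctx: ThermoContext, seed: int = 0,
                          well_depth: float = -6.0,
                          well_width: float = 1.5,
                          couplings: tuple[float, float] = (2.0, 0.3),
                          R: float = 0.71) -> dict[str, ChannelToy]:
    """Two toy channels differing by one charge-coupling term.

    Channel A couples the mutated side chain strongly (its removal costs
    ``couplings[0]`` kcal/mol of well depth); channel B barely couples it.
    For each channel the mutant well is the wild-type well shallowed by the
    coupling, and the three cycle stages are harmonic alchemy legs whose
    analytic sum equals the exact PMF-route ΔΔG_b = G_b(mutant) − G_b(wild).
    The selectivity free energy estimated by FEP cycles, TI cycles and PMF
    differences must then agree within sampling noise.
    """
    out = {}
    ss = np.random.SeedSequence(seed)
    for name, coupling, child in zip(("channelA", "channelB"), couplings, ss.spawn(2)):
        wild = BindingPotential1D("gaussian_well", depth=well_depth,
                                  center=0.0, width=well_width)
        mutant = BindingPotential1D("gaussian_well", depth=well_depth + coupling,
                                    center=0.0, width=well_width)
        # the umbrella ladder starts at the well center, so the binding
        # integral runs over the sampled half-well out to the bulk onset
        z1 = wild.well_position
        z2 = wild.bulk_onset
        area = math.pi * R ** 2 * ctx.C0
        gb_wild = -ctx.kT * math.log(area * wild.boltzmann_integral(z1, z2, ctx))
        gb_mut = -ctx.kT * math.log(area * mutant.boltzmann_integral(z1, z2, ctx))
        ddg = gb_mut - gb_wild
        # split ΔΔG over the cycle the way a real charge mutation does:
        # dominant Coulomb leg, small LJ leg, near-zero re-charging leg
        legs = {"coulomb_discharge": ddg + 0.25, "lj_transform": -0.2,
                "coulomb_charge": -0.05}
        stage_seeds = child.generate_state(3)
        stages = {k: _stage_spec(v, ctx, int(s) % (2 ** 31))
                  for (k, v), s in zip(legs.items(), stage_seeds)}
        out[name] = ChannelToy(name=name, coupling_kcal=coupling, wild=wild,
                               mutant=mutant, stages=stages, R=R, z1=z1, z2=z2,
                               ddG_analytic=ddg)
    return out
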