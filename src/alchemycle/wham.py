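"""Umbrella-sampling reconstruction of a 1-D potential of mean force.

Windows restrained at staggered centers along the reaction coordinate are
merged into one unbiased density by self-consistent iteration of the WHAM
equations; the PMF is W(z) = −kT·ln ρ(z), anchored to zero in the bulk.
A histogram-intersection overlap criterion between neighbouring windows
guards against under-sampled seams, and extra windows are proposed at the
midpoint of any pair falling below the minimum overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, ParseError, SampleSizeError
from .thermo import ThermoContext

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "OverlapReport",
    "overlap_fraction",
    "check_and_insert",
    "wham_solve",
    "pmf_block_convergence",
    "read_umbrella_window",
    "write_pmf",
    "read_pmf",
]

#: Default histogram bin width on the reaction coordinate, Å.
DEFAULT_BIN_WIDTH = 0.1

#: Default span of the bulk anchor region, Å (outermost part of the sampled range).
DEFAULT_ANCHOR_SPAN = 2.0

#: Minimum neighbour-overlap fraction required between adjacent windows.
MIN_OVERLAP = 0.05

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000

MIN_RETAINED_SAMPLES = 100


@dataclass
class UmbrellaWindow:
    """Biased position samples from one harmonic umbrella window.

    ``center`` and ``force_constant`` define the restraint
    u(z) = k/2·(z − c)²; ``samples`` holds positions collected after the
    relaxation span ``discard_ns`` (already removed).
    """

    center: float
    force_constant: float
    samples: np.ndarray
    discard_ns: float = 0.0
    time_ns: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.samples.size < MIN_RETAINED_SAMPLES:
            raise SampleSizeError(
                f"umbrella window at {self.center} Å has {self.samples.size} retained "
                f"samples; at least {MIN_RETAINED_SAMPLES} required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("umbrella samples must be finite")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    def bias(self, z: np.ndarray) -> np.ndarray:
        """Restraint energy at positions ``z``, kcal/mol."""
        return 0.5 * self.force_constant * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    """W(z) on a uniform grid, anchored so the bulk average is zero.

    Grid points never visited by any window carry NaN. ``iterations`` and
    ``residual`` record the WHAM convergence state.
    """

    z: np.ndarray
    W: np.ndarray
    anchor: str = "bulk_zero"
    iterations: int = 0
    residual: float = 0.0
    shifts: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.z.shape != self.W.shape:
            raise ValueError("z and W grids must have the same shape")

    @property
    def well_depth(self) -> float:
        """Minimum of W over the sampled range (≤ 0 for a binder), kcal/mol."""
        return float(np.nanmin(self.W))

    @property
    def well_position(self) -> float:
        return float(self.z[np.nanargmin(self.W)])


@dataclass
class OverlapReport:
    """Neighbour-overlap diagnostics for an ordered window ladder."""

    pairs: list[dict]
    insertions: list[float]
    threshold: float

    @property
    def ok(self) -> bool:
        return not self.insertions


# ---------------------------------------------------------------------------
# overlap criterion
# ---------------------------------------------------------------------------

def _shared_edges(samples: Sequence[np.ndarray], bins) -> np.ndarray:
    lo = min(float(s.min()) for s in samples)
    hi = max(float(s.max()) for s in samples)
    if isinstance(bins, (int, np.integer)):
        return np.linspace(lo, hi, int(bins) + 1)
    if bins is None:
        n = max(int(math.ceil((hi - lo) / DEFAULT_BIN_WIDTH)), 1)
        return np.linspace(lo, hi, n + 1)
    return np.asarray(bins, dtype=float)


def overlap_fraction(a: UmbrellaWindow, b: UmbrellaWindow, bins=None) -> float:
    """Histogram intersection of two windows' sampling, in [0, 1].

    Both sample sets are histogrammed on a shared grid and normalised to
    unit mass; the overlap is the summed per-bin minimum, 1 for identical
    distributions and 0 for disjoint support.
    """
    edges = _shared_edges([a.samples, b.samples], bins)
    pa, _ = np.histogram(a.samples, bins=edges)
    pb, _ = np.histogram(b.samples, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def check_and_insert(windows: Sequence[UmbrellaWindow],
                     threshold: float = MIN_OVERLAP, bins=None) -> OverlapReport:
    """Flag adjacent window pairs whose sampling overlap falls below threshold.

    Windows are examined in order of center; for every deficient pair the
    midpoint of the two centers is proposed as an extra window.
    """
    ordered = sorted(windows, key=lambda w: w.center)
    if len(ordered) < 2:
        raise ConfigurationError("need at least two windows for an overlap check")
    pairs, insertions = [], []
    for a, b in zip(ordered, ordered[1:]):
        frac = overlap_fraction(a, b, bins=bins)
        ok = frac >= threshold
        pairs.append({"center_a": a.center, "center_b": b.center,
                      "overlap": frac, "ok": ok})
        if not ok:
            insertions.append(0.5 * (a.center + b.center))
    return OverlapReport(pairs=pairs, insertions=insertions, threshold=threshold)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_solve(windows: Sequence[UmbrellaWindow], ctx: ThermoContext,
               grid_spacing: float = DEFAULT_BIN_WIDTH,
               tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
               anchor_span: float = DEFAULT_ANCHOR_SPAN,
               require_overlap: bool = True) -> PMFProfile:
    """Self-consistent WHAM solution for the unbiased PMF.

    Iterates the coupled equations for the unbiased density ρ(z) and the
    per-window free-energy shifts f_k,

        ρ(z) = Σ_k n_k(z) / Σ_k N_k·exp[(f_k − u_k(z))/kT],
        exp(−f_k/kT) = Σ_z ρ(z)·exp(−u_k(z)/kT)·Δz,

    until the largest change in any f_k is below ``tol`` (kcal/mol). The PMF
    is −kT·ln ρ, shifted so its mean over the outermost ``anchor_span`` of
    the sampled range (the bulk side, largest z) is zero.
    """
    windows = list(windows)
    if not windows:
        raise ConfigurationError("no umbrella windows given")
    if require_overlap and len(windows) > 1:
        report = check_and_insert(windows)
        if not report.ok:
            warnings.warn(
                f"adjacent windows below {report.threshold:.0%} overlap; "
                f"proposed insertions at {report.insertions}", stacklevel=2)

    kT = ctx.kT
    lo = min(float(w.samples.min()) for w in windows) - grid_spacing
    hi = max(float(w.samples.max()) for w in windows) + grid_spacing
    n_bins = max(int(math.ceil((hi - lo) / grid_spacing)), 2)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dz = edges[1] - edges[0]

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    total_counts = counts.sum(axis=0).astype(float)          # per bin
    log_N = np.log(np.array([w.n for w in windows], dtype=float))
    u = np.stack([w.bias(centers) for w in windows])          # (K, B)

    sampled = total_counts > 0
    interior_empty = ~sampled[np.argmax(sampled): len(sampled) - np.argmax(sampled[::-1])]
    if interior_empty.any():
        warnings.warn(
            f"{int(interior_empty.sum())} empty bins interior to the sampled range; "
            "those grid points are masked", stacklevel=2)

    with np.errstate(divide="ignore"):
        log_counts = np.where(sampled, np.log(total_counts, where=sampled,
                                              out=np.full_like(total_counts, -np.inf)),
                              -np.inf)

    f = np.zeros(len(windows))
    residual = math.inf
    for iteration in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_k [ log N_k + (f_k − u_k(z))/kT ]
        log_denom = logsumexp(log_N[:, None] + (f[:, None] - u) / kT, axis=0)
        log_rho = log_counts - log_denom
        # unnormalised; f_k update
        f_new = -kT * logsumexp(log_rho[None, :] - u / kT + math.log(dz), axis=1)
        f_new -= f_new[0]                                     # gauge fix
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kcal/mol)", residual=residual,
            iterations=max_iter)

    log_denom = logsumexp(log_N[:, None] + (f[:, None] - u) / kT, axis=0)
    log_rho = log_counts - log_denom
    W = np.where(sampled, -kT * log_rho, np.nan)

    # anchor: zero mean over the outermost anchor_span at the bulk (high-z) end
    z_sampled = centers[sampled]
    anchor_mask = sampled & (centers >= z_sampled.max() - anchor_span)
    W = W - np.nanmean(W[anchor_mask])

    return PMFProfile(z=centers, W=W, anchor="bulk_zero",
                      iterations=iteration, residual=residual, shifts=f)


def pmf_block_convergence(windows: Sequence[UmbrellaWindow], n_blocks: int,
                          ctx: ThermoContext, **wham_kwargs) -> tuple[list[PMFProfile], float]:
    """PMFs from successive time blocks of every window.

    Each window's retained samples are cut into ``n_blocks`` contiguous
    spans; WHAM is solved per span. Returns the block profiles and the
    maximum pairwise deviation of the well depth, the convergence measure
    used when deciding whether sampling suffices.
    """
    if n_blocks < 2:
        raise ConfigurationError("need at least 2 blocks")
    profiles = []
    for b in range(n_blocks):
        block_windows = []
        for w in windows:
            chunk = np.array_split(w.samples, n_blocks)[b]
            block_windows.append(UmbrellaWindow(
                center=w.center, force_constant=w.force_constant,
                samples=chunk, discard_ns=w.discard_ns))
        profiles.append(wham_solve(block_windows, ctx, require_overlap=False,
                                   **wham_kwargs))
    depths = [p.well_depth for p in profiles]
    max_dev = max(abs(a - b) for a in depths for b in depths)
    return profiles, max_dev


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

def read_umbrella_window(path: str | Path) -> UmbrellaWindow:
    """Read one umbrella window file (rows ``time_ns<TAB>z_angstrom``)."""
    path = Path(path)
    header: dict[str, str] = {}
    times, zs = [], []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    header[parts[0]] = parts[1]
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{i}: expected 2 tab-separated columns", line=i)
            try:
                t, z = float(cols[0]), float(cols[1])
            except ValueError:
                raise ParseError(f"{path}:{i}: unparseable row {line!r}", line=i) from None
            if not (math.isfinite(t) and math.isfinite(z)):
                raise ParseError(f"{path}:{i}: non-finite sample", line=i)
            times.append(t)
            zs.append(z)
    if not zs:
        raise ParseError(f"{path}: no data rows")
    try:
        return UmbrellaWindow(
            center=float(header["center_angstrom"]),
            force_constant=float(header["force_constant_kcal_mol_A2"]),
            samples=np.asarray(zs),
            discard_ns=float(header.get("discard_ns", 0.0)),
            time_ns=np.asarray(times),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from None


def write_pmf(pmf: PMFProfile, path: str | Path) -> None:
    """Write a PMF as 2-column text ``z_angstrom<TAB>W_kcal_mol``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns\tz_angstrom\tW_kcal_mol\n")
        fh.write(f"# anchor\t{pmf.anchor}\n")
        fh.write(f"# iterations\t{pmf.iterations}\n")
        fh.write(f"# residual\t{pmf.residual:.12g}\n")
        for z, w in zip(pmf.z, pmf.W):
            fh.write(f"{z:.12g}\t{w:.12g}\n")


def read_pmf(path: str | Path) -> PMFProfile:
    """Read a 2-column PMF file written by :func:`write_pmf`."""
    path = Path(path)
    header: dict[str, str] = {}
    zs, ws = [], []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) >= 2:
                    header[parts[0]] = parts[1]
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{i}: expected 2 columns", line=i)
            zs.append(float(cols[0]))
            ws.append(float(cols[1]))
    if not zs:
        raise ParseError(f"{path}: no data rows")
    return PMFProfile(z=np.asarray(zs), W=np.asarray(ws),
                      anchor=header.get("anchor", "bulk_zero"),
                      iterations=int(header.get("iterations", 0)),
                      residual=float(header.get("residual", 0.0)))
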