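"""Alchemical free-energy estimation for a single transformation stage.

Free energy perturbation (FEP) sums per-window exponential averages of the
energy gap ΔU between adjacent λ states; thermodynamic integration (TI)
integrates the ensemble mean of ∂H/∂λ over λ with Gauss–Legendre quadrature.
Both carry block-averaged standard errors, and forward/backward pairs are
compared for hysteresis as a convergence diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .errors import ParseError, SampleSizeError, ScheduleError
from .thermo import ThermoContext

__all__ = [
    "LambdaSchedule",
    "EnergySeries",
    "FreeEnergyEstimate",
    "build_schedule",
    "quadratic_charging_probe",
    "fep_estimate",
    "ti_estimate",
    "hysteresis",
    "block_error",
    "running_average",
    "read_fep_window",
    "read_ti_node",
    "read_stage_directory",
]

#: Default block-count grid for block-averaged error estimation.
BLOCK_GRID = (4, 8, 16, 32, 64)

#: Default per-window free-energy target, in multiples of kT. Exponential
#: averaging converges with reasonable sampling when each window's ΔG stays
#: below about 2 kT.
DEFAULT_TARGET_KT = 2.0

#: Amplitude (in kT) of the default quadratic charging probe used to fit the
#: exponential schedule: the linear-response magnitude of a full charging leg
#: for which uniform spacing would need over 130 windows.
DEFAULT_PROBE_AMPLITUDE_KT = 131.0

_TILE_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaSchedule:
    """An ordered λ grid (FEP window edges) or quadrature nodes+weights.

    ``kind`` is one of ``uniform``, ``exponential`` (window edges spanning
    [0, 1]) or ``gauss_legendre_7`` (7 interior nodes with weights summing
    to 1 on [0, 1]).
    """

    kind: str
    values: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        v = self.values
        if v.ndim != 1 or len(v) < 2:
            raise ScheduleError("schedule needs at least two λ values")
        if np.any(np.diff(v) <= 0):
            raise ScheduleError("λ values must be strictly increasing")
        if self.kind in ("gauss_legendre_7", "quadrature"):
            if len(self.weights) != len(v):
                raise ScheduleError("quadrature schedules need one weight per node")
            if self.kind == "gauss_legendre_7":
                if len(v) != 7:
                    raise ScheduleError("gauss_legendre_7 requires exactly 7 nodes and weights")
                if not math.isclose(self.weights.sum(), 1.0, rel_tol=1e-12):
                    raise ScheduleError("quadrature weights must sum to 1 on [0,1]")
                if v[0] <= 0.0 or v[-1] >= 1.0:
                    raise ScheduleError("gauss_legendre_7 nodes must be interior to (0,1)")
            if v[0] < 0.0 or v[-1] > 1.0:
                raise ScheduleError("quadrature nodes must lie within [0,1]")
        else:
            if not (math.isclose(v[0], 0.0, abs_tol=1e-12)
                    and math.isclose(v[-1], 1.0, abs_tol=1e-12)):
                raise ScheduleError("FEP schedules must start at λ=0 and end at λ=1")
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ScheduleError("λ values must lie in [0,1]")

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1

    def subintervals(self) -> list[tuple[float, float]]:
        v = self.values
        return [(float(v[i]), float(v[i + 1])) for i in range(len(v) - 1)]


@dataclass
class EnergySeries:
    """One window's sample stream: ΔU for FEP or ∂H/∂λ for TI.

    ``lam`` is the λ at which configurations were sampled; for FEP windows
    ``lam_target`` is the neighbouring λ the gap is taken to (greater than
    ``lam`` for forward windows, smaller for backward). ``weight`` is the
    quadrature weight for TI nodes. ``samples`` holds post-equilibration
    values only; the discarded span is recorded as metadata.
    """

    samples: np.ndarray
    lam: float
    kind: str = "delta_u"            # "delta_u" | "dhdl"
    lam_target: float | None = None
    weight: float | None = None
    stage: str = "stage"
    direction: str = "forward"
    window: int = 0
    sample_interval_ps: float = 1.0
    equilibration_ps: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise SampleSizeError("EnergySeries requires at least one retained sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EnergySeries samples must be finite")
        if self.kind not in ("delta_u", "dhdl"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def n(self) -> int:
        return int(self.samples.size)


@dataclass
class FreeEnergyEstimate:
    """A stage free energy with its block-analysis uncertainty.

    ``per_window`` is a list of dicts (window, λ metadata, ΔG, stderr, n)
    preserving the per-subinterval breakdown.
    """

    value: float
    stderr: float
    method: str                       # "FEP" | "TI"
    direction: str                    # "forward" | "backward" | "averaged"
    per_window: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")

    @staticmethod
    def average(forward: "FreeEnergyEstimate",
                backward: "FreeEnergyEstimate") -> "FreeEnergyEstimate":
        """Combine a forward/backward pair: (forward − backward)/2.

        The backward run estimates −ΔG, so the half-difference is the
        symmetrised estimate of ΔG.
        """
        if forward.method != backward.method:
            raise ValueError("cannot average estimates from different methods")
        return FreeEnergyEstimate(
            value=0.5 * (forward.value - backward.value),
            stderr=0.5 * math.hypot(forward.stderr, backward.stderr),
            method=forward.method,
            direction="averaged",
        )


# ---------------------------------------------------------------------------
# λ scheduling
# ---------------------------------------------------------------------------

def quadratic_charging_probe(amplitude_kT: float = DEFAULT_PROBE_AMPLITUDE_KT
                             ) -> Callable[[np.ndarray], np.ndarray]:
    """Linear-response model of a charging leg: G(λ) = −a·λ² in kT units.

    Charging a side chain against a polarisable environment gives a free
    energy quadratic in the coupling; the default amplitude corresponds to a
    leg steep enough that uniform λ spacing needs over 130 windows to keep
    every per-window ΔG below 2 kT.
    """
    if amplitude_kT <= 0:
        raise ValueError("probe amplitude must be positive")

    def probe(lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return -amplitude_kT * lam ** 2

    return probe


def _exponential_values(alpha: float, n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    if abs(alpha) < 1e-9:
        return k / n
    return np.expm1(alpha * k / n) / np.expm1(alpha)


def _max_window_dg(values: np.ndarray, probe: Callable) -> float:
    g = np.asarray(probe(values), dtype=float)
    return float(np.max(np.abs(np.diff(g))))


def _fit_alpha(n: int, probe: Callable) -> tuple[float, float]:
    """Best geometric-spacing α for ``n`` windows; returns (α, max ΔG in kT)."""
    best = (0.0, _max_window_dg(_exponential_values(0.0, n), probe))
    for lo, hi in ((-60.0, -1e-3), (1e-3, 60.0)):
        res = minimize_scalar(
            lambda a: _max_window_dg(_exponential_values(a, n), probe),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun < best[1]:
            best = (float(res.x), float(res.fun))
    return best


def _required_n(fit: Callable[[int], float], target: float, n_max: int = 100_000) -> int:
    """Smallest n with fit(n) ≤ target, by doubling then bisection."""
    lo, hi = 2, 2
    while fit(hi) > target:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ScheduleError(f"target {target} kT unreachable below n={n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if fit(mid) <= target:
            hi = mid
        else:
            lo = mid + 1
    return hi


def build_schedule(kind: str,
                   n_windows: int | None = None,
                   target_per_window: float = DEFAULT_TARGET_KT,
                   probe: Callable[[np.ndarray], np.ndarray] | None = None,
                   ) -> LambdaSchedule:
    """Construct a λ schedule.

    Parameters
    ----------
    kind : {"uniform", "exponential", "gauss_legendre_7"}
    n_windows : int
        Number of subintervals (FEP kinds). Ignored for quadrature.
    target_per_window : float
        Per-window |ΔG| bound in multiples of kT, enforced against ``probe``.
    probe : callable, optional
        Model free energy G(λ)/kT evaluated on an array of λ values. For the
        exponential kind, the spacing parameter α is fitted by minimising the
        maximum per-window |ΔG| on this probe (default: quadratic charging
        model). For the uniform kind a probe, when given, is only used to
        verify the target.

    Raises
    ------
    ScheduleError
        If the target is unsatisfiable at ``n_windows``; ``required_n`` on
        the exception is the smallest satisfying window count.
    """
    if kind == "gauss_legendre_7":
        x, w = np.polynomial.legendre.leggauss(7)
        return LambdaSchedule("gauss_legendre_7", (x + 1.0) / 2.0, w / 2.0)

    if n_windows is None or n_windows < 2:
        raise ScheduleError("n_windows must be an integer ≥ 2")

    if kind == "uniform":
        values = np.linspace(0.0, 1.0, n_windows + 1)
        if probe is not None:
            worst = _max_window_dg(values, probe)
            if worst > target_per_window:
                n_req = _required_n(
                    lambda n: _max_window_dg(np.linspace(0, 1, n + 1), probe),
                    target_per_window)
                raise ScheduleError(
                    f"uniform schedule with {n_windows} windows has max window "
                    f"ΔG = {worst:.3f} kT > {target_per_window} kT; "
                    f"{n_req} windows required", required_n=n_req)
        return LambdaSchedule("uniform", values)

    if kind == "exponential":
        if probe is None:
            probe = quadratic_charging_probe()
        alpha, worst = _fit_alpha(n_windows, probe)
        if worst > target_per_window:
            n_req = _required_n(lambda n: _fit_alpha(n, probe)[1], target_per_window)
            raise ScheduleError(
                f"exponential schedule with {n_windows} windows has best "
                f"max window ΔG = {worst:.3f} kT > {target_per_window} kT; "
                f"{n_req} windows required", required_n=n_req)
        return LambdaSchedule("exponential", _exponential_values(alpha, n_windows))

    raise ScheduleError(f"unknown schedule kind {kind!r}")


# ---------------------------------------------------------------------------
# block-averaged errors and running diagnostics
# ---------------------------------------------------------------------------

def _block_se(x: np.ndarray, n_blocks: int) -> float:
    m = x.size // n_blocks
    means = x[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


def block_error(samples: EnergySeries | np.ndarray,
                n_blocks_grid: Sequence[int] = BLOCK_GRID) -> float:
    """Block-averaged standard error of the mean at the plateau.

    The error is computed on a grid of block counts, coarse (few, long
    blocks) to fine; the plateau is the first adjacent pair whose errors
    differ by less than 10%, and the coarser member's error is returned.
    Without a plateau the maximum over the grid is returned, which is
    conservative for correlated data.
    """
    x = samples.samples if isinstance(samples, EnergySeries) else np.asarray(samples, float)
    grid = sorted(n_blocks_grid)
    if x.size < 2 * grid[0]:
        raise SampleSizeError(
            f"need at least {2 * grid[0]} samples for {grid[0]}-block analysis, got {x.size}")
    if np.ptp(x) == 0.0:
        return 0.0
    errs = [_block_se(x, nb) for nb in grid if x.size // nb >= 2]
    for coarse, fine in zip(errs, errs[1:]):
        if coarse == 0.0:
            return 0.0
        if abs(fine - coarse) < 0.1 * coarse:
            return coarse
    return max(errs)


def running_average(series: EnergySeries, statistic: str = "mean",
                    ctx: ThermoContext | None = None) -> np.ndarray:
    """Cumulative per-sample estimate, for convergence plots.

    ``statistic="mean"`` gives running sample means (the TI integrand);
    ``statistic="fep"`` gives the running window free energy
    −kT·ln⟨exp(−ΔU/kT)⟩ over the first k samples, whose final element equals
    the full-window FEP estimate.
    """
    x = series.samples
    if statistic == "mean":
        return np.cumsum(x) / np.arange(1, x.size + 1)
    if statistic == "fep":
        if ctx is None:
            raise ValueError("statistic='fep' requires a ThermoContext")
        s = -x / ctx.kT
        log_cumsum = np.logaddexp.accumulate(s)
        return -ctx.kT * (log_cumsum - np.log(np.arange(1, x.size + 1)))
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# FEP and TI estimators
# ---------------------------------------------------------------------------

def _window_fep(series: EnergySeries, kT: float) -> tuple[float, float]:
    """Per-window ΔG = −kT·ln⟨exp(−ΔU/kT)⟩ with a block-analysis stderr.

    The exponential average is evaluated through a log-sum-exp shift; the
    error of the log-mean is the block error of the shifted weights divided
    by their mean (delta method).
    """
    s = -series.samples / kT
    n = s.size
    dg = -kT * (logsumexp(s) - math.log(n))
    w = np.exp(s - s.max())
    mean_w = w.mean()
    try:
        se_w = block_error(w)
    except SampleSizeError:
        se_w = float(w.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(dg), float(kT * se_w / mean_w)


def _check_tiling(windows: list[EnergySeries]) -> list[EnergySeries]:
    intervals = []
    for s in windows:
        if s.lam_target is None:
            raise ScheduleError("FEP windows need lam_target metadata")
        lo, hi = sorted((s.lam, s.lam_target))
        intervals.append((lo, hi, s))
    intervals.sort(key=lambda t: t[0])
    if abs(intervals[0][0]) > _TILE_TOL or abs(intervals[-1][1] - 1.0) > _TILE_TOL:
        raise ScheduleError("FEP windows must tile [0,1]: endpoints missing")
    for (_, hi_a, _), (lo_b, _, _) in zip(intervals, intervals[1:]):
        if abs(hi_a - lo_b) > _TILE_TOL:
            kindw = "gap" if lo_b > hi_a else "overlap"
            raise ScheduleError(f"FEP windows must tile [0,1]: {kindw} at λ={hi_a:.6g}")
    return [s for (_, _, s) in intervals]


def fep_estimate(windows: Iterable[EnergySeries], ctx: ThermoContext) -> FreeEnergyEstimate:
    """Stage free energy by exponential averaging over contiguous λ windows.

    Each window contributes ΔG_i = −kT·ln⟨exp(−ΔU_i/kT)⟩; the stage value is
    Σ ΔG_i and the uncertainty combines per-window block errors in
    quadrature. All windows must share a direction and tile [0,1].
    """
    ws = list(windows)
    if not ws:
        raise ScheduleError("no FEP windows given")
    directions = {s.direction for s in ws}
    if len(directions) > 1:
        raise ScheduleError(f"mixed window directions {sorted(directions)}")
    ordered = _check_tiling(ws)
    kT = ctx.kT
    per_window, total, var = [], 0.0, 0.0
    for s in ordered:
        dg, se = _window_fep(s, kT)
        total += dg
        var += se * se
        per_window.append({
            "window": s.window, "lam": s.lam, "lam_target": s.lam_target,
            "dG": dg, "stderr": se, "n": s.n,
        })
    return FreeEnergyEstimate(total, math.sqrt(var), "FEP",
                              direction=directions.pop(), per_window=per_window)


def ti_estimate(nodes: Iterable[EnergySeries], schedule: LambdaSchedule,
                ctx: ThermoContext) -> FreeEnergyEstimate:
    """Stage free energy as the quadrature sum Σ w_j·⟨∂H/∂λ⟩_j.

    Expects one ∂H/∂λ series per schedule node; per-node block errors are
    propagated through the quadrature weights. Node sets other than
    seven-point Gauss–Legendre are allowed but flagged with a warning.
    """
    if schedule.kind != "gauss_legendre_7":
        warnings.warn("TI with a non-gauss_legendre_7 node set", stacklevel=2)
        if schedule.weights.size != schedule.values.size:
            raise ScheduleError("TI schedule must carry one weight per node")
    ns = sorted(nodes, key=lambda s: s.lam)
    if len(ns) != len(schedule.values):
        raise ScheduleError(
            f"{len(ns)} series for {len(schedule.values)} quadrature nodes")
    directions = {s.direction for s in ns}
    if len(directions) > 1:
        raise ScheduleError(f"mixed node directions {sorted(directions)}")
    per_window, total, var = [], 0.0, 0.0
    for s, lam, w in zip(ns, schedule.values, schedule.weights):
        if abs(s.lam - lam) > 1e-6:
            raise ScheduleError(f"series at λ={s.lam} does not match node λ={lam}")
        mean = float(s.samples.mean())
        try:
            se = block_error(s)
        except SampleSizeError:
            se = float(s.samples.std(ddof=1) / math.sqrt(s.n)) if s.n > 1 else 0.0
        total += w * mean
        var += (w * se) ** 2
        per_window.append({
            "window": s.window, "lam": float(lam), "weight": float(w),
            "mean_dHdl": mean, "stderr": se, "n": s.n,
        })
    return FreeEnergyEstimate(float(total), math.sqrt(var), "TI",
                              direction=directions.pop(), per_window=per_window)


def hysteresis(forward: FreeEnergyEstimate, backward: FreeEnergyEstimate) -> float:
    """Forward + backward stage values; zero for a perfectly converged pair.

    The backward run estimates −ΔG, so the sum measures the systematic
    discrepancy. Values above 1 kcal/mol in magnitude are flagged by the
    reporting layer.
    """
    return forward.value + backward.value


# ---------------------------------------------------------------------------
# readers for the stage-file dialects
# ---------------------------------------------------------------------------

def _parse_tsv(path: Path) -> tuple[dict, np.ndarray]:
    """Read '#'-headed TSV; returns (header dict, sample column)."""
    header: dict[str, str] = {}
    values: list[float] = []
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
                v = float(cols[1])
            except ValueError:
                raise ParseError(f"{path}:{i}: unparseable value {cols[1]!r}", line=i) from None
            if not math.isfinite(v):
                raise ParseError(f"{path}:{i}: non-finite sample {cols[1]!r}", line=i)
            values.append(v)
    if not values:
        raise ParseError(f"{path}: no data rows")
    return header, np.asarray(values)


def read_fep_window(path: str | Path) -> EnergySeries:
    """Read one FEP window file (rows ``step<TAB>deltaU_kcal_mol``)."""
    path = Path(path)
    header, samples = _parse_tsv(path)
    try:
        return EnergySeries(
            samples=samples,
            lam=float(header["lambda0"]),
            lam_target=float(header["lambda1"]),
            kind="delta_u",
            stage=header.get("stage", "stage"),
            direction=header.get("direction", "forward"),
            window=int(header.get("window", 0)),
            sample_interval_ps=float(header.get("sample_interval_ps", 1.0)),
            equilibration_ps=float(header.get("equilibration_ps", 0.0)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from None


def read_ti_node(path: str | Path) -> EnergySeries:
    """Read one TI node file (rows ``step<TAB>dHdlambda_kcal_mol``)."""
    path = Path(path)
    header, samples = _parse_tsv(path)
    try:
        return EnergySeries(
            samples=samples,
            lam=float(header["lambda"]),
            weight=float(header["weight"]),
            kind="dhdl",
            stage=header.get("stage", "stage"),
            direction=header.get("direction", "forward"),
            window=int(header.get("window", 0)),
            sample_interval_ps=float(header.get("sample_interval_ps", 1.0)),
            equilibration_ps=float(header.get("equilibration_ps", 0.0)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from None


def read_stage_directory(directory: str | Path, kind: str = "delta_u") -> list[EnergySeries]:
    """Read every window/node file of a stage directory, sorted by filename."""
    directory = Path(directory)
    reader = read_fep_window if kind == "delta_u" else read_ti_node
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise ParseError(f"no .tsv window files in {directory}")
    return [reader(f) for f in files]
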