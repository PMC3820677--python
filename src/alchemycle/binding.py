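"""Standard-state binding free energies from a PMF, and affinity conversions.

A 1-D PMF along the channel axis is turned into a binding constant by
integrating the Boltzmann factor over the bound region and weighting with
the cross-sectional area πR² explored by the ligand's center of mass:

    K_b = C0 · πR² · ∫_{z1}^{z2} exp(−W(z)/kT) dz,     G_b = −kT·ln K_b.

Experimental half-inhibitory concentrations of a pore blocker are treated as
dissociation constants (full block at a single saturable site), giving
G_b = kT·ln(IC50/C0) on the same 1 M standard state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnchorError
from .thermo import ThermoContext
from .wham import DEFAULT_ANCHOR_SPAN, PMFProfile

__all__ = [
    "BindingResult",
    "AffinityMeasurement",
    "integrate_pmf",
    "transverse_R",
    "ic50_to_Gb",
    "Gb_to_ic50",
    "ic50_Gb_uncertainty",
    "fold_selectivity",
]

#: Tolerated |W| in the declared bulk region before the anchor is rejected.
BULK_TOLERANCE = 0.5

#: Default offset of z1 below the PMF minimum, Å.
DEFAULT_Z1_OFFSET = 2.0


@dataclass(frozen=True)
class BindingResult:
    """Binding constant and absolute free energy derived from one PMF."""

    well_depth: float          # ΔW_well = min W − bulk (≤ 0 for binders), kcal/mol
    K_b: float                 # dimensionless, relative to C0
    G_b: float                 # kcal/mol
    R: float                   # transverse radius, Å
    z1: float
    z2: float
    ctx: ThermoContext
    stderr: float = 0.0


@dataclass(frozen=True)
class AffinityMeasurement:
    """An experimental half-inhibitory concentration for one channel–ligand pair."""

    channel: str
    ligand: str
    ic50_molar: float
    uncertainty_molar: float = 0.0

    def __post_init__(self):
        if self.ic50_molar <= 0:
            raise ValueError("IC50 must be positive")
        if self.uncertainty_molar < 0:
            raise ValueError("IC50 uncertainty must be non-negative")


def integrate_pmf(pmf: PMFProfile, R: float, ctx: ThermoContext,
                  z1: float | None = None, z2: float | None = None) -> BindingResult:
    """Binding constant and G_b from the Boltzmann integral of the PMF.

    ``z1`` defaults to 2 Å below the PMF minimum (clipped to the grid) and
    ``z2`` to the start of the bulk anchor span. The profile must be
    anchored: if W at the bulk boundary deviates from zero by more than
    0.5 kcal/mol an :class:`AnchorError` is raised. Integration is
    trapezoidal on the (dense) PMF grid.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    finite = np.isfinite(pmf.W)
    z = pmf.z[finite]
    W = pmf.W[finite]
    if z.size < 2:
        raise ValueError("PMF has fewer than two finite grid points")
    if z1 is None:
        z1 = max(float(z[np.argmin(W)]) - DEFAULT_Z1_OFFSET, float(z[0]))
    if z2 is None:
        z2 = float(z[-1]) - DEFAULT_ANCHOR_SPAN
    if not (z[0] - 1e-9 <= z1 < z2 <= z[-1] + 1e-9):
        raise ValueError(f"[z1, z2] = [{z1}, {z2}] must lie within the PMF grid")

    w_bulk = float(np.interp(z2, z, W))
    if abs(w_bulk) > BULK_TOLERANCE:
        raise AnchorError(
            f"W({z2:.2f} Å) = {w_bulk:.3f} kcal/mol: the declared bulk boundary "
            f"deviates from zero by more than {BULK_TOLERANCE} kcal/mol")

    kT = ctx.kT
    inside = (z >= z1) & (z <= z2)
    zi = np.concatenate(([z1], z[inside], [z2]))
    wi = np.concatenate(([np.interp(z1, z, W)], W[inside], [w_bulk]))
    # de-duplicate in case z1/z2 coincide with grid points
    keep = np.concatenate(([True], np.diff(zi) > 1e-12))
    zi, wi = zi[keep], wi[keep]

    integral = float(np.trapezoid(np.exp(-wi / kT), zi))     # Å
    K_b = ctx.C0 * math.pi * R ** 2 * integral               # dimensionless
    G_b = -kT * math.log(K_b)
    well_depth = float(W[inside].min())
    return BindingResult(well_depth=well_depth, K_b=K_b, G_b=G_b,
                         R=R, z1=float(z1), z2=float(z2), ctx=ctx)


def transverse_R(x_fluct: np.ndarray, y_fluct: np.ndarray) -> float:
    """Transverse radius from center-of-mass fluctuations in the bound state.

    R = sqrt(⟨δx²⟩ + ⟨δy²⟩) over restraint-free samples; this combined RMS
    width is the radius whose circle πR² measures the cross-sectional area
    the ligand's center of mass explores in the binding pocket.
    """
    x = np.asarray(x_fluct, dtype=float)
    y = np.asarray(y_fluct, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two samples per axis")
    r2 = x.var() + y.var()
    if r2 == 0.0:
        warnings.warn("zero transverse variance: degenerate fluctuation input",
                      stacklevel=2)
        return 0.0
    return float(math.sqrt(r2))


def ic50_to_Gb(m: AffinityMeasurement, ctx: ThermoContext) -> float:
    """Binding free energy from an IC50 treated as a dissociation constant.

    G_b = kT·ln(IC50/C0) with C0 = 1 M; negative for sub-molar affinities.
    """
    return ctx.kT * math.log(m.ic50_molar / ctx.C0_molar)


def Gb_to_ic50(G_b: float, ctx: ThermoContext) -> float:
    """Inverse of :func:`ic50_to_Gb`: the molar IC50 implied by G_b."""
    return ctx.C0_molar * math.exp(G_b / ctx.kT)


def ic50_Gb_uncertainty(m: AffinityMeasurement, ctx: ThermoContext) -> float:
    """First-order propagation of the IC50 uncertainty into G_b, kcal/mol."""
    return ctx.kT * m.uncertainty_molar / m.ic50_molar


def fold_selectivity(a: AffinityMeasurement, b: AffinityMeasurement) -> float:
    """Ratio IC50(a)/IC50(b); >1 when the ligand prefers system b."""
    return a.ic50_molar / b.ic50_molar
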