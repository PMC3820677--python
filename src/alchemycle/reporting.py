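"""Thermodynamic-cycle accounting, selectivity free energies and reports.

The charge-neutral mutation cycle has three legs — discharge the mutated
side chain in the site (with the reverse in bulk), transform the uncharged
side chain, re-charge the new side chain — and the relative binding free
energy is their sum:

    ΔΔG_b = ΔG_coulomb_discharge + ΔG_lj_transform + ΔG_coulomb_charge.

The selectivity gain of a mutation between two channels is the difference
of its ΔΔG_b values, ΔΔG_sel = ΔΔG_b(off-target) − ΔΔG_b(target); stage and
leg uncertainties combine in quadrature throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .binding import BindingResult, integrate_pmf
from .errors import ConfigurationError, IncompleteCycleError, LabelError, ParseError
from .estimators import (FreeEnergyEstimate, build_schedule, fep_estimate,
                         hysteresis, ti_estimate)
from .thermo import ThermoContext
from .wham import pmf_block_convergence, wham_solve

__all__ = [
    "CYCLE_STAGES",
    "StageEstimate",
    "CycleResult",
    "SelectivityResult",
    "combine_cycle",
    "selectivity",
    "ddG_from_binding",
    "render_tables",
    "run_selectivity_benchmark",
    "write_machine_report",
    "read_machine_report",
    "read_config",
    "write_config",
    "round_half_away",
    "HYSTERESIS_FLAG_KCAL",
]

#: The three legs of the charge-neutral mutation cycle, in order.
CYCLE_STAGES = ("coulomb_discharge", "lj_transform", "coulomb_charge")

#: |forward + backward| above this value is flagged in reports, kcal/mol.
HYSTERESIS_FLAG_KCAL = 1.0


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table display convention)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StageEstimate:
    """One cycle leg for one channel, in forward and backward directions."""

    stage: str
    channel: str
    forward: FreeEnergyEstimate | None = None
    backward: FreeEnergyEstimate | None = None

    def __post_init__(self):
        if self.stage not in CYCLE_STAGES:
            raise LabelError(f"unknown stage {self.stage!r}; expected one of {CYCLE_STAGES}")
        if self.forward is None and self.backward is None:
            raise IncompleteCycleError(f"stage {self.stage} has no estimate")

    @classmethod
    def from_values(cls, stage: str, channel: str,
                    forward: tuple[float, float] | None = None,
                    backward: tuple[float, float] | None = None,
                    method: str = "FEP") -> "StageEstimate":
        """Build a stage from printed (value, stderr) pairs."""
        mk = lambda pair, direction: None if pair is None else FreeEnergyEstimate(
            value=pair[0], stderr=pair[1], method=method, direction=direction)
        return cls(stage=stage, channel=channel,
                   forward=mk(forward, "forward"), backward=mk(backward, "backward"))

    @property
    def method(self) -> str:
        return (self.forward or self.backward).method

    def estimate(self, direction: str = "averaged") -> FreeEnergyEstimate:
        """The stage value in the requested direction.

        ``averaged`` is (forward − backward)/2 when both runs exist — the
        backward leg estimates −ΔG — and falls back to whichever single
        direction is present.
        """
        if direction == "forward":
            if self.forward is None:
                raise IncompleteCycleError(f"stage {self.stage} has no forward run")
            return self.forward
        if direction == "backward":
            if self.backward is None:
                raise IncompleteCycleError(f"stage {self.stage} has no backward run")
            return self.backward
        if direction == "averaged":
            if self.forward is not None and self.backward is not None:
                return FreeEnergyEstimate.average(self.forward, self.backward)
            return self.forward or self.backward
        raise ValueError(f"unknown direction {direction!r}")

    @property
    def hysteresis(self) -> float | None:
        if self.forward is None or self.backward is None:
            return None
        return hysteresis(self.forward, self.backward)


@dataclass
class CycleResult:
    """The three stage estimates of one channel and their cycle sum."""

    channel: str
    method: str
    stages: dict[str, StageEstimate]
    ddG: float
    stderr: float
    direction: str = "averaged"

    def total(self, direction: str) -> tuple[float, float]:
        """Cycle sum and quadrature error for one direction."""
        vals = [s.estimate(direction) for s in (self.stages[k] for k in CYCLE_STAGES)]
        return (sum(v.value for v in vals),
                math.sqrt(sum(v.stderr ** 2 for v in vals)))

    def hysteresis_by_stage(self) -> dict[str, float | None]:
        return {k: self.stages[k].hysteresis for k in CYCLE_STAGES}

    def flagged_stages(self) -> list[str]:
        """Stages whose |forward + backward| exceeds the 1 kcal/mol flag."""
        return [k for k, h in self.hysteresis_by_stage().items()
                if h is not None and abs(h) > HYSTERESIS_FLAG_KCAL]


@dataclass
class SelectivityResult:
    """Mutation-induced ΔΔG_b of two channels and their difference."""

    ddG_off_target: float           # e.g. Kv1.1
    ddG_target: float               # e.g. Kv1.3
    ddG_sel: float
    stderr: float
    provenance: str = "FEP"
    stderr_off_target: float = 0.0
    stderr_target: float = 0.0
    channels: tuple[str, str] = ("off_target", "target")


# ---------------------------------------------------------------------------
# cycle arithmetic
# ---------------------------------------------------------------------------

def combine_cycle(stages, direction: str = "averaged") -> CycleResult:
    """Sum the three cycle legs of one channel with quadrature errors.

    ``stages`` are :class:`StageEstimate` objects covering exactly the three
    legs of the mutation cycle for the same channel and method.
    """
    stages = list(stages)
    by_stage = {s.stage: s for s in stages}
    missing = [k for k in CYCLE_STAGES if k not in by_stage]
    if missing or len(stages) != len(CYCLE_STAGES):
        raise IncompleteCycleError(
            f"cycle needs exactly stages {CYCLE_STAGES}; missing {missing or 'none'}, "
            f"got {[s.stage for s in stages]}")
    channels = {s.channel for s in stages}
    if len(channels) != 1:
        raise LabelError(f"mixed channels in one cycle: {sorted(channels)}")
    methods = {s.method for s in stages}
    method = methods.pop() if len(methods) == 1 else "mixed"
    vals = [by_stage[k].estimate(direction) for k in CYCLE_STAGES]
    ddG = sum(v.value for v in vals)
    stderr = math.sqrt(sum(v.stderr ** 2 for v in vals))
    return CycleResult(channel=channels.pop(), method=method, stages=by_stage,
                       ddG=ddG, stderr=stderr, direction=direction)


def _value_err_label(x) -> tuple[float, float, str]:
    if isinstance(x, CycleResult):
        return x.ddG, x.stderr, x.method
    if isinstance(x, BindingResult):
        return x.G_b, x.stderr, "PMF"
    if isinstance(x, FreeEnergyEstimate):
        return x.value, x.stderr, x.method
    if isinstance(x, tuple):
        return float(x[0]), float(x[1]), "scalar"
    return float(x), 0.0, "scalar"


def selectivity(off_target, target, provenance: str | None = None,
                channels: tuple[str, str] = ("off_target", "target")) -> SelectivityResult:
    """Selectivity free energy ΔΔG_sel = ΔΔG_b(off-target) − ΔΔG_b(target).

    Accepts :class:`CycleResult` objects, (value, stderr) tuples or plain
    scalars for either channel, so FEP/TI cycles, PMF differences and
    experimental ΔΔG_b values are treated uniformly. A positive ΔΔG_sel
    means the mutation penalises off-target binding more: a selectivity gain.
    """
    v1, e1, m1 = _value_err_label(off_target)
    v2, e2, m2 = _value_err_label(target)
    if provenance is None:
        provenance = m1 if m1 == m2 else "mixed"
    return SelectivityResult(
        ddG_off_target=v1, ddG_target=v2, ddG_sel=v1 - v2,
        stderr=math.hypot(e1, e2), provenance=provenance,
        stderr_off_target=e1, stderr_target=e2, channels=channels)


def ddG_from_binding(mutant, wild) -> tuple[float, float]:
    """ΔΔG_b = G_b(mutant) − G_b(wild), with quadrature error.

    Works identically for PMF-integrated :class:`BindingResult` objects,
    well depths, experimental G_b values or (value, stderr) tuples.
    """
    vm, em, _ = _value_err_label(mutant)
    vw, ew, _ = _value_err_label(wild)
    return vm - vw, math.hypot(em, ew)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(value: float, err: float | None = None, decimals: int = 1) -> str:
    v = round_half_away(value, decimals)
    if err is None:
        return f"{v:.{decimals}f}"
    return f"{v:.{decimals}f}±{round_half_away(err, decimals):.{decimals}f}"


def _provenance_header(provenance: dict | None) -> list[str]:
    lines = []
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}\t{val}")
    return lines


def write_machine_report(records: list[dict], path: str | Path,
                         provenance: dict | None = None) -> None:
    """One record per quantity: name, value, stderr, method, provenance.

    Full precision is preserved (floats written with repr); the rendered
    tables are derived views of this file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_header(provenance):
            fh.write(line + "\n")
        fh.write("name\tvalue\tstderr\tmethod\tprovenance\n")
        for r in records:
            fh.write(f"{r['name']}\t{float(r['value'])!r}\t{float(r.get('stderr', 0.0))!r}"
                     f"\t{r.get('method', '-')}\t{r.get('provenance', '-')}\n")


def read_machine_report(path: str | Path) -> list[dict]:
    """Read back a machine report; inverse of :func:`write_machine_report`."""
    records = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(f"{path}:{i}: expected 5 columns", line=i)
            records.append({"name": cols[0], "value": float(cols[1]),
                            "stderr": float(cols[2]), "method": cols[3],
                            "provenance": cols[4]})
    return records


def render_tables(directory: str | Path,
                  cycles: list[CycleResult] = (),
                  bindings: dict[str, BindingResult | tuple] | None = None,
                  experimental: dict[str, tuple] | None = None,
                  selectivities: list[SelectivityResult] = (),
                  provenance: dict | None = None) -> dict[str, Path]:
    """Emit per-stage, binding and selectivity tables plus a machine report.

    Three human-readable/TSV tables mirror the standard presentation of a
    mutation study — stage breakdowns with forward/backward/average rows,
    well depths with absolute binding energies, and ΔΔG_b/ΔΔG_sel per
    method — all displayed to 1 decimal with ± errors. ``report.tsv`` keeps
    every number at full precision and re-reads losslessly. A missing
    bindings input omits the binding table with a notice.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    records: list[dict] = []
    header = _provenance_header(provenance)

    # --- stage table -------------------------------------------------------
    stage_path = directory / "stage_table.tsv"
    with open(stage_path, "w") as fh:
        fh.write("\n".join(header) + ("\n" if header else ""))
        fh.write("channel/method\tdirection\t" + "\t".join(CYCLE_STAGES) + "\ttotal\tflags\n")
        for cyc in cycles:
            directions = ["forward", "backward", "averaged"] \
                if all(s.backward is not None for s in cyc.stages.values()) else ["forward"]
            for direction in directions:
                cells = []
                for k in CYCLE_STAGES:
                    est = cyc.stages[k].estimate(direction)
                    cells.append(_fmt(est.value, est.stderr))
                    records.append({
                        "name": f"{cyc.channel}.{cyc.method}.{k}.{direction}",
                        "value": est.value, "stderr": est.stderr,
                        "method": cyc.method, "provenance": "stage"})
                tot, err = cyc.total(direction)
                records.append({
                    "name": f"{cyc.channel}.{cyc.method}.cycle_total.{direction}",
                    "value": tot, "stderr": err, "method": cyc.method,
                    "provenance": "cycle"})
                flags = ",".join(cyc.flagged_stages()) or "-"
                fh.write(f"{cyc.channel}/{cyc.method}\t{direction}\t"
                         + "\t".join(cells) + f"\t{_fmt(tot, err)}\t{flags}\n")
    paths["stage_table"] = stage_path

    # --- binding table -----------------------------------------------------
    binding_path = directory / "binding_table.tsv"
    with open(binding_path, "w") as fh:
        fh.write("\n".join(header) + ("\n" if header else ""))
        if not bindings:
            fh.write("# no PMF binding results supplied; table omitted\n")
        else:
            fh.write("complex\twell_depth\tG_b_PMF\tG_b_exp\n")
            for name, res in bindings.items():
                if isinstance(res, BindingResult):
                    depth, gb, err = res.well_depth, res.G_b, res.stderr
                else:
                    depth, gb, err = math.nan, float(res[0]), float(res[1])
                exp = (experimental or {}).get(name)
                exp_cell = _fmt(exp[0], exp[1]) if exp else "-"
                depth_cell = "-" if math.isnan(depth) else _fmt(depth)
                fh.write(f"{name}\t{depth_cell}\t{_fmt(gb, err)}\t{exp_cell}\n")
                records.append({"name": f"{name}.G_b", "value": gb, "stderr": err,
                                "method": "PMF", "provenance": "binding"})
                if not math.isnan(depth):
                    records.append({"name": f"{name}.well_depth", "value": depth,
                                    "stderr": 0.0, "method": "PMF",
                                    "provenance": "binding"})
                if exp:
                    records.append({"name": f"{name}.G_b_exp", "value": exp[0],
                                    "stderr": exp[1], "method": "experiment",
                                    "provenance": "binding"})
    paths["binding_table"] = binding_path

    # --- selectivity table -------------------------------------------------
    sel_path = directory / "selectivity_table.tsv"
    with open(sel_path, "w") as fh:
        fh.write("\n".join(header) + ("\n" if header else ""))
        fh.write("method\tddG_b_" + "\tddG_b_".join(
            selectivities[0].channels if selectivities else ("off_target", "target"))
            + "\tddG_sel\n")
        for sel in selectivities:
            fh.write(f"{sel.provenance}\t{_fmt(sel.ddG_off_target, sel.stderr_off_target)}"
                     f"\t{_fmt(sel.ddG_target, sel.stderr_target)}"
                     f"\t{_fmt(sel.ddG_sel, sel.stderr)}\n")
            records.append({"name": f"ddG_sel.{sel.provenance}", "value": sel.ddG_sel,
                            "stderr": sel.stderr, "method": sel.provenance,
                            "provenance": "selectivity"})
            records.append({"name": f"ddG_b.{sel.channels[0]}.{sel.provenance}",
                            "value": sel.ddG_off_target,
                            "stderr": sel.stderr_off_target,
                            "method": sel.provenance, "provenance": "selectivity"})
            records.append({"name": f"ddG_b.{sel.channels[1]}.{sel.provenance}",
                            "value": sel.ddG_target, "stderr": sel.stderr_target,
                            "method": sel.provenance, "provenance": "selectivity"})
    paths["selectivity_table"] = sel_path

    report_path = directory / "report.tsv"
    write_machine_report(records, report_path, provenance)
    paths["machine_report"] = report_path
    return paths


# ---------------------------------------------------------------------------
# end-to-end toy benchmark
# ---------------------------------------------------------------------------

def run_selectivity_benchmark(ctx: ThermoContext, seed: int = 0,
                              n_samples: int = 4000,
                              n_fep_windows: int = 12,
                              langevin_steps: int = 20_000,
                              n_blocks: int = 4) -> dict:
    """Estimate the toy two-channel selectivity by all three routes.

    For each toy channel the mutation ΔΔG_b is computed three independent
    ways — exponential-averaging cycles (FEP), quadrature cycles (TI), and
    the difference of PMF-integrated binding free energies of mutant and
    wild-type — and the selectivity ΔΔG_sel is formed per route. Because the
    benchmark's stage targets sum to the exact PMF-route answer by
    construction, the three routes are estimates of the same quantity and
    must agree within sampling noise. PMF-route uncertainties come from the
    scatter of block-wise profiles.

    Returns a dict with per-channel route results and per-route
    :class:`SelectivityResult` objects plus the analytic answer.
    """
    # imported here to keep the module import graph one-directional
    from .toy_systems import (LangevinParams, PullProtocol,
                              run_umbrella_protocol, sample_fep_windows,
                              sample_ti_nodes, two_channel_benchmark)

    import numpy as np

    bench = two_channel_benchmark(ctx, seed=seed)
    sched = build_schedule("uniform", n_fep_windows)
    gl7 = build_schedule("gauss_legendre_7")
    seeds = iter(np.random.SeedSequence(seed).generate_state(64) % (2 ** 31))

    channels: dict[str, dict] = {}
    for name, toy in bench.items():
        fep_stages, ti_stages = [], []
        for stage, spec in toy.stages.items():
            fwd = fep_estimate(sample_fep_windows(
                spec, sched, ctx, n_samples, stage=stage, seed=int(next(seeds))), ctx)
            bwd = fep_estimate(sample_fep_windows(
                spec, sched, ctx, n_samples, direction="backward", stage=stage,
                seed=int(next(seeds))), ctx)
            fep_stages.append(StageEstimate(stage, name, fwd, bwd))
            tfwd = ti_estimate(sample_ti_nodes(
                spec, gl7, ctx, n_samples, stage=stage, seed=int(next(seeds))),
                gl7, ctx)
            tbwd = ti_estimate(sample_ti_nodes(
                spec, gl7, ctx, n_samples, direction="backward", stage=stage,
                seed=int(next(seeds))), gl7, ctx)
            ti_stages.append(StageEstimate(stage, name, tfwd, tbwd))

        gbs = {}
        for label, pot in (("wild", toy.wild), ("mutant", toy.mutant)):
            lang = LangevinParams(n_steps=langevin_steps, seed=int(next(seeds)))
            windows = run_umbrella_protocol(pot, PullProtocol(), lang, ctx,
                                            margin=1.0)
            pmf = wham_solve(windows, ctx)
            central = integrate_pmf(pmf, R=toy.R, ctx=ctx, z1=toy.z1, z2=toy.z2)
            blocks, _ = pmf_block_convergence(windows, n_blocks, ctx)
            block_gb = [integrate_pmf(p, R=toy.R, ctx=ctx, z1=toy.z1,
                                      z2=toy.z2).G_b for p in blocks]
            se = float(np.std(block_gb, ddof=1) / math.sqrt(n_blocks))
            gbs[label] = (central.G_b, se)
        channels[name] = {
            "FEP": combine_cycle(fep_stages),
            "TI": combine_cycle(ti_stages),
            "PMF": ddG_from_binding(gbs["mutant"], gbs["wild"]),
            "exact": toy.ddG_analytic,
        }

    names = list(channels)
    sel = {route: selectivity(channels[names[0]][route], channels[names[1]][route],
                              provenance=route, channels=tuple(names))
           for route in ("FEP", "TI", "PMF")}
    sel["exact"] = channels[names[0]]["exact"] - channels[names[1]]["exact"]
    return {"channels": channels, "selectivity": sel}


# ---------------------------------------------------------------------------
# flat key=value configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a flat ``key = value`` file with ``[section]`` headers.

    Values stay strings; callers coerce. Comments start with '#'.
    """
    sections: dict[str, dict[str, str]] = {}
    current = sections.setdefault("global", {})
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = sections.setdefault(line[1:-1].strip(), {})
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{i}: expected key = value, got {line!r}")
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def write_config(sections: dict[str, dict[str, str]], path: str | Path) -> None:
    """Inverse of :func:`read_config`."""
    with open(path, "w") as fh:
        for name, kv in sections.items():
            if name != "global":
                fh.write(f"[{name}]\n")
            for key, val in kv.items():
                fh.write(f"{key} = {val}\n")
            fh.write("\n")
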