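"""Dredging scenario enumeration and execution.

A scenario run has three periods: initialisation (the model settles onto the
site's baseline pattern from its initial beliefs), stress (dredging reduces
the probability of above-saturation light), and response (baseline light
returns; recovery is assessed over at least five years, the horizon beyond
which a loss is considered permanent).

Dredge designs follow the ``<total>-<rest>`` naming: 1-0 … 12-0 are
continuous campaigns of that many months; 6-3 and 6-2 split six months of
dredging into blocks alternating with rest months (D3 R3 D3 and
D2 R2 D2 R2 D2), starting and ending on a dredge block.  Every design is
applied at each start month of the year; the standard grid of eight dredge
designs plus a control across 12 start months gives 108 scenarios per site.
During dredged months the light-saturation probability is the smaller of the
baseline climatology and the scenario's permitted level (0, 0.25, 0.50 or
0.75); rest months and everything outside the stress span see baseline light.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ecowindows.dbn import (
    ForwardFilter,
    NetworkSchema,
    TrajectoryBeliefs,
    detect_limit_cycle,
    month_add,
)
from ecowindows.seagrass import (
    SiteConfig,
    TRACKED_NODES,
    build_reference_network,
    healthy_initial_beliefs,
)

logger = logging.getLogger(__name__)

LIGHT_LEVELS = (0.0, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class DredgeDesign:
    """One dredging campaign design.

    ``on_block``/``rest_block`` describe the repeating cycle for alternating
    designs; continuous designs have ``rest_block = 0``.
    """

    label: str
    total_dredge_months: int
    on_block: int
    rest_block: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control:
            if self.total_dredge_months != 0:
                raise ValueError("control design has zero dredge months")
            return
        if self.rest_block == 0 and self.on_block != self.total_dredge_months:
            raise ValueError("continuous design needs on_block == total_dredge_months")
        if self.rest_block > 0 and self.total_dredge_months % self.on_block:
            raise ValueError("alternating design needs total divisible by on_block")

    def month_pattern(self) -> list[bool]:
        """True for dredged months, False for interleaved rest months.

        Cycles start with a dredge block and end on one, so 6-3 spans nine
        calendar months (six dredged) and 6-2 spans ten (six dredged).
        """
        if self.is_control:
            return []
        if self.rest_block == 0:
            return [True] * self.total_dredge_months
        pattern: list[bool] = []
        blocks = self.total_dredge_months // self.on_block
        for b in range(blocks):
            if b:
                pattern.extend([False] * self.rest_block)
            pattern.extend([True] * self.on_block)
        return pattern

    @property
    def span_months(self) -> int:
        return len(self.month_pattern())


CONTROL = DredgeDesign("control", 0, 0, 0, is_control=True)

#: the eight standard dredge designs
PAPER_DESIGNS = (
    DredgeDesign("1-0", 1, 1, 0),
    DredgeDesign("2-0", 2, 2, 0),
    DredgeDesign("3-0", 3, 3, 0),
    DredgeDesign("6-0", 6, 6, 0),
    DredgeDesign("6-3", 6, 3, 3),
    DredgeDesign("6-2", 6, 2, 2),
    DredgeDesign("9-0", 9, 9, 0),
    DredgeDesign("12-0", 12, 12, 0),
)

DESIGNS_BY_LABEL = {d.label: d for d in PAPER_DESIGNS + (CONTROL,)}


@dataclass(frozen=True)
class Scenario:
    """Site × dredge design × start month × permitted light level."""

    site: SiteConfig
    design: DredgeDesign
    start_month: int
    light_level: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be in 1..12")
        if self.light_level not in LIGHT_LEVELS:
            raise ValueError(f"light_level must be one of {LIGHT_LEVELS}")

    @property
    def scenario_id(self) -> str:
        if self.design.is_control:
            return f"{self.site.site_name}__control__m{self.start_month:02d}"
        return (f"{self.site.site_name}__{self.design.label}"
                f"__m{self.start_month:02d}__l{int(self.light_level * 100):02d}")


@dataclass(frozen=True)
class RunWindows:
    """Lengths of the initialisation and response periods, in months."""

    initialisation_months: int = 24
    response_months: int = 60
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.initialisation_months < 0 or self.response_months < 1:
            raise ValueError("window lengths must be positive")


@dataclass
class RunResult:
    """Paired baseline (control) and stressed trajectories for one scenario."""

    scenario: Scenario
    baseline_traj: TrajectoryBeliefs
    response_traj: TrajectoryBeliefs
    stress_span: tuple[int, int] | None  # first/last dredging slice, inclusive
    windows: RunWindows
    metadata: dict = field(default_factory=dict)

    @property
    def stress_end_slice(self) -> int:
        """Last dredging slice; for controls, the virtual end of a zero-length stress."""
        if self.stress_span is None:
            return self.windows.initialisation_months - 1
        return self.stress_span[1]


def enumerate_scenarios(site: SiteConfig,
                        designs: Sequence[DredgeDesign] = PAPER_DESIGNS,
                        light_levels: Sequence[float] = (0.0,),
                        include_control: bool = True) -> list[Scenario]:
    """Cartesian scenario grid in deterministic (design, month, level) order.

    The control is light-invariant and is emitted once per start month, so
    the standard 8 designs + control at one light level give 108 scenarios.
    """
    if not designs:
        raise ValueError("designs must be nonempty")
    out: list[Scenario] = []
    for design in designs:
        for month in range(1, 13):
            for level in light_levels:
                out.append(Scenario(site, design, month, level))
    if include_control:
        for month in range(1, 13):
            out.append(Scenario(site, CONTROL, month, 0.0))
    return out


def apply_stressor_to_light(baseline_p: Sequence[float], scenario: Scenario,
                            windows: RunWindows) -> np.ndarray:
    """Per-slice above-saturation-light probability for the stressed run.

    ``baseline_p`` is the 12-month climatology (January first).  Slice 0 is
    the start of initialisation; dredging starts at the first slice after
    initialisation, which carries the scenario's start month.  Dredged months
    take ``min(baseline, light_level)`` — full deprivation at level 0 — and
    every other slice (initialisation, rest blocks, response) is baseline.
    """
    pattern = scenario.design.month_pattern()
    init = windows.initialisation_months
    n = init + len(pattern) + windows.response_months
    sim_start = month_add(scenario.start_month, -init)
    p = np.empty(n)
    for t in range(n):
        month = month_add(sim_start, t)
        base = baseline_p[month - 1]
        if init <= t < init + len(pattern) and pattern[t - init]:
            p[t] = min(base, scenario.light_level)
        else:
            p[t] = base
    return p


def _light_drivers(schema: NetworkSchema, p: np.ndarray) -> list[dict]:
    states = schema.node("light").states
    above = states.index("above_saturation")
    drivers = []
    for v in p:
        vec = np.empty(2)
        vec[above] = v
        vec[1 - above] = 1.0 - v
        drivers.append({"light": vec})
    return drivers


def run_scenario(scenario: Scenario, schema: NetworkSchema,
                 windows: RunWindows = RunWindows(),
                 filter_: ForwardFilter | None = None,
                 baseline_traj: TrajectoryBeliefs | None = None) -> RunResult:
    """Run the control and stressed trajectories for one scenario.

    Both runs share the same initial beliefs, slice/month alignment and
    length; the baseline can be passed in (from a cache) to avoid recomputing
    the control once per dredge scenario.  Initialisation convergence onto
    the baseline pattern is checked with a limit-cycle test and logged —
    non-convergence is a warning, not a failure, since transitory meadows
    cycle by design and some climates settle slowly.
    """
    ff = filter_ or ForwardFilter(schema)
    site = scenario.site
    init_beliefs = healthy_initial_beliefs(schema)
    sim_start = month_add(scenario.start_month, -windows.initialisation_months)
    p_stressed = apply_stressor_to_light(site.light_p, scenario, windows)
    n = len(p_stressed)

    if baseline_traj is None or len(baseline_traj) < n:
        p_base = np.array([site.light_p[month_add(sim_start, t) - 1] for t in range(n)])
        baseline_traj = ff.run(init_beliefs, sim_start, n,
                               _light_drivers(schema, p_base))

    if scenario.design.is_control:
        response_traj = baseline_traj
        stress_span = None
    else:
        response_traj = ff.run(init_beliefs, sim_start, n,
                               _light_drivers(schema, p_stressed))
        first = windows.initialisation_months
        stress_span = (first, first + scenario.design.span_months - 1)

    meta: dict = {"scenario_id": scenario.scenario_id, "n_slices": n,
                  "sim_start_month": sim_start}
    if len(baseline_traj) >= 2 * 12:
        converged, cycle_start = detect_limit_cycle(
            baseline_traj, 12, windows.convergence_tol,
            nodes=("realised_shoot_density", "baseline_population"))
        meta["initialisation_converged"] = converged
        meta["cycle_start_slice"] = cycle_start
        if not converged:
            logger.warning("scenario %s: baseline not settled at tol %.1e",
                           scenario.scenario_id, windows.convergence_tol)
    return RunResult(scenario=scenario, baseline_traj=baseline_traj,
                     response_traj=response_traj, stress_span=stress_span,
                     windows=windows, metadata=meta)


# ---------------------------------------------------------------------------
# study-scale execution
# ---------------------------------------------------------------------------

def _result_record(result: RunResult) -> dict:
    """JSON-serialisable record: per-slice state probabilities + metadata."""
    def traj_block(traj: TrajectoryBeliefs) -> dict:
        return {
            node: np.round(traj.marginal_series(node), 10).tolist()
            for node in TRACKED_NODES
        }

    sc = result.scenario
    return {
        "scenario_id": sc.scenario_id,
        "site": sc.site.site_name,
        "life_history": sc.site.life_history,
        "design": sc.design.label,
        "start_month": sc.start_month,
        "light_level": sc.light_level,
        "stress_span": list(result.stress_span) if result.stress_span else None,
        "initialisation_months": result.windows.initialisation_months,
        "response_months": result.windows.response_months,
        "months": result.response_traj.months,
        "state_labels": {
            node: list(result.response_traj.schema.node(node).states.labels)
            for node in TRACKED_NODES
        },
        "baseline": traj_block(result.baseline_traj),
        "response": traj_block(result.response_traj),
        "metadata": result.metadata,
    }


def run_study(sites: Iterable[SiteConfig],
              designs: Sequence[DredgeDesign] = PAPER_DESIGNS,
              light_levels: Sequence[float] = (0.0,),
              windows: RunWindows = RunWindows(),
              out_dir: str | Path | None = None,
              bundle_seed: int = 0,
              schema_for_site=None) -> list[RunResult]:
    """Run the full site × scenario grid, optionally streaming records to disk.

    With ``out_dir`` set, one JSON record per scenario id is written and
    existing records are not recomputed, so an interrupted study resumes
    where it stopped.  Individual scenario failures are logged and recorded;
    the study continues.  ``schema_for_site`` can override how a site's
    network is built (default: reference network with the archetype bundle
    for the site's life history, seeded by ``bundle_seed``).
    """
    from ecowindows.synth import canonical_bundle

    if schema_for_site is None:
        def schema_for_site(site: SiteConfig) -> NetworkSchema:
            return build_reference_network(
                site, canonical_bundle(site.life_history, site.meadow_type,
                                       seed=bundle_seed))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    results: list[RunResult] = []
    for site in sites:
        schema = schema_for_site(site)
        ff = ForwardFilter(schema)
        scenarios = enumerate_scenarios(site, designs, light_levels)
        baseline_cache: dict[int, TrajectoryBeliefs] = {}
        max_span = max((d.span_months for d in designs), default=0)
        for sc in scenarios:
            if sc.start_month not in baseline_cache:
                # one max-length control per start month serves every design
                n_max = (windows.initialisation_months + max_span
                         + windows.response_months)
                sim_start = month_add(sc.start_month, -windows.initialisation_months)
                p_base = np.array([site.light_p[month_add(sim_start, t) - 1]
                                   for t in range(n_max)])
                baseline_cache[sc.start_month] = ff.run(
                    healthy_initial_beliefs(schema), sim_start, n_max,
                    _light_drivers(schema, p_base))
            record_file = (out_path / f"{sc.scenario_id}.json") if out_path else None
            if record_file is not None and record_file.exists():
                continue
            try:
                base = baseline_cache.get(sc.start_month)
                result = run_scenario(sc, schema, windows, filter_=ff,
                                      baseline_traj=base)
                baseline_cache[sc.start_month] = result.baseline_traj
            except Exception:  # noqa: BLE001 - study must survive single failures
                logger.exception("scenario %s failed", sc.scenario_id)
                if record_file is not None:
                    record_file.with_suffix(".failed").write_text(sc.scenario_id)
                continue
            results.append(result)
            if record_file is not None:
                record_file.write_text(json.dumps(_result_record(result)))
    return results
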