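"""Resilience criteria, scores and ecological-window tables.

State-probability trajectories are collapsed to a scalar weighted-mean
trajectory μ(t) on the percent-of-reference scale:

    μ'(t) = Σ_j p_j(t)·x̄_j,
    μ(t)  = p₀(t)·𝕀[μ'(t) < α] + (1 − p₀(t))·μ'(t)·𝕀[μ'(t) ≥ α],

where p_j(t) is the posterior probability of state j, x̄_j the state's
median value under a uniform within-interval distribution, p₀(t) the zero
(local extinction) state probability, and α a threshold for being in the
zero state.  The formula is evaluated literally: when μ' drops below α the
trajectory reports the extinction probability itself, deliberately mixing
scales so near-extinct trajectories sit near zero on the percent scale
(α defaults to 1.0, the lower edge of the low interval).

Three criteria compare a stressed run against the month-matched control of
the same site (baselines may be limit points or seasonal limit cycles, so a
scalar baseline would misjudge annual meadows):

* resistance  — <20 % change in μ relative to baseline at the first slice
  after the stress ends;
* recovery    — μ back within 20 % of the month-matched baseline within six
  months of stress removal; losses not recovered within 60 months are
  permanent;
* persistence — mean zero-state probability over the 60-month response
  window at most 1.025 × the baseline's.

Scores: 4 = all three, 3 = resistance+recovery only, 2 = recovery+persistence,
1 = recovery only, 0 = no recovery.  A (design × start month) cell with score
≥ 1 is an ecological window; ≥ 3 is a minimal-impact window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ecowindows.dbn import TrajectoryBeliefs
from ecowindows.scenarios import (
    LIGHT_LEVELS,
    RunResult,
    RunWindows,
    Scenario,
    run_scenario,
)
from ecowindows.seagrass import POPULATION_SCHEME, StateValueGrid, state_value_grid

logger = logging.getLogger(__name__)

PERMANENT = "permanent"


@dataclass(frozen=True)
class WeightedMeanParams:
    """State value grid and zero-state threshold α for the μ(t) trajectory."""

    grid: StateValueGrid = field(default_factory=lambda: state_value_grid(POPULATION_SCHEME))
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class ResilienceCriteriaConfig:
    """Thresholds of the three criteria and the permanence horizon."""

    resistance_threshold: float = 0.20
    recovery_threshold: float = 0.20
    recovery_window_months: int = 6
    persistence_ratio: float = 1.025
    permanence_horizon_months: int = 60
    #: "mean" zero-state aggregation over the response window, or "max" for
    #: the worst instantaneous ratio
    extinction_aggregation: str = "mean"

    def __post_init__(self) -> None:
        for thr in (self.resistance_threshold, self.recovery_threshold):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.recovery_window_months <= 0 or self.permanence_horizon_months <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class CriteriaResult:
    """Outcome of the three criteria for one scenario."""

    resistance: bool
    recovery: bool
    persistence: bool
    score: int
    recovery_time_months: int | str  # integer months or "permanent"
    extinction_ratio: float

    @property
    def is_window(self) -> bool:
        return self.score >= 1

    @property
    def minimal_impact(self) -> bool:
        return self.score >= 3


def weighted_mean_trajectory(state_probs: np.ndarray, state_labels: Sequence[str],
                             params: WeightedMeanParams = WeightedMeanParams()
                             ) -> np.ndarray:
    """Evaluate μ(t) for per-slice probability vectors (rows).

    ``state_labels`` name the columns; a ``zero`` label, if present, supplies
    p₀(t) (otherwise p₀ := 0 and μ = μ').
    """
    probs = np.asarray(state_probs, dtype=float)
    if probs.ndim == 1:
        probs = probs[None, :]
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("state probability vectors must be normalised")
    xbar = np.array([params.grid.medians[s] for s in state_labels])
    mu_prime = probs @ xbar
    if "zero" in state_labels:
        p0 = probs[:, list(state_labels).index("zero")]
    else:
        p0 = np.zeros(len(probs))
    below = mu_prime < params.alpha
    return np.where(below, p0, (1.0 - p0) * mu_prime)


def node_weighted_mean(traj: TrajectoryBeliefs, node: str,
                       params: WeightedMeanParams = WeightedMeanParams()) -> np.ndarray:
    labels = traj.schema.node(node).states.labels
    return weighted_mean_trajectory(traj.marginal_series(node), labels, params)


def _relative_change(baseline: float, response: float, alpha: float) -> float:
    """|response − baseline| / baseline with the zero-baseline convention.

    When the month-matched baseline is zero (annual meadows out of season)
    the change is 0 if the response also sits below α — a response above an
    absent baseline is not a loss, so it, too, counts as no change.
    """
    if baseline > 0:
        return abs(response - baseline) / baseline
    if response >= alpha:
        logger.info("zero baseline with response %.3g >= alpha: treated as no loss",
                    response)
    return 0.0


def assess_resistance(baseline_mu: np.ndarray, response_mu: np.ndarray,
                      stress_end_slice: int,
                      cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
                      alpha: float = 1.0) -> bool:
    """Minimal-loss criterion immediately after the stress.

    Satisfied iff the month-matched relative change of μ at the first slice
    after the last dredging slice is below the resistance threshold.
    """
    t = stress_end_slice + 1
    if t >= len(baseline_mu) or t >= len(response_mu):
        raise IndexError("trajectory does not extend past the stress end")
    rel = _relative_change(float(baseline_mu[t]), float(response_mu[t]), alpha)
    return rel < cfg.resistance_threshold


def assess_recovery(baseline_mu: np.ndarray, response_mu: np.ndarray,
                    stress_end_slice: int,
                    cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
                    alpha: float = 1.0) -> tuple[bool, int | str]:
    """Recovery criterion and recovery time.

    Recovery time is the smallest m ≥ 0 months after stress end at which μ is
    within the recovery threshold of the month-matched baseline; the
    criterion asks m ≤ the six-month window.  If no month up to the
    permanence horizon qualifies, the loss is permanent.
    """
    first = stress_end_slice + 1
    horizon = cfg.permanence_horizon_months
    if first + horizon > len(response_mu):
        raise IndexError(
            f"response extends {len(response_mu) - first} months past the "
            f"stress, need {horizon} to assess permanence"
        )
    for m in range(horizon + 1):
        t = first + m
        if t >= len(response_mu):
            break
        rel = _relative_change(float(baseline_mu[t]), float(response_mu[t]), alpha)
        if rel < cfg.recovery_threshold:
            return m <= cfg.recovery_window_months, m
    return False, PERMANENT


def assess_persistence(baseline_zero_p: np.ndarray, response_zero_p: np.ndarray,
                       stress_end_slice: int,
                       cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig()
                       ) -> tuple[bool, float]:
    """No-additional-extinction-risk criterion.

    The extinction ratio aggregates the zero-state probability over the
    permanence horizon after stress end (mean by default, max optional) and
    divides response by month-matched baseline; 0/0 counts as ratio 1.
    """
    first = stress_end_slice + 1
    last = min(first + cfg.permanence_horizon_months, len(response_zero_p))
    resp = np.asarray(response_zero_p[first:last], dtype=float)
    base = np.asarray(baseline_zero_p[first:last], dtype=float)
    if cfg.extinction_aggregation == "max":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where((base == 0) & (resp == 0), 1.0, resp / base)
        ratio = float(np.max(ratios))
    else:
        b, r = float(base.mean()), float(resp.mean())
        ratio = 1.0 if (b == 0 and r == 0) else (math.inf if b == 0 else r / b)
    return ratio < cfg.persistence_ratio, ratio


def resilience_score(resistance: bool, recovery_criterion: bool,
                     persistence: bool) -> int:
    """Map the three criteria booleans onto the 0–4 score.

    Resistance as defined implies the recovery criterion (a trajectory within
    20 % immediately after the stress has recovery time 0), so resistance
    without recovery is inconsistent input.
    """
    if resistance and not recovery_criterion:
        raise ValueError("inconsistent criteria: resistance implies recovery")
    if not recovery_criterion:
        return 0
    if resistance:
        return 4 if persistence else 3
    return 2 if persistence else 1


def decode_score(score: int) -> tuple[bool, bool, bool]:
    """Inverse of resilience_score over the five admissible combinations."""
    return {
        4: (True, True, True),
        3: (True, True, False),
        2: (False, True, True),
        1: (False, True, False),
        0: (False, False, False),
    }[score]


def assess_run(result: RunResult,
               cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
               params: WeightedMeanParams = WeightedMeanParams(),
               node: str = "realised_shoot_density") -> CriteriaResult:
    """All three criteria and the score for one scenario run."""
    base_mu = node_weighted_mean(result.baseline_traj, node, params)
    resp_mu = node_weighted_mean(result.response_traj, node, params)
    zero = result.response_traj.schema.node(node).states.zero_label
    base_z = result.baseline_traj.state_prob_series(node, zero)
    resp_z = result.response_traj.state_prob_series(node, zero)
    end = result.stress_end_slice

    resistance = assess_resistance(base_mu, resp_mu, end, cfg, params.alpha)
    recovery_ok, rec_time = assess_recovery(base_mu, resp_mu, end, cfg, params.alpha)
    persistence, ratio = assess_persistence(base_z, resp_z, end, cfg)
    score = resilience_score(resistance, recovery_ok, persistence)
    return CriteriaResult(resistance=resistance, recovery=recovery_ok,
                          persistence=persistence, score=score,
                          recovery_time_months=rec_time, extinction_ratio=ratio)


def assess_record(record: Mapping,
                  cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
                  params: WeightedMeanParams = WeightedMeanParams(),
                  node: str = "realised_shoot_density") -> CriteriaResult:
    """Criteria and score from a stored study record (one scenario's JSON)."""
    labels = record["state_labels"][node]
    base = np.asarray(record["baseline"][node], dtype=float)
    resp = np.asarray(record["response"][node], dtype=float)
    base_mu = weighted_mean_trajectory(base, labels, params)
    resp_mu = weighted_mean_trajectory(resp, labels, params)
    zero_idx = labels.index("zero")
    if record["stress_span"] is not None:
        end = record["stress_span"][1]
    else:
        end = record["initialisation_months"] - 1
    resistance = assess_resistance(base_mu, resp_mu, end, cfg, params.alpha)
    recovery_ok, rec_time = assess_recovery(base_mu, resp_mu, end, cfg, params.alpha)
    persistence, ratio = assess_persistence(base[:, zero_idx], resp[:, zero_idx],
                                            end, cfg)
    return CriteriaResult(resistance=resistance, recovery=recovery_ok,
                          persistence=persistence,
                          score=resilience_score(resistance, recovery_ok, persistence),
                          recovery_time_months=rec_time, extinction_ratio=ratio)


# ---------------------------------------------------------------------------
# window tables
# ---------------------------------------------------------------------------

@dataclass
class WindowTable:
    """Per (design, start month) criteria results for one site."""

    site_name: str
    cells: dict[tuple[str, int], CriteriaResult]
    min_light: dict[tuple[str, int], float | str] = field(default_factory=dict)

    def score(self, design: str, start_month: int) -> int:
        return self.cells[(design, start_month)].score

    def is_window(self, design: str, start_month: int) -> bool:
        return self.cells[(design, start_month)].is_window

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (design, month), cr in sorted(self.cells.items()):
            rows.append({
                "site": self.site_name, "design": design, "start_month": month,
                "resistance": cr.resistance, "recovery": cr.recovery,
                "persistence": cr.persistence, "score": cr.score,
                "recovery_time": cr.recovery_time_months,
                "extinction_ratio": cr.extinction_ratio,
                "is_window": cr.is_window,
                "min_light": self.min_light.get((design, month)),
            })
        return pd.DataFrame(rows)


def build_window_table(results: Sequence[RunResult],
                       cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
                       params: WeightedMeanParams = WeightedMeanParams(),
                       designs: Sequence[str] | None = None) -> WindowTable:
    """Score the full (design × start month) grid for one site.

    ``results`` must cover all 12 start months for every non-control design
    present (or those named in ``designs``); missing cells are reported in
    the raised error.
    """
    sites = {r.scenario.site.site_name for r in results}
    if len(sites) != 1:
        raise ValueError(f"results span {len(sites)} sites, expected exactly 1")
    cells: dict[tuple[str, int], CriteriaResult] = {}
    for r in results:
        if r.scenario.design.is_control:
            continue
        cells[(r.scenario.design.label, r.scenario.start_month)] = assess_run(
            r, cfg, params)
    expected_designs = set(designs) if designs is not None else \
        {d for d, _m in cells}
    missing = [(d, m) for d in sorted(expected_designs) for m in range(1, 13)
               if (d, m) not in cells]
    if missing:
        raise ValueError(f"incomplete scenario grid; missing cells: {missing}")
    return WindowTable(site_name=sites.pop(), cells=cells)


def min_light_for_window(site, design, start_month, schema,
                         levels: Sequence[float] = LIGHT_LEVELS,
                         cfg: ResilienceCriteriaConfig = ResilienceCriteriaConfig(),
                         params: WeightedMeanParams = WeightedMeanParams(),
                         windows: RunWindows = RunWindows(),
                         filter_=None, baseline_traj=None) -> float | str:
    """Smallest permitted light level whose scenario scores ≥ 1, else "none".

    Levels are tried in ascending order; "none" means even the least
    restrictive level fails and no light reduction is allowable for that
    (design, start month) cell.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    for level in levels:
        sc = Scenario(site, design, start_month, level)
        result = run_scenario(sc, schema, windows, filter_=filter_,
                              baseline_traj=baseline_traj)
        baseline_traj = result.baseline_traj
        if assess_run(result, cfg, params).score >= 1:
            return level
    return "none"
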