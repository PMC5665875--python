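"""Light calibration, observation conversion, validation MSE, sensitivity.

Monthly above-saturation-light probabilities are estimated from daily
benthic light records with a conjugate beta-binomial model (per calendar
month, pooled across years); population observations are converted to state
probabilities with a Dirichlet-multinomial posterior over the discretised
replicate counts.  Both give the closed-form posterior means and intervals
of the corresponding binomial/multinomial likelihoods, so estimates are
exactly reproducible without a sampler.

Model fit against observation series is summarised as the mean squared
error between predicted and observed state probabilities (over all states,
and over the zero state alone, since avoiding local extinction is the key
management objective).  Variable influence on the simulated responses is
ranked with gradient-boosted regression trees over logit-transformed
posterior state probabilities, including one-step-lagged predictors to
match the transition structure of the DBN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from ecowindows.dbn import TrajectoryBeliefs
from ecowindows.scenarios import RunResult
from ecowindows.seagrass import (
    DiscretizationScheme,
    InputError,
    POPULATION_SCHEME,
    POPULATION_STATES,
    discretize_measurement,
)

logger = logging.getLogger(__name__)

LOGIT_EPS = 1e-6


# ---------------------------------------------------------------------------
# monthly light estimation
# ---------------------------------------------------------------------------

@dataclass
class DailyLightSeries:
    """Daily benthic light records with a saturation threshold.

    ``values`` holds either irradiance (mol photons m⁻² d⁻¹, requires
    ``saturation_threshold`` in the same units) or pre-thresholded binary
    above/below flags (threshold may then be omitted).
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    saturation_threshold: float | None = None
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise InputError("dates and values differ in length")
        if self.dates.has_duplicates:
            raise InputError("daily light series has duplicate dates")
        if np.any(self.values < 0):
            raise InputError("irradiance must be nonnegative")

    @classmethod
    def from_csv(cls, path, saturation_threshold: float | None = None,
                 is_binary: bool = False) -> "DailyLightSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(pd.DatetimeIndex(df["date"]), df["value"].to_numpy(),
                   saturation_threshold, is_binary)

    def above_flags(self) -> np.ndarray:
        if self.is_binary:
            return self.values.astype(bool)
        if self.saturation_threshold is None:
            raise InputError(
                "saturation_threshold required when raw irradiance is supplied"
            )
        return self.values > self.saturation_threshold


@dataclass
class MonthlyLightEstimate:
    """Per-calendar-month posterior for the above-saturation probability."""

    table: pd.DataFrame  # index month 1..12; mean, ci_low, ci_high, n_days, n_above

    @property
    def light_p(self) -> tuple[float, ...]:
        """12 posterior-mean probabilities (NaN for months without data)."""
        return tuple(float(x) for x in self.table["mean"])

    def months_without_data(self) -> list[int]:
        return [int(m) for m, n in self.table["n_days"].items() if n == 0]


def estimate_light_saturation_probability(
    series: DailyLightSeries,
    prior: tuple[float, float] = (1.0, 1.0),
) -> MonthlyLightEstimate:
    """Beta-binomial monthly estimates, pooled across years.

    For month m with ``n`` observed days of which ``k`` were above
    saturation, the posterior is Beta(a+k, b+n−k) for prior Beta(a, b);
    the table reports the posterior mean and equal-tailed 95 % interval.
    Months with no data are flagged with NaN estimates, never interpolated.
    """
    a, b = prior
    if a <= 0 or b <= 0:
        raise InputError("beta prior parameters must be positive")
    flags = series.above_flags()
    months = series.dates.month
    rows = []
    for m in range(1, 13):
        sel = months == m
        n = int(sel.sum())
        k = int(flags[sel].sum())
        if n == 0:
            rows.append((m, np.nan, np.nan, np.nan, 0, 0))
            continue
        post_a, post_b = a + k, b + n - k
        mean = post_a / (post_a + post_b)
        lo, hi = beta_dist.ppf([0.025, 0.975], post_a, post_b)
        rows.append((m, mean, float(lo), float(hi), n, k))
    table = pd.DataFrame(
        rows, columns=["month", "mean", "ci_low", "ci_high", "n_days", "n_above"]
    ).set_index("month")
    return MonthlyLightEstimate(table)


# ---------------------------------------------------------------------------
# observations -> state probabilities
# ---------------------------------------------------------------------------

@dataclass
class ObservationStateSeries:
    """Per-time-point state probability vectors derived from measurements."""

    dates: pd.DatetimeIndex
    probs: np.ndarray  # (n_points, n_states)
    state_labels: tuple[str, ...]
    excluded_dates: tuple = ()


def observations_to_state_probabilities(
    observations: Mapping | pd.DataFrame,
    reference_value: float,
    scheme: DiscretizationScheme = POPULATION_SCHEME,
    state_labels: Sequence[str] = POPULATION_STATES.labels,
) -> ObservationStateSeries:
    """Dirichlet-multinomial state probabilities from replicated measurements.

    ``observations`` is a frame (or dict) with columns date and value, one
    row per replicate.  Each replicate is discretised against the reference
    value; per time point the posterior mean under a flat Dirichlet(1,…,1)
    prior is (count_j + 1)/(n + K).  Time points with no replicates are
    excluded and flagged.
    """
    df = pd.DataFrame(observations)
    if reference_value <= 0:
        raise InputError("reference value must be positive")
    labels = tuple(state_labels)
    k = len(labels)
    dates, rows, excluded = [], [], []
    for date, group in df.groupby("date", sort=True):
        values = group["value"].dropna()
        if len(values) == 0:
            excluded.append(date)
            continue
        counts = np.zeros(k)
        for v in values:
            counts[labels.index(discretize_measurement(v, reference_value, scheme))] += 1
        rows.append((counts + 1.0) / (counts.sum() + k))
        dates.append(date)
    if excluded:
        logger.warning("excluded %d observation time points with no replicates",
                       len(excluded))
    return ObservationStateSeries(
        dates=pd.DatetimeIndex(dates), probs=np.array(rows),
        state_labels=labels, excluded_dates=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# validation MSE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """MSE of predicted state probabilities against observation-derived ones."""

    mse_all_states: float
    mse_zero_state: float
    residuals: pd.DataFrame  # per aligned time point × state


def validation_mse(predicted: TrajectoryBeliefs, observed: ObservationStateSeries,
                   node: str, start_date: pd.Timestamp | str) -> ValidationReport:
    """Align observations to slices at month resolution and compute MSEs.

    ``start_date`` anchors slice 0 in calendar time; an observation falls in
    the slice sharing its year and month.  The zero-state MSE is computed
    over the ``zero`` column only.
    """
    labels = predicted.schema.node(node).states.labels
    if tuple(observed.state_labels) != tuple(labels):
        raise InputError(
            f"observed state labels {observed.state_labels} do not match "
            f"node states {labels}"
        )
    start = pd.Timestamp(start_date)
    series = predicted.marginal_series(node)
    rows = []
    for date, obs in zip(observed.dates, observed.probs):
        offset = (date.year - start.year) * 12 + (date.month - start.month)
        if 0 <= offset < len(predicted):
            rows.append((date, offset, series[offset], obs))
    if not rows:
        raise InputError("no observation time points align with the trajectory")
    res = []
    for date, t, pred, obs in rows:
        for j, lab in enumerate(labels):
            res.append({"date": date, "slice": t, "state": lab,
                        "predicted": pred[j], "observed": obs[j],
                        "residual": pred[j] - obs[j]})
    residuals = pd.DataFrame(res)
    mse_all = float((residuals["residual"] ** 2).mean())
    zero_rows = residuals[residuals["state"] == "zero"]
    mse_zero = float((zero_rows["residual"] ** 2).mean()) if len(zero_rows) else np.nan
    return ValidationReport(mse_all, mse_zero, residuals)


def calibrate_reference_scaling(
    predicted: TrajectoryBeliefs, observations, base_reference: float,
    node: str, start_date,
    scalings: Sequence[float] = (0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
    scheme: DiscretizationScheme = POPULATION_SCHEME,
) -> tuple[float, ValidationReport]:
    """Deterministic grid search over reference-value scaling minimising MSE.

    Replaces a visual calibration step: each candidate scaling rescales the
    reference value used to discretise the observations; the scaling with
    the smallest all-state MSE wins (ties go to the smaller scaling).
    """
    best = None
    labels = predicted.schema.node(node).states.labels
    for sc in scalings:
        obs = observations_to_state_probabilities(
            observations, base_reference * sc, scheme, labels)
        report = validation_mse(predicted, obs, node, start_date)
        if best is None or report.mse_all_states < best[1].mse_all_states:
            best = (sc, report)
    return best


# ---------------------------------------------------------------------------
# boosted-tree sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class InfluenceReport:
    """Normalised relative influence per predictor, per response variable."""

    influences: dict[str, pd.Series]  # response -> weights (sum to 1)
    top_sets: dict[str, tuple[str, ...]]  # top-two-orders-of-magnitude sets
    fit_r2: dict[str, float]
    skipped: tuple[str, ...] = ()


def _logit(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return np.log(q / (1.0 - q))


def sensitivity_influence(
    results: Sequence[RunResult],
    response_nodes: Sequence[str] = ("realised_shoot_density", "realised_biomass"),
    response_states: Sequence[str] = ("high", "moderate", "low", "zero"),
    predictor_nodes: Sequence[str] | None = None,
    seed: int = 0,
    n_estimators: int = 100,
    top_orders: float = 2.0,
) -> InfluenceReport:
    """Rank variable influence with one boosted tree ensemble per response.

    Every (node, state) posterior probability is a time-series variable;
    predictors enter logit-transformed at t and t−1 (the one-step lag of the
    DBN), excluding the response's own node at t.  One gradient-boosted
    regression tree is fitted per response (each state of each response
    node); influence weights are the trees' normalised importances, and the
    most influential set is everything within ``top_orders`` orders of
    magnitude of the maximum weight.  Constant responses are flagged and
    skipped.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    if len(results) < 2:
        raise ValueError("need results from at least 2 scenarios")

    # normalise inputs: RunResult objects or stored study records (dicts)
    def extract(r):
        if isinstance(r, Mapping):
            labels = {n: tuple(ls) for n, ls in r["state_labels"].items()}
            series = {n: np.asarray(r["response"][n], dtype=float) for n in labels}
        else:
            traj = r.response_traj
            schema = traj.schema
            labels = {n.name: n.states.labels for n in schema.nodes
                      if n.role != "site" and n.name in traj.beliefs[0].marginals}
            series = {n: traj.marginal_series(n) for n in labels}
        return labels, series

    labels_by_node, _ = extract(results[0])
    if predictor_nodes is None:
        predictor_nodes = list(labels_by_node)

    # long table: one row per (scenario, slice t >= 1)
    columns: dict[str, list] = {}
    for node in predictor_nodes:
        for state in labels_by_node[node]:
            columns[f"{node}[{state}]"] = []
            columns[f"{node}[{state}]@t-1"] = []
    for r in results:
        _labels, series_by_node = extract(r)
        for node in predictor_nodes:
            series = _logit(series_by_node[node])
            for j, state in enumerate(labels_by_node[node]):
                columns[f"{node}[{state}]"].extend(series[1:, j])
                columns[f"{node}[{state}]@t-1"].extend(series[:-1, j])
    frame = pd.DataFrame(columns)

    influences: dict[str, pd.Series] = {}
    top_sets: dict[str, tuple[str, ...]] = {}
    fit_r2: dict[str, float] = {}
    skipped: list[str] = []
    for node in response_nodes:
        for state in response_states:
            if state not in labels_by_node[node]:
                continue
            response = f"{node}[{state}]"
            y = frame[response].to_numpy()
            if np.ptp(y) < 1e-12:
                skipped.append(response)
                logger.warning("response %s is constant; skipped", response)
                continue
            drop = [c for c in frame.columns
                    if c.startswith(f"{node}[") and not c.endswith("@t-1")]
            X = frame.drop(columns=drop)
            model = GradientBoostingRegressor(
                n_estimators=n_estimators, max_depth=3, random_state=seed)
            model.fit(X.to_numpy(), y)
            weights = pd.Series(model.feature_importances_, index=X.columns)
            total = weights.sum()
            weights = weights / total if total > 0 else weights
            influences[response] = weights.sort_values(ascending=False)
            cutoff = weights.max() / 10.0 ** top_orders
            top_sets[response] = tuple(
                weights[weights >= cutoff].sort_values(ascending=False).index)
            fit_r2[response] = float(model.score(X.to_numpy(), y))
    return InfluenceReport(influences=influences, top_sets=top_sets,
                           fit_r2=fit_r2, skipped=tuple(skipped))
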