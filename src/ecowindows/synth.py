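"""Synthetic archetype CPTs and site light climatologies.

The original model's conditional probability tables were elicited from
expert panels with a nine-label linguistic scale and are not published; this
module generates stand-in bundles for the three seagrass life-history
archetypes with the statistical structure the downstream analysis assumes:

* every table is a valid dense CPT,
* ordinal monotonicity holds as first-order stochastic dominance — better
  light gives stochastically faster growth, faster growth stochastically
  higher net change, sustained light deprivation stochastically lower
  physiological status, and so on for every table, with the sign appropriate
  to the edge (loss *decreases* with light and resistance),
* the archetypes separate behaviourally: colonising meadows crash fast under
  deprivation and recover fast through growth and seed recruitment;
  persistent meadows resist short deprivation through physiological inertia
  but recover slowly; opportunistic meadows sit between the two.

Rows are built from a tempered binomial kernel: a row over K ordered states
with target level θ ∈ [0, 1] is Binomial(K−1, θ) raised to a concentration
power and renormalised.  The kernel is monotone-likelihood-ratio in θ, so
any θ monotone in a parent's ordinal level yields first-order stochastic
dominance in that parent — the property the resilience monotonicity checks
rely on.  These bundles target qualitative behavioural signatures only; no
numerical agreement with the original elicited tables is claimed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom

from ecowindows.dbn import ConditionalTable, StateSpace
from ecowindows.seagrass import (
    LIFE_HISTORIES,
    REFERENCE_TOPOLOGY,
    SEASONAL_NODES,
    SiteConfig,
)

# ---------------------------------------------------------------------------
# linguistic elicitation scale
# ---------------------------------------------------------------------------

LINGUISTIC_LABELS = (
    "certainty", "extremely_likely", "very_likely", "likely", "fifty_fifty",
    "unlikely", "very_unlikely", "extremely_unlikely", "impossible",
)


@dataclass(frozen=True)
class LinguisticScale:
    """Mapping from the nine elicitation labels to probabilities.

    Must be strictly decreasing from certainty (1.0) to impossible (0.0)
    with fifty_fifty at exactly 0.5.  The default is symmetric around 0.5;
    any published elicitation scale can be substituted.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != LINGUISTIC_LABELS:
            raise ValueError(f"scale must define exactly the labels {LINGUISTIC_LABELS}")
        vals = list(self.values.values())
        if any(a <= b for a, b in zip(vals[1:], vals[2:])) or vals[0] <= vals[1]:
            pass  # handled below by the full check
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("scale values must be strictly decreasing")
        if vals[0] != 1.0 or vals[-1] != 0.0:
            raise ValueError("scale must run from certainty=1.0 to impossible=0.0")
        if self.values["fifty_fifty"] != 0.5:
            raise ValueError("fifty_fifty must map to exactly 0.5")

    def __getitem__(self, label: str) -> float:
        return self.values[label]


DEFAULT_SCALE = LinguisticScale(dict(zip(
    LINGUISTIC_LABELS, (1.0, 0.95, 0.85, 0.70, 0.50, 0.30, 0.15, 0.05, 0.0)
)))


# ---------------------------------------------------------------------------
# archetype parameters
# ---------------------------------------------------------------------------

class ArchetypeOrderingError(ValueError):
    """Archetype parameters violate the life-history ordering invariants."""


@dataclass(frozen=True)
class ArchetypeParams:
    """Life-history trait strengths, expressed as linguistic labels."""

    life_history: str
    resistance_strength: str
    growth_rate: str
    seed_production: str
    seed_recruitment: str
    seasonal_amplitude: str
    mortality_under_low_light: str

    def strengths(self, scale: LinguisticScale = DEFAULT_SCALE) -> dict[str, float]:
        return {
            "resistance": scale[self.resistance_strength],
            "growth": scale[self.growth_rate],
            "seed_production": scale[self.seed_production],
            "seed_recruitment": scale[self.seed_recruitment],
            "amplitude": scale[self.seasonal_amplitude],
            "mortality": scale[self.mortality_under_low_light],
        }


ARCHETYPE_DEFAULTS: dict[str, ArchetypeParams] = {
    "colonising": ArchetypeParams(
        life_history="colonising",
        resistance_strength="unlikely",
        growth_rate="extremely_likely",
        seed_production="extremely_likely",
        seed_recruitment="very_likely",
        seasonal_amplitude="very_likely",
        mortality_under_low_light="very_likely",
    ),
    "opportunistic": ArchetypeParams(
        life_history="opportunistic",
        resistance_strength="fifty_fifty",
        growth_rate="likely",
        seed_production="likely",
        seed_recruitment="likely",
        seasonal_amplitude="fifty_fifty",
        mortality_under_low_light="likely",
    ),
    "persistent": ArchetypeParams(
        life_history="persistent",
        resistance_strength="extremely_likely",
        growth_rate="unlikely",
        seed_production="very_unlikely",
        seed_recruitment="very_unlikely",
        seasonal_amplitude="unlikely",
        mortality_under_low_light="fifty_fifty",
    ),
}


def check_archetype_ordering(params: dict[str, ArchetypeParams],
                             scale: LinguisticScale = DEFAULT_SCALE) -> None:
    """Enforce the cross-archetype trait orderings.

    Persistent must have strictly higher resistance and strictly lower
    growth/seed parameters than colonising; opportunistic must be strictly
    intermediate on every axis.
    """
    col = params["colonising"].strengths(scale)
    opp = params["opportunistic"].strengths(scale)
    per = params["persistent"].strengths(scale)
    if not per["resistance"] > col["resistance"]:
        raise ArchetypeOrderingError("persistent resistance must exceed colonising")
    for axis in ("growth", "seed_production", "seed_recruitment"):
        if not per[axis] < col[axis]:
            raise ArchetypeOrderingError(f"persistent {axis} must be below colonising")
    for axis in col:
        lo, hi = sorted((col[axis], per[axis]))
        if not lo < opp[axis] < hi:
            raise ArchetypeOrderingError(
                f"opportunistic {axis} must lie strictly between colonising and persistent"
            )


check_archetype_ordering(ARCHETYPE_DEFAULTS)


# ---------------------------------------------------------------------------
# ordinal row kernel
# ---------------------------------------------------------------------------

def ordinal_row(n_states: int, theta: float, concentration: float = 1.0) -> np.ndarray:
    """Tempered binomial row over ``n_states`` ordered states.

    ``theta`` in [0, 1] is the target level (0 = all mass on the worst state,
    1 = all on the best); ``concentration`` > 1 sharpens the row around the
    target without breaking monotone likelihood ratio in theta.
    """
    theta = float(np.clip(theta, 0.0, 1.0))
    base = binom.pmf(np.arange(n_states), n_states - 1, theta)
    if concentration != 1.0:
        base = base ** concentration
    return base / base.sum()


def elicited_row(n_states: int, label: str,
                 scale: LinguisticScale = DEFAULT_SCALE,
                 concentration: float = 1.0) -> np.ndarray:
    """A row elicited as a single linguistic label for the favoured (top) outcome."""
    return ordinal_row(n_states, scale[label], concentration)


def _level(idx: int, card: int) -> float:
    """Ordinal level of state ``idx`` among ``card`` states, in [0, 1]."""
    return idx / (card - 1)


# ---------------------------------------------------------------------------
# CPT bundle construction
# ---------------------------------------------------------------------------

#: expected dominance direction of each (table, parent) pair; +1 means a
#: higher parent level must stochastically raise the child, -1 lower it.
DOMINANCE_SIGNS: dict[str, dict[str, int]] = {
    "physiological_status": {"physiological_status[t-1]": +1, "light": +1},
    "growth__growing": {"light": +1, "physiological_status": +1,
                        "realised_shoot_density[t-1]": +1},
    "growth__senescent": {"light": +1, "physiological_status": +1,
                          "realised_shoot_density[t-1]": +1},
    "ability_to_resist": {"physiological_status": +1},
    "seed_density__growing": {"seed_density[t-1]": +1, "realised_shoot_density[t-1]": +1},
    "seed_density__senescent": {"seed_density[t-1]": +1, "realised_shoot_density[t-1]": +1},
    "recruitment_from_seeds__growing": {"seed_density": +1, "light": +1},
    "recruitment_from_seeds__senescent": {"seed_density": +1, "light": +1},
    "ability_to_recover": {"growth": +1, "recruitment_from_seeds": +1},
    "loss": {"light": -1, "ability_to_resist": -1},
    "recovery": {"ability_to_recover": +1, "baseline_population": +1},
    "net_change": {"loss": -1, "recovery": +1},
    "baseline_population__growing": {"baseline_population[t-1]": +1},
    "baseline_population__senescent": {"baseline_population[t-1]": +1},
    "realised_shoot_density": {"realised_shoot_density[t-1]": +1, "net_change": +1},
    "realised_biomass": {"realised_shoot_density": +1, "physiological_status": +1},
}


def _parent_states(name: str) -> tuple[str, ...]:
    base = name[:-5] if name.endswith("[t-1]") else name
    return REFERENCE_TOPOLOGY[base][0].labels


def _theta_functions(s: dict[str, float], transitory: bool):
    """Target-level functions per table; inputs are parent ordinal levels."""
    # physiological inertia grows with resistance: persistent plants buffer
    # light deprivation with stored reserves, colonising plants do not
    inertia = 0.25 + 0.55 * s["resistance"]
    senescent_growth = 0.10 if transitory else 1.0
    baseline_gain = 0.55 if transitory else 0.35
    baseline_drop = 0.65 if transitory else 0.02 * s["amplitude"]

    return {
        "physiological_status": (
            lambda p: inertia * p["physiological_status[t-1]"] + (1 - inertia) * p["light"], 3.0),
        # vegetative growth needs surviving shoots: a crashed meadow can only
        # come back through seed recruitment
        "growth__growing": (
            lambda p: s["growth"] * (0.1 + 0.9 * p["realised_shoot_density[t-1]"])
            * (0.2 + 0.8 * p["light"]) * (0.3 + 0.7 * p["physiological_status"]), 2.5),
        "growth__senescent": (
            lambda p: senescent_growth * s["growth"]
            * (0.1 + 0.9 * p["realised_shoot_density[t-1]"])
            * (0.2 + 0.8 * p["light"]) * (0.3 + 0.7 * p["physiological_status"]), 2.5),
        # convex in status: resistance holds while reserves last, then collapses
        "ability_to_resist": (
            lambda p: s["resistance"] * p["physiological_status"] ** 2, 3.0),
        "seed_density__growing": (
            lambda p: max(0.88 * p["seed_density[t-1]"],
                          0.9 * s["seed_production"] * p["realised_shoot_density[t-1]"]), 2.5),
        "seed_density__senescent": (
            (lambda p: 0.9 * p["seed_density[t-1]"]) if transitory else
            (lambda p: max(0.88 * p["seed_density[t-1]"],
                           0.9 * s["seed_production"] * p["realised_shoot_density[t-1]"])), 2.5),
        "recruitment_from_seeds__growing": (
            lambda p: s["seed_recruitment"] * p["seed_density"] * (0.2 + 0.8 * p["light"]), 2.5),
        "recruitment_from_seeds__senescent": (
            lambda p: (0.05 * s["seed_recruitment"]) if transitory else (s["seed_recruitment"])
            * p["seed_density"] * (0.2 + 0.8 * p["light"]), 2.5),
        "ability_to_recover": (
            lambda p: min(1.0, 0.65 * p["growth"] + 0.55 * p["recruitment_from_seeds"]), 2.5),
        "loss": (
            lambda p: s["mortality"] * (1 - 0.85 * p["ability_to_resist"]) * (1 - p["light"]), 2.5),
        "recovery": (
            lambda p: p["ability_to_recover"] * (0.1 + 0.9 * p["baseline_population"]), 2.5),
        "net_change": (
            lambda p: 0.5 + 0.6 * (p["recovery"] - p["loss"]), 5.0),
        "baseline_population__growing": (
            lambda p: p["baseline_population[t-1]"] + baseline_gain, 5.0),
        "baseline_population__senescent": (
            lambda p: p["baseline_population[t-1]"] - baseline_drop, 5.0),
        "realised_shoot_density": (
            lambda p: p["realised_shoot_density[t-1]"] + 0.45 * (2 * p["net_change"] - 1), 5.0),
        "realised_biomass": (
            lambda p: p["realised_shoot_density"] * (0.55 + 0.45 * p["physiological_status"]), 3.0),
    }


def synth_site_archetype_cpts(params: ArchetypeParams,
                              scale: LinguisticScale = DEFAULT_SCALE,
                              seed: int = 0,
                              transitory: bool = False) -> dict[str, ConditionalTable]:
    """Emit the complete CPT bundle for one life-history archetype.

    Deterministic given ``seed``: a small seeded per-table shift of the
    target level emulates elicitation variability between sites without
    breaking any dominance property (a constant shift of θ within a table is
    monotone-preserving).
    """
    if params.life_history not in LIFE_HISTORIES:
        raise ValueError(f"unknown life history {params.life_history!r}")
    s = params.strengths(scale)
    rng = np.random.default_rng(seed)
    thetas = _theta_functions(s, transitory)

    bundle: dict[str, ConditionalTable] = {}
    for tid, (theta_fn, conc) in thetas.items():
        node = tid.split("__")[0]
        states, intra, inter, _role = REFERENCE_TOPOLOGY[node]
        parent_order = tuple(f"{p}[t-1]" for p in inter) + tuple(intra)
        jitter = float(rng.uniform(-0.015, 0.015))
        rows: dict[tuple[str, ...], np.ndarray] = {}
        combos = itertools.product(*[_parent_states(p) for p in parent_order])
        for combo in combos:
            levels = {
                p: _level(_parent_states(p).index(lab), len(_parent_states(p)))
                for p, lab in zip(parent_order, combo)
            }
            theta = theta_fn(levels) + jitter
            rows[combo] = ordinal_row(len(states), theta, conc)
        bundle[tid] = ConditionalTable(node, parent_order, rows)
    check_bundle_dominance(bundle)
    return bundle


def stochastically_dominates(a: np.ndarray, b: np.ndarray, tol: float = 1e-12) -> bool:
    """First-order stochastic dominance of ``a`` over ``b`` (states ordered worst→best)."""
    return bool(np.all(np.cumsum(a) <= np.cumsum(b) + tol))


def check_bundle_dominance(bundle: dict[str, ConditionalTable]) -> None:
    """Verify the declared dominance direction for every table and parent.

    Raises AssertionError naming the first offending (table, parent, context).
    """
    for tid, table in bundle.items():
        signs = DOMINANCE_SIGNS[tid]
        for ip, parent in enumerate(table.parent_order):
            sign = signs[parent]
            labels = _parent_states(parent)
            others = [list(_parent_states(p)) for p in table.parent_order]
            others[ip] = [None]
            for ctx in itertools.product(*others):
                rows = []
                for lab in labels:
                    key = tuple(lab if i == ip else c for i, c in enumerate(ctx))
                    rows.append(table.rows[key])
                for lo, hi in zip(rows, rows[1:]):
                    better, worse = (hi, lo) if sign > 0 else (lo, hi)
                    if not stochastically_dominates(better, worse):
                        raise AssertionError(
                            f"table {tid!r}: dominance violated for parent "
                            f"{parent!r} in context {ctx}"
                        )


# ---------------------------------------------------------------------------
# light climatologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightClimatologyParams:
    """Seasonal above-saturation-light climate for a synthetic site.

    ``annual_mean`` and ``seasonal_amplitude`` define a sinusoidal monthly
    mean peaking at ``peak_month``; ``noise_concentration`` is the beta
    concentration of monthly noise around that mean (None = deterministic);
    ``days_per_month`` sets the basis for emitted daily series.
    """

    annual_mean: float = 0.7
    seasonal_amplitude: float = 0.2
    peak_month: int = 1
    noise_concentration: float | None = None
    days_per_month: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_mean <= 1.0:
            raise ValueError("annual_mean must lie in [0, 1]")
        if not 1 <= self.peak_month <= 12:
            raise ValueError("peak_month must be in 1..12")


def synth_light_climatology(params: LightClimatologyParams, seed: int = 0,
                            emit_daily_years: int = 0
                            ) -> tuple[tuple[float, ...], np.ndarray | None]:
    """Monthly above-saturation-light probabilities, optionally a daily series.

    Returns 12 probabilities (January first) and, if ``emit_daily_years`` > 0,
    a binary array of shape (years*12*days_per_month,) of above/below flags
    drawn day-by-day from the monthly probabilities (for testing the
    beta-binomial calibration path).
    """
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    mean = params.annual_mean + params.seasonal_amplitude * np.cos(
        2 * np.pi * (months - params.peak_month) / 12.0
    )
    mean = np.clip(mean, 0.0, 1.0)
    if params.noise_concentration:
        kappa = params.noise_concentration
        m = np.clip(mean, 0.02, 0.98)
        p = rng.beta(m * kappa, (1 - m) * kappa)
    else:
        p = mean
    p = tuple(float(x) for x in np.clip(p, 0.0, 1.0))

    daily = None
    if emit_daily_years > 0:
        flags = []
        for _year in range(emit_daily_years):
            for k in range(12):
                flags.append(rng.random(params.days_per_month) < p[k])
        daily = np.concatenate(flags).astype(int)
    return p, daily


# ---------------------------------------------------------------------------
# study fixture
# ---------------------------------------------------------------------------

#: (life_history, meadow_type, latitude, climate, tidal, genus) templates that
#: the study fixture cycles through; spans both hemispheres, all three life
#: histories and both meadow types, mirroring the global site selection
_SITE_TEMPLATES = (
    ("persistent", "enduring", -30.3, "temperate", "subtidal", "Amphibolis"),
    ("colonising", "transitory", -21.3, "tropical", "subtidal", "Halophila"),
    ("opportunistic", "enduring", 47.6, "temperate", "subtidal", "Zostera"),
    ("colonising", "enduring", -27.5, "tropical", "intertidal", "Halophila"),
    ("opportunistic", "enduring", 64.2, "temperate", "intertidal", "Zostera"),
    ("persistent", "enduring", -32.0, "temperate", "subtidal", "Posidonia"),
    ("opportunistic", "enduring", 26.1, "tropical", "subtidal", "Halodule"),
    ("colonising", "transitory", -17.9, "tropical", "subtidal", "Halophila"),
)


def make_study_fixture(n_sites: int = 28, seed: int = 0) -> list[SiteConfig]:
    """Generate the synthetic global site set for full-grid studies.

    Default 28 sites, matching the scale of the original global study; sites
    cycle through templates spanning hemispheres, life histories and meadow
    types, each with its own seeded seasonal light climatology.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    sites: list[SiteConfig] = []
    for i in range(n_sites):
        life, meadow, lat0, climate, tidal, genus = _SITE_TEMPLATES[i % len(_SITE_TEMPLATES)]
        lat = lat0 + float(rng.uniform(-3, 3))
        peak = 1 if lat < 0 else 7
        mean = 0.55 if meadow == "transitory" else 0.8 - 0.25 * abs(lat) / 70.0
        amp = 0.1 + 0.25 * abs(lat) / 70.0
        light_p, _ = synth_light_climatology(
            LightClimatologyParams(annual_mean=mean, seasonal_amplitude=amp,
                                   peak_month=peak, noise_concentration=80.0),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sites.append(SiteConfig(
            site_name=f"site{i:02d}_{life}_{meadow}",
            latitude=round(lat, 2),
            climate=climate,
            tidal=tidal,
            meadow_type=meadow,
            life_history=life,
            light_p=light_p,
            genus_label=genus,
        ))
    return sites


def canonical_site(life_history: str, meadow_type: str = "enduring") -> SiteConfig:
    """The shipped per-archetype fixture site: temperate, southern, subtidal.

    Light climate is a deterministic sinusoid (mean 0.75, amplitude 0.15,
    Austral summer peak), so archetype comparisons are not confounded by
    climatology noise.
    """
    light_p, _ = synth_light_climatology(LightClimatologyParams(
        annual_mean=0.55 if meadow_type == "transitory" else 0.85,
        seasonal_amplitude=0.25 if meadow_type == "transitory" else 0.07,
        peak_month=1, noise_concentration=None,
    ))
    return SiteConfig(
        site_name=f"{life_history}_{meadow_type}_reference",
        latitude=-27.0,
        climate="temperate",
        tidal="subtidal",
        meadow_type=meadow_type,
        life_history=life_history,
        light_p=light_p,
        genus_label={"colonising": "Halophila", "opportunistic": "Zostera",
                     "persistent": "Amphibolis"}[life_history],
    )


def canonical_bundle(life_history: str, meadow_type: str = "enduring",
                     seed: int = 0) -> dict[str, ConditionalTable]:
    """CPT bundle for the shipped fixture of one life history."""
    return synth_site_archetype_cpts(
        ARCHETYPE_DEFAULTS[life_history],
        seed=seed,
        transitory=(meadow_type == "transitory"),
    )
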