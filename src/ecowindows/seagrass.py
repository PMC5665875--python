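"""Seagrass reference network, discretization schemes and site configuration.

Population metrics (shoot density in shoots m⁻², biomass in g dry matter m⁻²)
are discretised into ordinal states as a percentage of a site reference
value: high/moderate/low/zero at (80,100] / (20,80] / (0,20] / 0 %.
Loss and recovery magnitudes use the elicited scheme (30,100] / (10,30] /
(0,10] / 0 %.  Each nonzero state carries a five-point quantile grid under a
uniform within-interval distribution; the grid median is the state value used
by the weighted-mean trajectory.

The reference network is a ~15-node reduction of the full elicited model: it
keeps every factor the analysis tracks (light, baseline and realised
population, net change, loss, recovery, growth, physiological status, seed
density, recruitment from seeds, ability to resist / recover) and folds site
descriptors (climate, tidal exposure, meadow type) into root metadata nodes.
Burial, sediment-quality and connectivity branches are extension points of
the schema format, not part of the shipped topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ecowindows.dbn import (
    ConditionalTable,
    NetworkSchema,
    NodeSpec,
    RegimeRule,
    RegimeSelector,
    StateSpace,
    validate_schema,
)

# ordinal state spaces, ordered worst -> best so that index == ordinal level
POPULATION_STATES = StateSpace(("zero", "low", "moderate", "high"), zero_label="zero")
LOSS_RECOVERY_STATES = StateSpace(("zero", "low", "moderate", "high"), zero_label="zero")
LIGHT_STATES = StateSpace(("below_saturation", "above_saturation"))

LIFE_HISTORIES = ("colonising", "opportunistic", "persistent")
MEADOW_TYPES = ("enduring", "transitory")
CLIMATES = ("tropical", "temperate")
TIDAL = ("subtidal", "intertidal")


class InputError(ValueError):
    """Invalid measurement or configuration input."""


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationScheme:
    """Half-open percentage intervals (lower, upper] mapping to states.

    ``intervals`` maps each nonzero state to its (exclusive lower, inclusive
    upper] bound on the percent-of-reference scale; the ``zero`` state is
    exactly 0 %.
    """

    kind: str
    intervals: dict[str, tuple[float, float]]

    def classify(self, percent: float) -> str:
        if percent == 0.0:
            return "zero"
        for state, (lo, hi) in self.intervals.items():
            if lo < percent <= hi:
                return state
        raise InputError(f"percentage {percent} outside (0, 100]")


POPULATION_SCHEME = DiscretizationScheme(
    "population", {"low": (0.0, 20.0), "moderate": (20.0, 80.0), "high": (80.0, 100.0)}
)
LOSS_RECOVERY_SCHEME = DiscretizationScheme(
    "loss_recovery", {"low": (0.0, 10.0), "moderate": (10.0, 30.0), "high": (30.0, 100.0)}
)


def discretize_measurement(value: float, reference: float,
                           scheme: DiscretizationScheme = POPULATION_SCHEME) -> str:
    """Classify a measurement as a percentage of the site reference value.

    Percentages above 100 are clamped to 100 (a meadow denser than its
    reference site is simply ``high``).
    """
    if reference <= 0:
        raise InputError(f"reference value must be positive, got {reference}")
    if value < 0:
        raise InputError(f"measurement must be nonnegative, got {value}")
    percent = min(100.0 * value / reference, 100.0)
    return scheme.classify(percent)


@dataclass(frozen=True)
class StateValueGrid:
    """Per-state five-point quantile grids and medians on the percent scale."""

    scheme: DiscretizationScheme
    grids: dict[str, tuple[int, ...]]
    medians: dict[str, float]

    def median_values(self, states: StateSpace) -> np.ndarray:
        return np.array([self.medians[s] for s in states.labels])


def state_value_grid(scheme: DiscretizationScheme = POPULATION_SCHEME) -> StateValueGrid:
    """Five-point quantile grid per state under a uniform distribution.

    For a state with integer-labelled interval ``lo..hi`` (``lo`` = exclusive
    lower bound + 1) the grid is {lo, ⌈lo+w/4⌉, ⌈lo+w/2⌉, ⌈lo+3w/4⌉, hi} with
    ``w = hi − lo``; the state value is the grid median (equal to the mean for
    a uniform distribution).  The high population state (81..100) yields
    {81, 86, 91, 96, 100} with median 91.  The zero state has value 0.
    """
    grids: dict[str, tuple[int, ...]] = {"zero": (0, 0, 0, 0, 0)}
    medians: dict[str, float] = {"zero": 0.0}
    for state, (lo_excl, hi) in scheme.intervals.items():
        lo = int(lo_excl) + 1
        w = int(hi) - lo
        grid = (lo,
                lo + math.ceil(w / 4),
                lo + math.ceil(w / 2),
                lo + math.ceil(3 * w / 4),
                int(hi))
        grids[state] = grid
        medians[state] = float(grid[2])
    return StateValueGrid(scheme=scheme, grids=grids, medians=medians)


# ---------------------------------------------------------------------------
# site configuration
# ---------------------------------------------------------------------------

@dataclass
class SiteConfig:
    """A study site: life history, local conditions, monthly light climate.

    ``light_p`` holds the probability of above-saturation benthic light for
    each calendar month (January first); ``reference_value`` is the
    population reference in shoots m⁻² or g DM m⁻² (metadata only — the
    network itself works on the percent-of-reference scale).
    """

    site_name: str
    latitude: float
    climate: str
    tidal: str
    meadow_type: str
    life_history: str
    light_p: tuple[float, ...]
    genus_label: str = ""
    reference_value: float = 100.0
    reference_units: str = "shoots per m2"

    def __post_init__(self) -> None:
        self.light_p = tuple(float(p) for p in self.light_p)
        if len(self.light_p) != 12:
            raise InputError("light_p needs 12 monthly probabilities")
        if any(not 0.0 <= p <= 1.0 for p in self.light_p):
            raise InputError("light probabilities must lie in [0, 1]")
        if self.life_history not in LIFE_HISTORIES:
            raise InputError(f"life_history must be one of {LIFE_HISTORIES}")
        if self.meadow_type not in MEADOW_TYPES:
            raise InputError(f"meadow_type must be one of {MEADOW_TYPES}")
        if self.climate not in CLIMATES:
            raise InputError(f"climate must be one of {CLIMATES}")
        if self.tidal not in TIDAL:
            raise InputError(f"tidal must be one of {TIDAL}")

    @property
    def hemisphere(self) -> str:
        return "south" if self.latitude < 0 else "north"

    def growing_months(self) -> frozenset[int]:
        """Months of the main growth/reproduction season for this site.

        Austral growing season October–March for southern sites; boreal
        April–September for northern sites.
        """
        if self.hemisphere == "south":
            return frozenset({10, 11, 12, 1, 2, 3})
        return frozenset({4, 5, 6, 7, 8, 9})


# ---------------------------------------------------------------------------
# reference network
# ---------------------------------------------------------------------------

#: 3-level ordinal spaces for process nodes (worst -> best)
STATUS_STATES = StateSpace(("low", "moderate", "high"))
GROWTH_STATES = StateSpace(("slow", "moderate", "fast"))
ABILITY_STATES = StateSpace(("low", "moderate", "high"))
SEED_STATES = StateSpace(("zero", "low", "high"), zero_label="zero")
RECRUIT_STATES = StateSpace(("none", "low", "high"))
NET_CHANGE_STATES = StateSpace(("decline", "stable", "increase"))

#: node name -> (states, intra parents, inter parents, role)
REFERENCE_TOPOLOGY: dict[str, tuple[StateSpace, tuple[str, ...], tuple[str, ...], str]] = {
    "light": (LIGHT_STATES, (), (), "environment"),
    "climate": (StateSpace(CLIMATES), (), (), "site"),
    "tidal": (StateSpace(TIDAL), (), (), "site"),
    "meadow_type": (StateSpace(MEADOW_TYPES), (), (), "site"),
    "physiological_status": (STATUS_STATES, ("light",), ("physiological_status",), "process"),
    "growth": (GROWTH_STATES, ("light", "physiological_status"),
               ("realised_shoot_density",), "process"),
    "ability_to_resist": (ABILITY_STATES, ("physiological_status",), (), "process"),
    "seed_density": (SEED_STATES, (), ("seed_density", "realised_shoot_density"), "population"),
    "recruitment_from_seeds": (RECRUIT_STATES, ("seed_density", "light"), (), "process"),
    "ability_to_recover": (ABILITY_STATES, ("growth", "recruitment_from_seeds"), (), "process"),
    "loss": (LOSS_RECOVERY_STATES, ("light", "ability_to_resist"), (), "process"),
    "recovery": (LOSS_RECOVERY_STATES, ("ability_to_recover", "baseline_population"), (), "process"),
    "net_change": (NET_CHANGE_STATES, ("loss", "recovery"), (), "process"),
    "baseline_population": (POPULATION_STATES, (), ("baseline_population",), "population"),
    "realised_shoot_density": (POPULATION_STATES, ("net_change",), ("realised_shoot_density",), "output"),
    "realised_biomass": (POPULATION_STATES, ("realised_shoot_density", "physiological_status"), (), "output"),
}

#: nodes whose regime selector switches between growing/senescent season tables
SEASONAL_NODES = ("growth", "seed_density", "recruitment_from_seeds", "baseline_population")

#: nodes whose per-slice marginals scenario runs persist
TRACKED_NODES = (
    "realised_shoot_density", "realised_biomass", "baseline_population",
    "net_change", "loss", "recovery", "growth", "physiological_status",
    "seed_density", "recruitment_from_seeds", "ability_to_resist",
    "ability_to_recover",
)


class MissingTableError(KeyError):
    """A CPT bundle lacks a table the reference topology names."""


def reference_nodes() -> list[NodeSpec]:
    return [
        NodeSpec(name, states, intra, inter, role)
        for name, (states, intra, inter, role) in REFERENCE_TOPOLOGY.items()
    ]


def build_reference_network(site: SiteConfig,
                            archetype_tables: dict[str, ConditionalTable]) -> NetworkSchema:
    """Assemble and validate the site's network from an archetype CPT bundle.

    The bundle must contain one table per non-seasonal node (id = node name)
    and ``<node>__growing`` / ``<node>__senescent`` variants for the seasonal
    nodes; the site's hemisphere decides which calendar months select the
    growing-season table.  Site descriptor nodes get point-mass priors from
    the SiteConfig.
    """
    nodes = reference_nodes()
    tables: dict[str, ConditionalTable] = {}
    selectors: dict[str, RegimeSelector] = {}

    for name, (states, intra, inter, role) in REFERENCE_TOPOLOGY.items():
        if role == "environment":
            continue
        if role == "site":
            value = {"climate": site.climate, "tidal": site.tidal,
                     "meadow_type": site.meadow_type}[name]
            row = np.zeros(len(states))
            row[states.index(value)] = 1.0
            tables[name] = ConditionalTable(name, (), {(): row})
            selectors[name] = RegimeSelector(default=name)
            continue
        if name in SEASONAL_NODES:
            for season in ("growing", "senescent"):
                tid = f"{name}__{season}"
                if tid not in archetype_tables:
                    raise MissingTableError(
                        f"bundle is missing table {tid!r} for node {name!r}"
                    )
                tables[tid] = archetype_tables[tid]
            selectors[name] = RegimeSelector(
                rules=(RegimeRule(table=f"{name}__growing",
                                  months=site.growing_months()),),
                default=f"{name}__senescent",
            )
        else:
            if name not in archetype_tables:
                raise MissingTableError(
                    f"bundle is missing table {name!r} for node {name!r}"
                )
            tables[name] = archetype_tables[name]
            selectors[name] = RegimeSelector(default=name)

    schema = NetworkSchema(nodes=nodes, tables=tables, selectors=selectors,
                           name=f"seagrass:{site.site_name}")
    diags = validate_schema(schema)
    if diags:
        raise ValueError(
            "reference network failed validation: " + "; ".join(diags)
        )
    return schema


def healthy_initial_beliefs(schema: NetworkSchema) -> dict[str, np.ndarray]:
    """Initial interface beliefs for an established meadow entering slice 0.

    Population at the reference level, physiological status high, a modest
    seed bank.  The initialisation period then settles the system onto its
    site-specific baseline pattern before any stress is applied.
    """
    init: dict[str, np.ndarray] = {}
    for name in schema.interface:
        states = schema.node(name).states
        vec = np.zeros(len(states))
        if "high" in states.labels:
            vec[states.index("high")] = 1.0
        else:
            vec[-1] = 1.0
        init[name] = vec
    return init
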