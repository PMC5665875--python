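"""Discrete-state, monthly-slice, non-homogeneous dynamic Bayesian networks.

A network is a set of named nodes, each with an ordered categorical state
space, parents within the same time slice (``intra_parents``) and parents in
the previous slice (``inter_parents``).  Conditional probability tables (CPTs)
may change with the calendar month, the slice index, or an externally supplied
regime label — this is what makes the DBN *non-homogeneous*: mortality-driven
transitions towards a zero (local extinction) state and recovery-driven
transitions away from it can both be expressed, each active under its own
regime.

Inference is exact forward filtering over the *interface* set (the nodes that
feed the next slice through some ``inter_parents`` list).  The joint over the
interface is propagated slice by slice with a sum-product sweep over the
within-slice factor graph; no sampling and no projection/approximation is
performed.  A brute-force enumerator over the full per-slice joint serves as
an independent oracle for testing.

Time slices are calendar months.  Months are numbered 1..12 (12 = December)
and advance cyclically from the ``start_month`` of slice 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PROB_TOL = 1e-9
#: renormalisation drift beyond this is logged (see forward_infer)
RENORM_WARN = 1e-6
#: hard cap on the interface joint size; exceeding it raises ResourceCapError
DEFAULT_INTERFACE_CAP = 100_000
#: cap for the brute-force oracle: (per-slice joint)^2 * n_slices
DEFAULT_BRUTE_FORCE_CAP = 10_000_000

ROLES = ("environment", "site", "population", "process", "output")


class SchemaError(ValueError):
    """A network schema violates a structural invariant."""


class ResourceCapError(RuntimeError):
    """Exact inference would exceed the configured state-count cap."""


def month_add(month: int, k: int) -> int:
    """Advance a calendar month (1..12) by ``k`` months, cyclically."""
    return (month - 1 + k) % 12 + 1


# ---------------------------------------------------------------------------
# schema types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """Ordered categorical state space of one node.

    ``zero_label`` optionally designates the absorbing-risk category (local
    extinction for population nodes).
    """

    labels: tuple[str, ...]
    zero_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))

    def check(self) -> list[str]:
        problems = []
        if len(self.labels) < 2:
            problems.append("state space needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            problems.append(f"duplicate state labels: {self.labels}")
        if self.zero_label is not None and self.zero_label not in self.labels:
            problems.append(
                f"zero_label {self.zero_label!r} not among labels {self.labels}"
            )
        return problems

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class NodeSpec:
    """One node: name, states, within- and cross-slice parents, role tag."""

    name: str
    states: StateSpace
    intra_parents: tuple[str, ...] = ()
    inter_parents: tuple[str, ...] = ()
    role: str = "process"

    def __post_init__(self) -> None:
        object.__setattr__(self, "intra_parents", tuple(self.intra_parents))
        object.__setattr__(self, "inter_parents", tuple(self.inter_parents))


@dataclass
class ConditionalTable:
    """Dense CPT: one probability row per full parent-state combination.

    ``parent_order`` lists parents as ``name`` (same slice) or ``name[t-1]``
    (previous slice); ``rows`` maps tuples of parent state labels, in that
    order, to probability vectors over the child's states.
    """

    child: str
    parent_order: tuple[str, ...]
    rows: dict[tuple[str, ...], np.ndarray]

    def __post_init__(self) -> None:
        self.parent_order = tuple(self.parent_order)
        self.rows = {
            tuple(k): np.asarray(v, dtype=float) for k, v in self.rows.items()
        }


@dataclass(frozen=True)
class RegimeRule:
    """One selector rule; the first matching rule wins.

    Empty criteria match anything, so a rule with only ``months`` set selects
    purely on calendar month (the usual seasonal-regime case).
    """

    table: str
    months: frozenset[int] | None = None
    slices: tuple[int, int] | None = None  # inclusive (first, last)
    regime: str | None = None

    def matches(self, slice_index: int, month: int, regime: str | None) -> bool:
        if self.months is not None and month not in self.months:
            return False
        if self.slices is not None and not (
            self.slices[0] <= slice_index <= self.slices[1]
        ):
            return False
        if self.regime is not None and self.regime != regime:
            return False
        return True


@dataclass
class RegimeSelector:
    """Ordered rules mapping (slice, month, regime label) to a CPT id."""

    rules: tuple[RegimeRule, ...] = ()
    default: str | None = None

    def resolve(self, slice_index: int, month: int, regime: str | None = None) -> str:
        for rule in self.rules:
            if rule.matches(slice_index, month, regime):
                return rule.table
        if self.default is None:
            raise SchemaError(
                f"no selector rule matches slice={slice_index} month={month} "
                f"regime={regime!r} and no default table is set"
            )
        return self.default

    def table_ids(self) -> list[str]:
        ids = [r.table for r in self.rules]
        if self.default is not None:
            ids.append(self.default)
        return ids


@dataclass
class NetworkSchema:
    """Complete network: nodes, named CPTs, and per-node regime selectors.

    Environment-role nodes take their per-slice distribution from the driver
    input instead of a CPT, so they appear in ``selectors`` only if they are
    not driver-fed.
    """

    nodes: list[NodeSpec]
    tables: dict[str, ConditionalTable]
    selectors: dict[str, RegimeSelector]
    name: str = "network"

    def __post_init__(self) -> None:
        self._by_name = {n.name: n for n in self.nodes}

    def node(self, name: str) -> NodeSpec:
        return self._by_name[name]

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def environment_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "environment"]

    @property
    def interface(self) -> list[str]:
        """Nodes with cross-slice children, in node order."""
        used: set[str] = set()
        for n in self.nodes:
            used.update(n.inter_parents)
        return [n.name for n in self.nodes if n.name in used]

    def interface_joint_size(self) -> int:
        return int(np.prod([len(self.node(n).states) for n in self.interface] or [1]))

    def topological_order(self) -> list[str]:
        """Within-slice topological order over intra-slice edges."""
        order: list[str] = []
        temp: set[str] = set()
        done: set[str] = set()

        def visit(name: str) -> None:
            if name in done:
                return
            if name in temp:
                raise SchemaError(f"intra-slice cycle through node {name!r}")
            temp.add(name)
            for p in self._by_name[name].intra_parents:
                if p in self._by_name:
                    visit(p)
            temp.discard(name)
            done.add(name)
            order.append(name)

        for n in self.nodes:
            visit(n.name)
        return order


@dataclass
class BeliefState:
    """Posterior marginals (and interface joint) for one time slice."""

    slice_index: int
    calendar_month: int
    marginals: dict[str, np.ndarray]
    interface_nodes: tuple[str, ...]
    interface_joint: np.ndarray  # one axis per interface node, in order


@dataclass
class TrajectoryBeliefs:
    """A sequence of BeliefStates, one per slice, slice 0 first."""

    beliefs: list[BeliefState]
    schema: NetworkSchema

    def __len__(self) -> int:
        return len(self.beliefs)

    def __getitem__(self, i: int) -> BeliefState:
        return self.beliefs[i]

    def marginal_series(self, node: str) -> np.ndarray:
        """(n_slices, n_states) array of the node's posterior marginals."""
        return np.stack([b.marginals[node] for b in self.beliefs])

    def state_prob_series(self, node: str, state: str) -> np.ndarray:
        idx = self.schema.node(node).states.index(state)
        return self.marginal_series(node)[:, idx]

    @property
    def months(self) -> list[int]:
        return [b.calendar_month for b in self.beliefs]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _parent_key(name: str) -> tuple[str, bool]:
    """Split ``name`` / ``name[t-1]`` into (node, is_previous_slice)."""
    if name.endswith("[t-1]"):
        return name[:-5], True
    return name, False


def validate_schema(schema: NetworkSchema) -> list[str]:
    """Check every structural invariant; return one diagnostic per violation.

    Returns an empty list iff the schema is well formed.  Never raises: this
    is the configuration-checking surface, and a config with five problems
    should report all five.
    """
    diags: list[str] = []
    names = set()
    for node in schema.nodes:
        if node.name in names:
            diags.append(f"node {node.name!r}: duplicate node name")
        names.add(node.name)
        for p in node.states.check():
            diags.append(f"node {node.name!r}: {p}")
        if node.role not in ROLES:
            diags.append(f"node {node.name!r}: unknown role {node.role!r}")
        if node.name in node.intra_parents:
            diags.append(f"node {node.name!r}: self-parent within a slice")
        for p in node.intra_parents + node.inter_parents:
            if p not in {n.name for n in schema.nodes}:
                diags.append(f"node {node.name!r}: unknown parent {p!r}")

    try:
        schema.topological_order()
    except SchemaError as e:
        diags.append(str(e))

    env = set(schema.environment_nodes)
    for node in schema.nodes:
        if node.role == "environment" and (node.intra_parents or node.inter_parents):
            diags.append(f"node {node.name!r}: environment nodes cannot have parents")
        for p in node.inter_parents:
            if p in env:
                diags.append(
                    f"node {node.name!r}: environment node {p!r} cannot be a "
                    "cross-slice parent (drivers are per-slice)"
                )

    # every non-environment node needs a selector whose tables all exist
    for node in schema.nodes:
        if node.name in env:
            continue
        sel = schema.selectors.get(node.name)
        if sel is None:
            diags.append(f"node {node.name!r}: no regime selector")
            continue
        for tid in sel.table_ids():
            if tid not in schema.tables:
                diags.append(f"node {node.name!r}: selector references missing table {tid!r}")

    for tid, table in schema.tables.items():
        diags.extend(_validate_table(schema, tid, table))
    return diags


def _validate_table(schema: NetworkSchema, tid: str, table: ConditionalTable) -> list[str]:
    diags: list[str] = []
    if table.child not in {n.name for n in schema.nodes}:
        return [f"table {tid!r}: unknown child {table.child!r}"]
    child = schema.node(table.child)

    declared = [f"{p}[t-1]" for p in child.inter_parents] + list(child.intra_parents)
    if sorted(table.parent_order) != sorted(declared):
        diags.append(
            f"table {tid!r}: parent_order {list(table.parent_order)} does not match "
            f"declared parents {declared} of node {table.child!r}"
        )
        return diags

    parent_states = []
    for p in table.parent_order:
        base, _ = _parent_key(p)
        parent_states.append(schema.node(base).states.labels)
    expected = set(itertools.product(*parent_states)) if parent_states else {()}

    seen = set(table.rows)
    for combo in sorted(expected - seen):
        diags.append(f"table {tid!r}: missing row for parent combination {combo}")
    for combo in sorted(seen - expected):
        diags.append(f"table {tid!r}: unexpected parent combination {combo}")

    k = len(child.states)
    for combo, row in table.rows.items():
        if combo not in expected:
            continue
        if row.shape != (k,):
            diags.append(
                f"table {tid!r} row {combo}: has {row.shape[0]} entries, child has {k} states"
            )
            continue
        if np.any(row < -PROB_TOL) or np.any(row > 1 + PROB_TOL):
            diags.append(f"table {tid!r} row {combo}: entries outside [0, 1]")
        if abs(float(row.sum()) - 1.0) > PROB_TOL:
            diags.append(f"table {tid!r} row {combo}: sums to {row.sum():.6g}, not 1")
    return diags


def table_array(schema: NetworkSchema, table: ConditionalTable) -> np.ndarray:
    """CPT as a dense array, axes = parents in parent_order, then the child."""
    child = schema.node(table.child)
    shape = []
    parent_labels = []
    for p in table.parent_order:
        base, _ = _parent_key(p)
        labels = schema.node(base).states.labels
        parent_labels.append(labels)
        shape.append(len(labels))
    shape.append(len(child.states))
    arr = np.empty(shape, dtype=float)
    for combo in itertools.product(*parent_labels) if parent_labels else [()]:
        idx = tuple(labels.index(s) for labels, s in zip(parent_labels, combo))
        arr[idx] = table.rows[tuple(combo)]
    return arr


# ---------------------------------------------------------------------------
# drivers and initial beliefs
# ---------------------------------------------------------------------------

def _as_distribution(value, states: StateSpace) -> np.ndarray:
    """Coerce a driver entry (state label or distribution) to a prob vector."""
    if isinstance(value, str):
        vec = np.zeros(len(states))
        vec[states.index(value)] = 1.0
        return vec
    if isinstance(value, Mapping):
        vec = np.zeros(len(states))
        for label, p in value.items():
            vec[states.index(label)] = float(p)
    else:
        vec = np.asarray(value, dtype=float)
    if vec.shape != (len(states),):
        raise ValueError(f"driver distribution has wrong length for states {states.labels}")
    if abs(float(vec.sum()) - 1.0) > 1e-6 or np.any(vec < 0):
        raise ValueError("driver distribution must be a probability vector")
    return vec / vec.sum()


def _initial_joint(schema: NetworkSchema, initial) -> np.ndarray:
    """Joint over interface nodes from a joint array or per-node marginals."""
    iface = schema.interface
    shape = tuple(len(schema.node(n).states) for n in iface)
    if isinstance(initial, Mapping):
        joint = np.ones(shape if shape else ())
        for axis, n in enumerate(iface):
            if n not in initial:
                raise ValueError(f"initial beliefs missing interface node {n!r}")
            vec = _as_distribution(initial[n], schema.node(n).states)
            idx = [None] * len(iface)
            idx[axis] = slice(None)
            joint = joint * vec[tuple(idx)]
    else:
        joint = np.asarray(initial, dtype=float)
        if joint.shape != shape:
            raise ValueError(f"initial joint has shape {joint.shape}, expected {shape}")
    total = float(joint.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"initial joint sums to {total:.6g}, not 1")
    return joint / total


# ---------------------------------------------------------------------------
# exact forward filtering
# ---------------------------------------------------------------------------

class _SliceOperators:
    """Compiled one-slice propagators for a fixed (table ids, env states) key.

    ``trans``  : array [prev interface ..., new interface ...]
                 P(I_t | I_{t-1}) with env nodes clamped.
    ``margin`` : per node, array [prev interface ..., node states]
                 P(X_t | I_{t-1}) with env nodes clamped.
    """

    __slots__ = ("trans", "margin")

    def __init__(self, trans: np.ndarray, margin: dict[str, np.ndarray]):
        self.trans = trans
        self.margin = margin


class ForwardFilter:
    """Exact interface filtering with per-(regime, month, env-state) caching.

    The cache makes repeated scenario runs over the same schema cheap: each
    distinct combination of resolved CPTs and clamped environment states is
    compiled once into dense linear operators over the interface joint.
    """

    def __init__(self, schema: NetworkSchema, interface_cap: int = DEFAULT_INTERFACE_CAP):
        diags = validate_schema(schema)
        if diags:
            raise SchemaError("invalid schema: " + "; ".join(diags[:5]))
        self.schema = schema
        if schema.interface_joint_size() > interface_cap:
            raise ResourceCapError(
                f"interface joint has {schema.interface_joint_size()} states, "
                f"cap is {interface_cap}; exact filtering refused"
            )
        self._cache: dict[tuple, _SliceOperators] = {}
        self._topo = [
            n for n in schema.topological_order()
            if schema.node(n).role != "environment"
        ]
        self._env = schema.environment_nodes

    # -- compilation ------------------------------------------------------

    def _compile(self, table_ids: tuple[tuple[str, str], ...],
                 env_states: tuple[tuple[str, int], ...]) -> _SliceOperators:
        schema = self.schema
        iface = schema.interface
        env_map = dict(env_states)
        tables = dict(table_ids)

        # frontier: all prev-interface axes are kept throughout; current-slice
        # variables are added in topological order and summed out once no
        # remaining factor needs them.
        axes: list[tuple[str, str]] = [("prev", n) for n in iface]
        arr = np.ones(tuple(len(schema.node(n).states) for n in iface))

        remaining_need: dict[str, int] = {}
        for n in self._topo:
            for p in schema.node(n).intra_parents:
                remaining_need[p] = remaining_need.get(p, 0) + 1

        margins: dict[str, np.ndarray] = {}

        def sum_out(key: tuple[str, str], a: np.ndarray, ax: list) -> np.ndarray:
            i = ax.index(key)
            ax.pop(i)
            return a.sum(axis=i)

        for name in self._topo:
            node = schema.node(name)
            cpt = table_array(schema, schema.tables[tables[name]])
            # build the factor with axes ordered as (parents..., child)
            f_axes: list[tuple[str, str]] = []
            clamp: list = []
            for p in schema.tables[tables[name]].parent_order:
                base, prev = _parent_key(p)
                if not prev and base in env_map:
                    clamp.append(env_map[base])  # clamp env parent
                    f_axes.append(("CLAMP", base))
                else:
                    clamp.append(slice(None))
                    f_axes.append(("prev" if prev else "cur", base))
            clamp.append(slice(None))
            cpt = cpt[tuple(clamp)]
            f_axes = [a for a in f_axes if a[0] != "CLAMP"]
            f_axes.append(("cur", name))

            # align factor to frontier: move shared axes into frontier order,
            # append the new child axis.
            new_axes = axes + [("cur", name)]
            # expand factor to new_axes
            perm_src = []
            exp = cpt
            # place factor axes into a dict
            pos = {a: i for i, a in enumerate(f_axes)}
            order = [pos[a] for a in new_axes if a in pos]
            exp = np.transpose(exp, order)
            # insert singleton dims for frontier axes not in the factor
            full_shape = []
            j = 0
            for a in new_axes:
                if a in pos:
                    full_shape.append(exp.shape[j])
                    j += 1
                else:
                    full_shape.append(1)
            exp = exp.reshape(full_shape)
            arr = arr[..., None] * exp
            axes = new_axes

            # marginal operator for this node: sum out every *current* axis
            # except the node itself (prev axes are kept as free indices)
            m = arr
            m_axes = list(axes)
            for a in list(m_axes):
                if a[0] == "cur" and a[1] != name:
                    m = m.sum(axis=m_axes.index(a))
                    m_axes.remove(a)
            margins[name] = m

            # retire current-slice variables no longer needed
            for p in node.intra_parents:
                if p in remaining_need:
                    remaining_need[p] -= 1
            for a in list(axes):
                if a[0] != "cur":
                    continue
                v = a[1]
                if remaining_need.get(v, 0) == 0 and v != name and v not in iface:
                    arr = sum_out(a, arr, axes)
            # also retire the node itself immediately if nothing needs it
            if remaining_need.get(name, 0) == 0 and name not in iface:
                arr = sum_out(("cur", name), arr, axes)

        # transition operator: keep prev axes + current interface axes,
        # ordered prev interface then new interface
        for a in list(axes):
            if a[0] == "cur" and a[1] not in iface:
                arr = sum_out(a, arr, axes)
        want = [("prev", n) for n in iface] + [("cur", n) for n in iface]
        arr = np.transpose(arr, [axes.index(a) for a in want])
        return _SliceOperators(arr, margins)

    def _operators(self, slice_index: int, month: int, regime: str | None,
                   env_states: tuple[tuple[str, int], ...]) -> _SliceOperators:
        table_ids = tuple(
            (n, self.schema.selectors[n].resolve(slice_index, month, regime))
            for n in self._topo
        )
        key = (table_ids, env_states)
        if key not in self._cache:
            self._cache[key] = self._compile(table_ids, env_states)
        return self._cache[key]

    # -- filtering --------------------------------------------------------

    def run(self, initial, start_month: int, n_slices: int,
            drivers: Sequence[Mapping[str, object]] | None = None,
            regimes: Sequence[str | None] | None = None) -> TrajectoryBeliefs:
        schema = self.schema
        if n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 1 <= start_month <= 12:
            raise ValueError("start_month must be in 1..12")
        iface = schema.interface
        n_iface = len(iface)
        joint = _initial_joint(schema, initial)

        env_nodes = self._env
        beliefs: list[BeliefState] = []
        for t in range(n_slices):
            month = month_add(start_month, t)
            regime = regimes[t] if regimes is not None else None
            env_dists = {}
            for e in env_nodes:
                if drivers is None or t >= len(drivers) or e not in drivers[t]:
                    raise ValueError(f"driver missing for environment node {e!r} at slice {t}")
                env_dists[e] = _as_distribution(drivers[t][e], schema.node(e).states)

            # mixture over environment assignments, weighted by driver probs
            new_joint = None
            marg_acc: dict[str, np.ndarray] = {}
            combos = itertools.product(*[range(len(schema.node(e).states)) for e in env_nodes]) \
                if env_nodes else [()]
            for combo in combos:
                w = 1.0
                for e, s in zip(env_nodes, combo):
                    w *= float(env_dists[e][s])
                if w == 0.0:
                    continue
                ops = self._operators(t, month, regime,
                                      tuple(zip(env_nodes, combo)))
                contrib = np.tensordot(joint, ops.trans, axes=n_iface) if n_iface \
                    else ops.trans * joint
                new_joint = w * contrib if new_joint is None else new_joint + w * contrib
                for name, m in ops.margin.items():
                    mm = np.tensordot(joint, m, axes=n_iface) if n_iface else m * joint
                    marg_acc[name] = w * mm if name not in marg_acc else marg_acc[name] + w * mm

            total = float(new_joint.sum())
            if abs(total - 1.0) > RENORM_WARN:
                logger.warning(
                    "slice %d: renormalisation drift %.3e", t, abs(total - 1.0)
                )
            joint = new_joint / total

            marginals = {}
            for name, m in marg_acc.items():
                s = float(m.sum())
                marginals[name] = m / s
            for e in env_nodes:
                marginals[e] = env_dists[e]
            beliefs.append(BeliefState(
                slice_index=t,
                calendar_month=month,
                marginals=marginals,
                interface_nodes=tuple(iface),
                interface_joint=joint.copy(),
            ))
        return TrajectoryBeliefs(beliefs=beliefs, schema=schema)


def forward_infer(schema: NetworkSchema, initial, start_month: int, n_slices: int,
                  drivers: Sequence[Mapping[str, object]] | None = None,
                  regimes: Sequence[str | None] | None = None,
                  interface_cap: int = DEFAULT_INTERFACE_CAP) -> TrajectoryBeliefs:
    """Exact filtering: propagate the interface joint slice by slice.

    ``initial`` is the belief over the interface nodes *entering* slice 0
    (either a joint array or per-node marginals, taken as independent);
    ``drivers`` supplies a distribution or point state for every
    environment-role node at every slice (soft evidence — the light driver is
    a probability, not an observation).
    """
    return ForwardFilter(schema, interface_cap=interface_cap).run(
        initial, start_month, n_slices, drivers, regimes
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_trajectory_joint(
    schema: NetworkSchema, initial, start_month: int, n_slices: int,
    drivers: Sequence[Mapping[str, object]] | None = None,
    regimes: Sequence[str | None] | None = None,
    cap: int = DEFAULT_BRUTE_FORCE_CAP,
) -> TrajectoryBeliefs:
    """Reference implementation of :func:`forward_infer` by full enumeration.

    Maintains the exact joint over *all* nodes of a slice and propagates it
    with nested loops over every (previous assignment, current assignment)
    pair, multiplying CPT entries one by one.  Deliberately shares no
    machinery with the filtering path; used as the testing oracle.
    """
    diags = validate_schema(schema)
    if diags:
        raise SchemaError("invalid schema: " + "; ".join(diags[:5]))
    names = schema.node_names
    cards = [len(schema.node(n).states) for n in names]
    full = int(np.prod(cards))
    if full * full * n_slices > cap:
        raise ResourceCapError(
            f"brute force would evaluate ~{full * full * n_slices} transition "
            f"entries, cap is {cap}"
        )
    topo = schema.topological_order()
    iface = schema.interface
    env = set(schema.environment_nodes)
    init_joint = _initial_joint(schema, initial)

    assignments = list(itertools.product(*[range(c) for c in cards]))
    pos = {n: i for i, n in enumerate(names)}

    def prob_of_slice(prev: tuple[int, ...] | None, cur: tuple[int, ...],
                      t: int, month: int, regime, env_dists) -> float:
        p = 1.0
        for n in topo:
            node = schema.node(n)
            if n in env:
                p *= float(env_dists[n][cur[pos[n]]])
                continue
            tid = schema.selectors[n].resolve(t, month, regime)
            table = schema.tables[tid]
            key = []
            for par in table.parent_order:
                base, is_prev = _parent_key(par)
                src = prev if is_prev else cur
                key.append(schema.node(base).states.labels[src[pos[base]]])
            p *= float(table.rows[tuple(key)][cur[pos[n]]])
            if p == 0.0:
                return 0.0
        return p

    # expand the initial interface joint over full assignments of a virtual
    # previous slice (non-interface coordinates are irrelevant: transition
    # probabilities only read interface coordinates of `prev`)
    iface_pos = [pos[n] for n in iface]

    beliefs: list[BeliefState] = []
    # previous-slice distribution represented over interface assignments only
    prev_iface_assignments = list(
        itertools.product(*[range(cards[i]) for i in iface_pos])
    )
    prev_dist = {a: float(init_joint[a]) for a in prev_iface_assignments} \
        if iface else {(): 1.0}

    for t in range(n_slices):
        month = month_add(start_month, t)
        regime = regimes[t] if regimes is not None else None
        env_dists = {}
        for e in env:
            if drivers is None or t >= len(drivers) or e not in drivers[t]:
                raise ValueError(f"driver missing for environment node {e!r} at slice {t}")
            env_dists[e] = _as_distribution(drivers[t][e], schema.node(e).states)

        cur_dist: dict[tuple[int, ...], float] = {}
        for prev_a, pw in prev_dist.items():
            if pw == 0.0:
                continue
            # build a full previous assignment whose interface coords are prev_a
            full_prev = [0] * len(names)
            for coord, i in zip(prev_a, iface_pos):
                full_prev[i] = coord
            full_prev = tuple(full_prev)
            for cur in assignments:
                p = prob_of_slice(full_prev, cur, t, month, regime, env_dists)
                if p > 0.0:
                    cur_dist[cur] = cur_dist.get(cur, 0.0) + pw * p

        z = sum(cur_dist.values())
        cur_dist = {a: v / z for a, v in cur_dist.items()}

        marginals = {n: np.zeros(cards[pos[n]]) for n in names}
        iface_shape = tuple(cards[i] for i in iface_pos)
        ij = np.zeros(iface_shape if iface else ())
        for a, v in cur_dist.items():
            for n in names:
                marginals[n][a[pos[n]]] += v
            if iface:
                ij[tuple(a[i] for i in iface_pos)] += v
            else:
                ij += v
        beliefs.append(BeliefState(
            slice_index=t, calendar_month=month, marginals=marginals,
            interface_nodes=tuple(iface), interface_joint=ij,
        ))
        prev_dist = {a: float(ij[a]) for a in prev_iface_assignments} \
            if iface else {(): 1.0}
    return TrajectoryBeliefs(beliefs=beliefs, schema=schema)


# ---------------------------------------------------------------------------
# limit-cycle detection
# ---------------------------------------------------------------------------

def detect_limit_cycle(traj: TrajectoryBeliefs, period: int = 12,
                       tol: float = 1e-3,
                       nodes: Iterable[str] | None = None
                       ) -> tuple[bool, int | None]:
    """Detect settling into a periodic baseline (limit cycle or fixed point).

    The trajectory has converged at slice ``s`` if, for every tracked node,
    the month-matched marginals of slices ``[s, s+period)`` and
    ``[s+period, s+2*period)`` differ by less than ``tol`` in total variation.
    Returns ``(converged, first such s)`` or ``(False, None)``.
    """
    if len(traj) < 2 * period:
        raise ValueError(f"need at least {2 * period} slices, have {len(traj)}")
    tracked = list(nodes) if nodes is not None else traj.schema.node_names
    series = {n: traj.marginal_series(n) for n in tracked}
    for s in range(len(traj) - 2 * period + 1):
        ok = True
        for n in tracked:
            a = series[n][s:s + period]
            b = series[n][s + period:s + 2 * period]
            tv = 0.5 * np.abs(a - b).sum(axis=1).max()
            if tv >= tol:
                ok = False
                break
        if ok:
            return True, s
    return False, None
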