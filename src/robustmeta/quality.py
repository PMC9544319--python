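"""Quality-constraint sets and their discretization into quality grids.

A study quality q_i in (0, 1] rescales study i's effect variance to
sigma_theta^2 / q_i: q_i = 1 means no bias, small q_i down-weights the
study.  Qualitative risk-of-bias ratings induce a *set* of admissible
quality vectors (the constraint set M): studies with a clear rating
share one quality per category, unclear studies float between the high
and low categories, and category cut-offs bound each group's interval.

M is a polytope of a restricted shape — per-group interval bounds plus
pairwise order constraints between groups.  It is discretized either by
a regular box grid (no order constraints) or by enumerating the
polytope's extreme points and taking lattice-weighted convex
combinations of them.  All grid construction uses exact rational
arithmetic so that duplicate removal is reproducible.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConstraintError
from .studies import RobTable

FractionPair = tuple[Fraction, Fraction]


def _as_fraction(x) -> Fraction:
    """Convert user-facing numbers to exact rationals.

    Floats are snapped to the shortest rational within 1e-9, so 0.1
    becomes 1/10 rather than its binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    f = Fraction(x).limit_denominator(10**9)
    return f


def _interval(pair) -> FractionPair:
    lb, ub = _as_fraction(pair[0]), _as_fraction(pair[1])
    if not (0 < lb <= ub <= 1):
        raise ConstraintError(f"interval [{lb}, {ub}] must satisfy 0 < lb <= ub <= 1")
    return lb, ub


@dataclass(frozen=True)
class CategoryBounds:
    """Quality cut-offs per risk-of-bias category.

    Defaults: low risk [0.5, 0.95], high risk [0.1, 0.5], unclear
    [0.1, 0.95] — a deliberately conservative choice spanning most of
    the unit interval while staying away from q = 0 (which would give a
    study infinite error variance).
    """

    low: FractionPair = (Fraction(1, 2), Fraction(19, 20))
    high: FractionPair = (Fraction(1, 10), Fraction(1, 2))
    unclear: FractionPair = (Fraction(1, 10), Fraction(19, 20))

    def __post_init__(self) -> None:
        object.__setattr__(self, "low", _interval(self.low))
        object.__setattr__(self, "high", _interval(self.high))
        object.__setattr__(self, "unclear", _interval(self.unclear))

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryBounds":
        """Load cut-off overrides from JSON: {"low": [lb, ub], ...};
        omitted categories keep their defaults."""
        with open(path) as fh:
            spec = json.load(fh)
        unknown = set(spec) - {"low", "high", "unclear"}
        if unknown:
            raise ConstraintError(f"unknown category keys {sorted(unknown)}")
        return cls(**{k: tuple(v) for k, v in spec.items()})


@dataclass(frozen=True)
class QualityConstraintSet:
    """Symbolic description of the admissible set M of quality vectors.

    ``group_of`` maps each study position to a group label; all studies
    in a group share one quality value.  ``bounds`` gives each group's
    interval and ``order`` is a set of pairs (a, b) meaning the quality
    of group a is <= that of group b.
    """

    group_of: tuple[str, ...]            # study position -> group label
    bounds: Mapping[str, FractionPair]   # group label -> (lb, ub)
    order: tuple[tuple[str, str], ...]   # (a, b): q_a <= q_b

    def __post_init__(self) -> None:
        labels = set(self.group_of)
        if labels != set(self.bounds):
            raise ConstraintError(
                f"groups {sorted(labels)} and bounds {sorted(self.bounds)} disagree"
            )
        for a, b in self.order:
            if a not in labels or b not in labels:
                raise ConstraintError(f"order pair ({a!r}, {b!r}) names unknown group")
        # canonicalize
        object.__setattr__(
            self, "bounds", {g: _interval(iv) for g, iv in self.bounds.items()}
        )
        object.__setattr__(self, "order", tuple(sorted(set(self.order))))
        self.propagated_bounds()  # raises if cyclic or infeasible

    @property
    def K(self) -> int:
        return len(self.group_of)

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels in order of first appearance along the studies."""
        seen: dict[str, None] = {}
        for g in self.group_of:
            seen.setdefault(g)
        return tuple(seen)

    def _toposort(self) -> list[str]:
        succ: dict[str, set[str]] = {g: set() for g in self.groups}
        indeg: dict[str, int] = {g: 0 for g in self.groups}
        for a, b in self.order:
            if b not in succ[a]:
                succ[a].add(b)
                indeg[b] += 1
        ready = [g for g in self.groups if indeg[g] == 0]
        out: list[str] = []
        while ready:
            g = ready.pop(0)
            out.append(g)
            for h in sorted(succ[g]):
                indeg[h] -= 1
                if indeg[h] == 0:
                    ready.append(h)
        if len(out) != len(self.groups):
            cyc = sorted(set(self.groups) - set(out))
            raise ConstraintError(f"order constraints are cyclic among groups {cyc}")
        return out

    def propagated_bounds(self) -> dict[str, FractionPair]:
        """Tightest per-group intervals implied by bounds plus order.

        Lower bounds propagate forward along a <= b edges, upper bounds
        backward.  Raises if any interval empties (infeasible system).
        """
        topo = self._toposort()
        lo = {g: self.bounds[g][0] for g in self.groups}
        hi = {g: self.bounds[g][1] for g in self.groups}
        for a in topo:  # forward: lb(b) >= lb(a)
            for x, b in self.order:
                if x == a and lo[b] < lo[a]:
                    lo[b] = lo[a]
        for b in reversed(topo):  # backward: ub(a) <= ub(b)
            for a, y in self.order:
                if y == b and hi[a] > hi[b]:
                    hi[a] = hi[b]
        for g in self.groups:
            if lo[g] > hi[g]:
                chain = [p for p in self.order if g in p]
                raise ConstraintError(
                    f"infeasible constraints: group {g!r} interval empties to "
                    f"[{lo[g]}, {hi[g]}] after propagating order constraints {chain}"
                )
        return {g: (lo[g], hi[g]) for g in self.groups}

    def contains(self, q: Sequence) -> bool:
        """Exact membership test for a quality vector (rational-snapped)."""
        qf = [_as_fraction(x) for x in q]
        if len(qf) != self.K:
            return False
        val: dict[str, Fraction] = {}
        for pos, g in enumerate(self.group_of):
            if g in val and val[g] != qf[pos]:
                return False
            val[g] = qf[pos]
        for g, (lb, ub) in self.bounds.items():
            if not (lb <= val[g] <= ub):
                return False
        return all(val[a] <= val[b] for a, b in self.order)


@dataclass(frozen=True)
class ExtremePointSet:
    """Vertices of a constraint-set polytope, as exact rationals."""

    vertices: tuple[tuple[Fraction, ...], ...]

    def __len__(self) -> int:
        return len(self.vertices)

    def as_array(self) -> np.ndarray:
        return np.array([[float(x) for x in v] for v in self.vertices])


@dataclass(frozen=True)
class QualityGrid:
    """Finite, deduplicated list of quality vectors discretizing M."""

    points: tuple[tuple[float, ...], ...]
    provenance: str                       # 'box', 'simplex', or 'explicit'
    spacing: float | None = None          # weight spacing or axis count metadata
    raw_count: int | None = None          # simplex: compositions before dedup

    def __post_init__(self) -> None:
        if not self.points:
            raise ConstraintError("QualityGrid must be nonempty")

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.array(self.points)


def build_constraints(
    rob: RobTable,
    domain: str | int | Mapping,
    cb: CategoryBounds | None = None,
) -> QualityConstraintSet:
    """Build the admissible quality set from risk-of-bias ratings.

    ``domain`` is either a single Cochrane domain (name or 1-based
    index) or an explicit multi-domain specification: a mapping with
    keys ``groups`` (label -> list of study ids), ``bounds`` (label ->
    [lb, ub] or a category name), and ``order`` (list of [a, b] pairs,
    meaning quality of group a <= quality of group b).

    Single-domain rules: all low-risk studies share one group with the
    low-category bounds, all high-risk studies one group with the
    high-category bounds, and each unclear study gets its own group
    bounded below by the high-category lower cut-off and above by the
    low-category upper cut-off, ordered between the high and low groups
    where those exist.  No automatic scoring rule combines multiple
    domains; cross-domain judgments must be passed explicitly.
    """
    cb = cb or CategoryBounds()
    if isinstance(domain, Mapping):
        return _constraints_from_spec(rob, domain, cb)
    if isinstance(domain, int):
        try:
            domain = rob.domains[domain - 1]
        except IndexError:
            raise ConstraintError(
                f"domain index {domain} outside 1..{len(rob.domains)}"
            ) from None
    ratings = rob.column(domain)

    group_of: list[str] = []
    bounds: dict[str, FractionPair] = {}
    order: list[tuple[str, str]] = []
    has_low = "low" in ratings
    has_high = "high" in ratings
    # unclear studies: widest cut-offs available (§ fallback: 0.1 and 0.95)
    u_lb, u_ub = cb.high[0], cb.low[1]
    for sid, rating in zip(rob.study_ids, ratings):
        if rating == "low":
            group_of.append("low")
            bounds["low"] = cb.low
        elif rating == "high":
            group_of.append("high")
            bounds["high"] = cb.high
        else:
            g = f"unclear:{sid}"
            group_of.append(g)
            bounds[g] = (u_lb, u_ub)
            if has_high:
                order.append(("high", g))
            if has_low:
                order.append((g, "low"))
    return QualityConstraintSet(tuple(group_of), bounds, tuple(order))


def _constraints_from_spec(
    rob: RobTable, spec: Mapping, cb: CategoryBounds
) -> QualityConstraintSet:
    groups = spec["groups"]
    sid_to_group: dict[str, str] = {}
    for label, sids in groups.items():
        for sid in sids:
            if sid in sid_to_group:
                raise ConstraintError(f"study {sid!r} assigned to two groups")
            sid_to_group[sid] = label
    missing = [sid for sid in rob.study_ids if sid not in sid_to_group]
    if missing:
        raise ConstraintError(f"constraint spec misses studies {missing}")
    group_of = tuple(sid_to_group[sid] for sid in rob.study_ids)
    bounds: dict[str, FractionPair] = {}
    for label, bspec in spec["bounds"].items():
        if isinstance(bspec, str):
            bounds[label] = getattr(cb, bspec)
        else:
            bounds[label] = _interval(bspec)
    order = tuple((a, b) for a, b in spec.get("order", []))
    return QualityConstraintSet(group_of, bounds, order)


def load_constraint_spec(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def extreme_points(cs: QualityConstraintSet) -> ExtremePointSet:
    """Enumerate the vertices of the constraint-set polytope.

    The polytope lives in group space (one coordinate per group) and is
    cut out by interval bounds and pairwise order constraints, so every
    vertex coordinate equals some group's interval endpoint, propagated
    along tight order constraints.  Candidates are therefore built by
    assigning each group one of the endpoint values lying inside its
    own interval; a candidate is kept iff it is feasible and its active
    constraints have full rank (a genuine vertex, not a face interior).
    Output is deterministic: vertices sorted lexicographically as
    K-vectors.
    """
    groups = cs.groups
    n = len(groups)
    endpoints = sorted({v for iv in cs.bounds.values() for v in iv})
    candidates = [
        [v for v in endpoints if cs.bounds[g][0] <= v <= cs.bounds[g][1]]
        for g in groups
    ]
    gidx = {g: i for i, g in enumerate(groups)}
    verts: set[tuple[Fraction, ...]] = set()
    for assign in itertools.product(*candidates):
        if any(assign[gidx[a]] > assign[gidx[b]] for a, b in cs.order):
            continue
        # active constraint normals in group space
        rows: list[list[float]] = []
        for i, g in enumerate(groups):
            lb, ub = cs.bounds[g]
            if assign[i] == lb or assign[i] == ub:
                e = [0.0] * n
                e[i] = 1.0
                rows.append(e)
        for a, b in cs.order:
            if assign[gidx[a]] == assign[gidx[b]]:
                e = [0.0] * n
                e[gidx[a]], e[gidx[b]] = 1.0, -1.0
                rows.append(e)
        if len(rows) < n or np.linalg.matrix_rank(np.array(rows)) < n:
            continue
        verts.add(tuple(assign))
    out = sorted(
        tuple(v[gidx[g]] for g in cs.group_of) for v in verts
    )
    if not out:
        raise ConstraintError("constraint set has no vertices (infeasible?)")
    return ExtremePointSet(vertices=tuple(out))


def _compositions(total: int, parts: int) -> Iterable[tuple[int, ...]]:
    """All tuples of ``parts`` nonnegative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def simplex_grid(vertices: ExtremePointSet, spacing: float | Fraction) -> QualityGrid:
    """Lattice of convex combinations of the polytope vertices.

    Weights alpha run over all compositions with components in
    {0, 1/s, ..., 1} summing to 1 (C(s+m-1, m-1) of them for m
    vertices); each q = sum alpha_i v_i is formed in exact integer
    arithmetic and duplicates are removed by exact equality, so the
    grid size is independent of floating-point representation.
    """
    sp = _as_fraction(spacing)
    if sp <= 0 or sp.numerator != 1:
        raise ConstraintError(f"spacing must be a reciprocal integer, got {spacing}")
    s = sp.denominator
    m = len(vertices)
    if m < 1:
        raise ConstraintError("need at least one vertex")
    K = len(vertices.vertices[0])
    # scale vertices to a common integer denominator
    den = math.lcm(*[x.denominator for v in vertices.vertices for x in v]) or 1
    vint = np.array(
        [[int(x * den) for x in v] for v in vertices.vertices], dtype=np.int64
    )  # (m, K)
    raw = 0
    seen: dict[tuple[int, ...], None] = {}
    for alpha in _compositions(s, m):
        raw += 1
        qint = tuple(int(x) for x in np.dot(alpha, vint))  # q * den * s, exact
        seen.setdefault(qint)
    scale = float(den * s)
    points = sorted(tuple(x / scale for x in qint) for qint in seen)
    return QualityGrid(
        points=tuple(points), provenance="simplex", spacing=float(sp), raw_count=raw
    )


def box_grid(cs: QualityConstraintSet, points_per_axis: int) -> QualityGrid:
    """Regular grid over a pure box constraint set.

    Each group's interval is split into ``points_per_axis`` equally
    spaced values (endpoints included, computed as exact rationals) and
    the Cartesian product over groups is taken.  Refuses constraint
    sets with order constraints — those are gridded via
    :func:`extreme_points` + :func:`simplex_grid`.
    """
    if cs.order:
        raise ConstraintError(
            "box_grid requires a pure box (no order constraints); "
            "use extreme_points + simplex_grid instead"
        )
    if points_per_axis < 2:
        raise ConstraintError("points_per_axis must be >= 2")
    groups = cs.groups
    axes: list[list[Fraction]] = []
    for g in groups:
        lb, ub = cs.bounds[g]
        step = (ub - lb) / (points_per_axis - 1)
        axes.append([lb + i * step for i in range(points_per_axis)])
    gidx = {g: i for i, g in enumerate(groups)}
    seen: dict[tuple[Fraction, ...], None] = {}
    for assign in itertools.product(*axes):
        q = tuple(assign[gidx[g]] for g in cs.group_of)
        seen.setdefault(q)
    points = sorted(tuple(float(x) for x in q) for q in seen)
    return QualityGrid(
        points=tuple(points), provenance="box", spacing=float(points_per_axis)
    )


def explicit_grid(points: Iterable[Sequence[float]]) -> QualityGrid:
    """Wrap user-supplied quality vectors as a grid (dedup, ordered)."""
    seen: dict[tuple[Fraction, ...], None] = {}
    for p in points:
        seen.setdefault(tuple(_as_fraction(x) for x in p))
    pts = sorted(tuple(float(x) for x in q) for q in seen)
    return QualityGrid(points=tuple(pts), provenance="explicit")
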