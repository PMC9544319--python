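"""Quality constraint sets, extreme points, and grid construction."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from robustmeta import (
    CategoryBounds,
    ConstraintError,
    QualityConstraintSet,
    box_grid,
    build_constraints,
    explicit_grid,
    extreme_points,
    simplex_grid,
)

F = Fraction


class TestBuildConstraints:
    def test_blinding_domain_groups(self, rituximab_rob):
        """Low-risk REFLEX/WA16291 share one quality; DANCER and SERENE
        float independently below it."""
        cs = build_constraints(rituximab_rob, 3)
        assert cs.group_of[0] == cs.group_of[1] == "low"
        assert cs.group_of[2] != cs.group_of[3]
        assert cs.bounds["low"] == (F(1, 2), F(19, 20))
        for g in (cs.group_of[2], cs.group_of[3]):
            assert cs.bounds[g] == (F(1, 10), F(19, 20))
            assert (g, "low") in cs.order

    def test_reporting_domain_single_group(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, "d5_reporting")
        assert set(cs.group_of) == {"low"}
        assert cs.bounds["low"] == (F(1, 2), F(19, 20))
        assert cs.order == ()

    def test_all_unclear_is_pure_box(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, 1)
        assert len(set(cs.group_of)) == 4
        assert cs.order == ()
        for g in cs.group_of:
            assert cs.bounds[g] == (F(1, 10), F(19, 20))

    def test_high_risk_ordering(self, rituximab_rob):
        """With high-risk studies present, unclear sits between the
        high and low groups."""
        ratings = {
            sid: dict(rituximab_rob.ratings[sid]) for sid in rituximab_rob.study_ids
        }
        ratings["REFLEX"]["d6_other"] = "high"
        ratings["WA16291"]["d6_other"] = "unclear"
        rob = type(rituximab_rob)(
            study_ids=rituximab_rob.study_ids, ratings=ratings
        )
        cs = build_constraints(rob, 6)
        g_u = "unclear:WA16291"
        assert ("high", g_u) in cs.order and (g_u, "low") in cs.order
        assert cs.bounds["high"] == (F(1, 10), F(1, 2))

    def test_multi_domain_spec(self, rituximab_rob, all_domains_spec):
        cs = build_constraints(rituximab_rob, all_domains_spec)
        assert cs.group_of == ("g1", "g2", "g34", "g34")
        assert cs.order == (("g1", "g2"), ("g34", "g2"))

    def test_infeasible_system(self, rituximab_rob):
        spec = {
            "groups": {"a": ["REFLEX", "WA16291"], "b": ["DANCER", "SERENE"]},
            "bounds": {"a": [0.8, 0.95], "b": [0.1, 0.5]},
            "order": [["a", "b"]],  # forces 0.8 <= q_a <= q_b <= 0.5
        }
        with pytest.raises(ConstraintError, match="infeasible"):
            build_constraints(rituximab_rob, spec)

    def test_cyclic_order(self, rituximab_rob):
        spec = {
            "groups": {"a": ["REFLEX", "WA16291"], "b": ["DANCER", "SERENE"]},
            "bounds": {"a": [0.1, 0.9], "b": [0.1, 0.9]},
            "order": [["a", "b"], ["b", "a"]],
        }
        with pytest.raises(ConstraintError, match="cyclic"):
            build_constraints(rituximab_rob, spec)


class TestExtremePoints:
    def test_blinding_domain_vertices(self, rituximab_rob):
        """All 8 published vertices of the blinding-domain set."""
        cs = build_constraints(rituximab_rob, 3)
        verts = {tuple(map(float, v)) for v in extreme_points(cs).vertices}
        assert verts == {
            (0.50, 0.50, 0.10, 0.10), (0.95, 0.95, 0.10, 0.10),
            (0.50, 0.50, 0.10, 0.50), (0.95, 0.95, 0.10, 0.95),
            (0.50, 0.50, 0.50, 0.10), (0.95, 0.95, 0.95, 0.10),
            (0.50, 0.50, 0.50, 0.50), (0.95, 0.95, 0.95, 0.95),
        }

    def test_attrition_domain_vertices(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, 4)
        verts = {tuple(map(float, v)) for v in extreme_points(cs).vertices}
        assert verts == {
            (0.10, 0.95, 0.95, 0.95), (0.10, 0.50, 0.50, 0.50),
            (0.50, 0.50, 0.50, 0.50), (0.95, 0.95, 0.95, 0.95),
        }

    def test_all_domains_vertices(self, rituximab_rob, all_domains_spec):
        cs = build_constraints(rituximab_rob, all_domains_spec)
        verts = {tuple(map(float, v)) for v in extreme_points(cs).vertices}
        assert verts == {
            (0.10, 0.10, 0.10, 0.10), (0.10, 0.95, 0.10, 0.10),
            (0.10, 0.95, 0.95, 0.95), (0.95, 0.95, 0.10, 0.10),
            (0.95, 0.95, 0.95, 0.95),
        }

    def test_vertices_satisfy_constraints(self, rituximab_rob, all_domains_spec):
        for sel in [1, 3, 4, 5, all_domains_spec]:
            cs = build_constraints(rituximab_rob, sel)
            for v in extreme_points(cs).vertices:
                assert cs.contains(v)

    def test_order_permutation_invariance(self, rituximab_rob, all_domains_spec):
        spec = dict(all_domains_spec)
        spec["order"] = list(reversed(all_domains_spec["order"]))
        a = extreme_points(build_constraints(rituximab_rob, all_domains_spec))
        b = extreme_points(build_constraints(rituximab_rob, spec))
        assert a.vertices == b.vertices


class TestSimplexGrid:
    def test_single_vertex_degenerate(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, 5)
        verts = extreme_points(cs)
        lo = [v for v in verts.vertices if float(v[0]) == 0.5]
        grid = simplex_grid(type(verts)(vertices=(lo[0],)), 0.1)
        assert len(grid) == 1
        assert grid.points[0] == (0.5, 0.5, 0.5, 0.5)

    def test_bad_spacing(self, rituximab_rob):
        verts = extreme_points(build_constraints(rituximab_rob, 3))
        with pytest.raises(ConstraintError, match="reciprocal"):
            simplex_grid(verts, 0.3)

    def test_points_satisfy_constraints(self, rituximab_rob, all_domains_spec):
        for sel in [3, 4, all_domains_spec]:
            cs = build_constraints(rituximab_rob, sel)
            grid = simplex_grid(extreme_points(cs), Fraction(1, 4))
            for q in grid.points:
                assert cs.contains(q), (sel, q)

    def test_matches_brute_force_oracle(self):
        """Small-case cross-check: nested-loop enumeration with exact
        rationals over explicit vertices."""
        verts = (
            (F(1, 10), F(1, 2)),
            (F(1, 2), F(1, 2)),
            (F(9, 10), F(9, 10)),
        )
        s = 4
        expected = set()
        for a in range(s + 1):
            for b in range(s + 1 - a):
                c = s - a - b
                q = tuple(
                    (a * verts[0][j] + b * verts[1][j] + c * verts[2][j]) / s
                    for j in range(2)
                )
                expected.add(tuple(float(x) for x in q))
        from robustmeta import ExtremePointSet

        grid = simplex_grid(ExtremePointSet(vertices=verts), Fraction(1, s))
        assert set(grid.points) == expected
        assert grid.raw_count == 15  # C(4+2, 2)

    def test_exact_dedup_independent_of_vertex_order(self, rituximab_rob):
        from robustmeta import ExtremePointSet

        verts = extreme_points(build_constraints(rituximab_rob, 3))
        shuffled = ExtremePointSet(vertices=tuple(reversed(verts.vertices)))
        g1 = simplex_grid(verts, Fraction(1, 5))
        g2 = simplex_grid(shuffled, Fraction(1, 5))
        assert g1.points == g2.points


class TestBoxGrid:
    def test_unclear_box_10k(self, rituximab_rob):
        grid = box_grid(build_constraints(rituximab_rob, 1), 10)
        assert len(grid) == 10_000
        axis = sorted({p[0] for p in grid.points})
        assert axis[0] == pytest.approx(0.10)
        assert axis[-1] == pytest.approx(0.95)
        assert any(abs(v - 0.7611111111111111) < 1e-12 for v in axis)

    def test_single_group_10(self, rituximab_rob):
        grid = box_grid(build_constraints(rituximab_rob, 6), 10)
        assert len(grid) == 10
        for p in grid.points:
            assert len(set(p)) == 1
        common = sorted(p[0] for p in grid.points)
        assert common[0] == pytest.approx(0.5)
        assert common[-1] == pytest.approx(0.95)
        assert np.allclose(np.diff(common), 0.05)

    def test_rejects_order_constraints(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, 3)
        with pytest.raises(ConstraintError, match="simplex"):
            box_grid(cs, 10)

    def test_degenerate_interval_collapses(self, rituximab_rob):
        cb = CategoryBounds(low=(0.95, 0.95))
        grid = box_grid(build_constraints(rituximab_rob, 5, cb), 4)
        assert grid.points == ((0.95, 0.95, 0.95, 0.95),)

    def test_two_point_endpoints_only(self):
        cs = QualityConstraintSet(
            group_of=("g",), bounds={"g": (F(1, 5), F(4, 5))}, order=()
        )
        grid = box_grid(cs, 2)
        assert grid.points == ((0.2,), (0.8,))

    def test_points_satisfy_constraints(self, rituximab_rob):
        cs = build_constraints(rituximab_rob, 2)
        grid = box_grid(cs, 3)
        assert all(cs.contains(q) for q in grid.points)


def test_category_bounds_from_json(tmp_path):
    p = tmp_path / "cb.json"
    p.write_text('{"low": [0.6, 0.9], "high": [0.05, 0.4]}')
    cb = CategoryBounds.from_json(p)
    assert cb.low == (F(3, 5), F(9, 10))
    assert cb.high == (F(1, 20), F(2, 5))
    assert cb.unclear == (F(1, 10), F(19, 20))  # default kept
    p.write_text('{"medium": [0.3, 0.6]}')
    with pytest.raises(ConstraintError):
        CategoryBounds.from_json(p)


def test_explicit_grid_dedup_and_order():
    grid = explicit_grid([(0.5, 0.2), (0.1, 0.9), (0.5, 0.2)])
    assert grid.points == ((0.1, 0.9), (0.5, 0.2))
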