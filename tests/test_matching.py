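"""Segment and root matching under the distance threshold."""

import itertools

import numpy as np
import pytest

import rsaeval as rv
from conftest import straight_root, translate


def brute_force_two_phase(values, threshold):
    """Direct evaluation of the two-phase segment rule on a dense matrix."""
    n_gt, n_tr = values.shape
    assignments = {i: [] for i in range(n_gt)}
    unmatched = []
    for j in range(n_tr):
        best = min(range(n_gt), key=lambda i: (values[i, j], i))
        if values[best, j] <= threshold:
            assignments[best].append(j)
        else:
            unmatched.append(j)
    singles = [i for i in range(n_gt) if len(assignments[i]) == 1]
    still = []
    for j in unmatched:
        if singles:
            best = min(singles, key=lambda i: (values[i, j], i))
            if values[best, j] <= threshold:
                assignments[best].append(j)
                continue
        still.append(j)
    return assignments, still


def make_dm(values):
    values = np.asarray(values, dtype=float)
    return rv.DistanceMatrix(
        values=values,
        row_root_ids=[f"g{i}" for i in range(values.shape[0])],
        col_root_ids=[f"t{j}" for j in range(values.shape[1])],
        row_lengths=np.ones(values.shape[0]),
        col_lengths=np.ones(values.shape[1]),
    )


class TestMatchSegments:
    def test_identical_systems_all_matched_at_zero(self, default_rsa):
        segs = rv.to_segments(default_rsa)
        D = rv.distance_matrix(segs, segs)
        corr = rv.match_segments(D, 0.75)
        assert corr.unmatched_traced == []
        assert all(d == pytest.approx(0.0) for d in corr.pair_distances.values())
        matched = sorted(j for js in corr.assignments.values() for j in js)
        assert matched == list(range(len(segs)))

    def test_far_displacement_leaves_all_unmatched(self, simple_system):
        far = translate(simple_system, (100, 0, 0))
        D = rv.distance_matrix(
            rv.to_segments(simple_system), rv.to_segments(far)
        )
        corr = rv.match_segments(D, 0.75)
        assert len(corr.unmatched_traced) == D.values.shape[1]

    def test_toy_matches_brute_force(self):
        values = np.array([
            [0.1, 0.9, 2.0, 0.3],
            [0.5, 0.2, 0.6, 0.4],
            [1.5, 1.1, 0.65, 2.5],
        ])
        D = make_dm(values)
        corr = rv.match_segments(D, 0.7)
        expect_assign, expect_unmatched = brute_force_two_phase(values, 0.7)
        assert corr.assignments == expect_assign
        assert corr.unmatched_traced == expect_unmatched

    def test_every_traced_segment_appears_exactly_once(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.random((rng.integers(2, 6), rng.integers(2, 8))) * 2
            corr = rv.match_segments(make_dm(values), 0.8)
            seen = sorted(
                list(corr.unmatched_traced)
                + [j for js in corr.assignments.values() for j in js]
            )
            assert seen == list(range(values.shape[1]))
            assert all(d <= 0.8 for d in corr.pair_distances.values())

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ValueError):
            rv.match_segments(make_dm([[0.1]]), 0.0)


class TestCumulativeRootDistance:
    def test_identical_roots_zero(self, simple_system):
        segs = rv.to_segments(simple_system)
        D = rv.distance_matrix(segs, segs)
        assert rv.cumulative_root_distance(D, "tap", "tap") == pytest.approx(0.0)

    def test_parallel_offset_equals_delta(self, simple_system):
        # every root is perpendicular to y, so each per-segment minimum is 0.4
        shifted = translate(simple_system, (0, 0.4, 0))
        D = rv.distance_matrix(
            rv.to_segments(simple_system), rv.to_segments(shifted)
        )
        for rid in simple_system.root_ids:
            assert rv.cumulative_root_distance(D, rid, rid) == pytest.approx(0.4)

    def test_weighted_mean_matches_loop_oracle(self):
        gt = straight_root("g", n_nodes=3, spacing=1.0)
        # uneven tracing: 3 segments of differing placement
        tr_nodes = [
            rv.Node((0.2, 0, 0)), rv.Node((0.2, 0, 0.7)),
            rv.Node((0.5, 0, 1.4)), rv.Node((0.5, 0, 2.3)),
        ]
        tr = rv.Root(root_id="t", nodes=tr_nodes)
        gt_segs = rv.to_segments(rv.RootSystem(roots=[gt]))
        tr_segs = rv.to_segments(rv.RootSystem(roots=[tr]))
        D = rv.distance_matrix(gt_segs, tr_segs)
        # independent loop computation of the length-weighted mean
        num = den = 0.0
        for i, s in enumerate(gt_segs):
            dmin = min(rv.segment_distance(s, t) for t in tr_segs)
            num += s.length * dmin
            den += s.length
        assert rv.cumulative_root_distance(D, "g", "t") == pytest.approx(num / den)

    def test_unknown_root_rejected(self, simple_system):
        segs = rv.to_segments(simple_system)
        D = rv.distance_matrix(segs, segs)
        with pytest.raises(ValueError):
            rv.cumulative_root_distance(D, "tap", "nope")


class TestMatchRoots:
    def test_self_match_is_perfect(self, default_rsa):
        match = rv.match_roots(default_rsa, rv.copy_system(default_rsa), 0.75)
        assert sorted(match.matched_gt) == sorted(default_rsa.root_ids)
        assert match.false_negative_roots == []
        assert match.false_positive_roots == []
        assert all(p.distance == pytest.approx(0.0) for p in match.pairs)

    def test_missing_lateral_becomes_false_negative(self, simple_system):
        traced = rv.RootSystem(
            roots=[r for r in rv.copy_system(simple_system).roots
                   if r.root_id != "lat2"]
        )
        match = rv.match_roots(simple_system, traced, 0.75)
        assert match.false_negative_roots == ["lat2"]
        assert sorted(match.matched_gt) == ["lat1", "tap"]

    def test_empty_tracing_all_false_negative(self, simple_system):
        match = rv.match_roots(simple_system, rv.RootSystem(), 0.75)
        assert match.pairs == []
        assert match.false_negative_roots == simple_system.root_ids

    def test_fragmented_lateral_matches_one_to_n(self, simple_system):
        traced = rv.copy_system(simple_system)
        lat1 = traced.root("lat1")
        frag_a = rv.Root(root_id="lat1a", nodes=lat1.nodes[:3], order=1,
                         parent_root_id="tap")
        frag_b = rv.Root(root_id="lat1b", nodes=lat1.nodes[2:], order=1,
                         parent_root_id="tap")
        traced.roots = [r for r in traced.roots if r.root_id != "lat1"]
        traced.roots += [frag_a, frag_b]
        match = rv.match_roots(simple_system, traced, 0.75)
        pair = next(p for p in match.pairs if p.gt_root_id == "lat1")
        assert sorted(pair.traced_root_ids) == ["lat1a", "lat1b"]
        assert match.false_positive_roots == []
        assert match.false_negative_roots == []

    def test_partition_invariant(self, default_rsa):
        traced = rv.perturb_tracing(
            default_rsa,
            rv.PerturbationParams(node_jitter_sd=0.2, drop_root_prob=0.3,
                                  false_positive_count=3, seed=5),
        )
        match = rv.match_roots(default_rsa, traced, 0.75)
        assert sorted(match.matched_gt + match.false_negative_roots) == sorted(
            default_rsa.root_ids
        )
        assert sorted(match.matched_traced + match.false_positive_roots) == sorted(
            traced.root_ids
        )

    def test_threshold_monotonicity(self, default_rsa):
        traced = rv.perturb_tracing(
            default_rsa, rv.PerturbationParams(node_jitter_sd=0.3, seed=9)
        )
        sizes = [
            len(rv.match_roots(default_rsa, traced, th).matched_gt)
            for th in (0.2, 0.4, 0.75, 1.5, 3.0)
        ]
        assert sizes == sorted(sizes)

    def test_stage1_total_distance_is_globally_optimal(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_gt = int(rng.integers(2, 6))
            n_tr = int(rng.integers(2, 6))
            gt = rv.RootSystem(roots=[
                straight_root(f"g{i}", start=rng.random(3) * 5,
                              direction=rng.standard_normal(3))
                for i in range(n_gt)
            ])
            tr = rv.RootSystem(roots=[
                straight_root(f"t{j}", start=rng.random(3) * 5,
                              direction=rng.standard_normal(3))
                for j in range(n_tr)
            ])
            D = rv.distance_matrix(rv.to_segments(gt), rv.to_segments(tr))
            cost = np.array([
                [rv.cumulative_root_distance(D, g.root_id, t.root_id)
                 for t in tr.roots]
                for g in gt.roots
            ])
            # exhaustive minimum over all full one-to-one assignments
            k = min(n_gt, n_tr)
            if n_gt <= n_tr:
                best = min(
                    sum(cost[r, c] for r, c in zip(range(k), cols))
                    for cols in itertools.permutations(range(n_tr), k)
                )
            else:
                best = min(
                    sum(cost[r, c] for r, c in zip(rows, range(k)))
                    for rows in itertools.permutations(range(n_gt), k)
                )
            big = 1e9  # threshold large enough to keep every optimal pair
            match = rv.match_roots(gt, tr, big)
            total = sum(p.distance for p in match.pairs)
            assert total == pytest.approx(best, rel=1e-9)

    def test_voxel_threshold_conversion(self):
        assert rv.voxel_threshold_to_cm(15, 0.05) == pytest.approx(0.75)
        assert rv.voxel_threshold_to_cm(15, 1.0) == pytest.approx(15.0)
        assert rv.voxel_threshold_to_cm(1, 0.027) == pytest.approx(0.027)
        with pytest.raises(ValueError):
            rv.voxel_threshold_to_cm(0, 0.05)
        with pytest.raises(ValueError):
            rv.voxel_threshold_to_cm(15, -1)
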