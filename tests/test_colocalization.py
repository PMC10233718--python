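"""Cross-channel grouping vs. an exhaustive oracle, and the random-chance model."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from nascentquant.colocalization import (
    ColocParams,
    classify_cooccurrence,
    coloc_fraction,
    expected_random_coloc,
    pair_candidates,
)


def table(xy, z=None, channel="A"):
    xy = np.asarray(xy, dtype=float)
    if z is None:
        z = np.zeros(len(xy))
    return pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "z_nm": np.asarray(z, float),
                         "amplitude": 100.0, "accepted": True, "channel": channel})


# ---------------------------------------------------------------------------
# exhaustive grouping oracle


def oracle_groupings(tables, params: ColocParams):
    """Enumerate every maximal valid grouping; return (all, best_signature).

    A grouping partitions all spots into records of 1-3 members with distinct
    channels that are pairwise within the co-localization radius (clique).
    Maximal means no single spot could still join another record under the
    same rule.  Groupings are ranked by their sorted multiset of within-record
    distances, padded with +inf (so groupings that pair more spots at equal
    cost rank first); the greedy closest-first procedure realizes the minimum.
    """
    spots = []
    for ch in sorted(tables):
        coords = tables[ch][["x_nm", "y_nm"] if params.frame == "2d"
                            else ["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        for i in range(len(coords)):
            spots.append((ch, i, coords[i]))
    n = len(spots)
    dist = np.full((n, n), np.inf)
    for a in range(n):
        for b in range(a + 1, n):
            if spots[a][0] != spots[b][0]:
                d = float(np.linalg.norm(spots[a][2] - spots[b][2]))
                dist[a, b] = dist[b, a] = d

    def clique(block):
        return all(dist[a, b] <= params.coloc_radius
                   for a, b in itertools.combinations(block, 2))

    blocks_of = {s: [] for s in range(n)}
    all_blocks = []
    for a in range(n):
        for b in range(a + 1, n):
            if dist[a, b] <= params.coloc_radius:
                all_blocks.append((a, b))
                for c in range(b + 1, n):
                    if len({spots[i][0] for i in (a, b, c)}) == 3 and clique((a, b, c)):
                        all_blocks.append((a, b, c))
    for blk in all_blocks:
        for s in blk:
            blocks_of[s].append(blk)

    groupings = []

    def recurse(assigned, records):
        s = next((i for i in range(n) if i not in assigned), None)
        if s is None:
            groupings.append(list(records))
            return
        records.append((s,))
        recurse(assigned | {s}, records)
        records.pop()
        for blk in blocks_of[s]:
            if blk[0] == s and not any(i in assigned for i in blk):
                records.append(blk)
                recurse(assigned | set(blk), records)
                records.pop()

    recurse(frozenset(), [])

    def is_maximal(records):
        for r1 in records:
            if len(r1) != 1:
                continue
            s = r1[0]
            for r2 in records:
                if r2 is r1 or len(r2) >= 3:
                    continue
                if spots[s][0] in {spots[m][0] for m in r2}:
                    continue
                if all(dist[s, m] <= params.coloc_radius for m in r2):
                    return False
        return True

    def signature(records):
        ds = sorted(dist[a, b] for rec in records
                    for a, b in itertools.combinations(rec, 2))
        return tuple(ds) + (np.inf,) * (n - len(ds))

    maximal = [g for g in groupings if is_maximal(g)]
    sigs = [signature(g) for g in maximal]
    best = min(sigs)
    winners = [frozenset(frozenset((spots[i][0], spots[i][1]) for i in rec) for rec in g)
               for g, s in zip(maximal, sigs) if s == best]
    return winners, best


def records_as_partition(records):
    return frozenset(frozenset(r.members) for r in records)


def random_instance(seed, n_channels=3, max_per_channel=8, extent=4000.0):
    rng = np.random.default_rng(seed)
    chans = ["farred", "red", "green"][:n_channels]
    tables = {}
    for ch in chans:
        k = int(rng.integers(0, max_per_channel + 1))
        tables[ch] = table(rng.uniform(0, extent, (k, 2)), channel=ch)
    return tables


class TestGroupingOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_greedy_matches_exhaustive_minimum(self, seed):
        params = ColocParams()
        tables = random_instance(seed)
        records, _ = classify_cooccurrence(tables, params)
        winners, _ = oracle_groupings(tables, params)
        assert records_as_partition(records) in winners

    def test_two_channel_instances(self):
        params = ColocParams()
        for seed in range(100, 106):
            tables = random_instance(seed, n_channels=2, extent=2500.0)
            records, _ = classify_cooccurrence(tables, params)
            winners, _ = oracle_groupings(tables, params)
            assert records_as_partition(records) in winners


class TestClassification:
    def test_mutually_close_trio_is_triple(self):
        tables = {"farred": table([[0, 0]]), "red": table([[300, 0]]),
                  "green": table([[150, 250]])}
        records, summary = classify_cooccurrence(tables)
        assert [r.label for r in records] == ["triple"]
        assert summary["triple"].tolist() == [1, 1, 1]

    def test_chain_without_clique_is_double_plus_single(self):
        # A-B 300, B-C 300, but A-C 600 > radius: clique rule excludes C
        tables = {"farred": table([[0, 0]]), "red": table([[300, 0]]),
                  "green": table([[600, 0]])}
        records, summary = classify_cooccurrence(tables)
        labels = sorted(r.label for r in records)
        assert labels == ["double:farred,red", "single"]
        assert summary.loc["green", "single"] == 1

    def test_chain_rule_admits_the_chain(self):
        tables = {"farred": table([[0, 0]]), "red": table([[300, 0]]),
                  "green": table([[600, 0]])}
        records, _ = classify_cooccurrence(tables, ColocParams(triple_rule="chain"))
        assert sorted(r.label for r in records) == ["triple"]

    def test_far_spots_are_singles(self):
        tables = {"farred": table([[0, 0], [5000, 5000]]),
                  "red": table([[2000, 2000]])}
        records, summary = classify_cooccurrence(tables)
        assert all(r.label == "single" for r in records)
        assert summary["single"].tolist() == [2, 1]

    def test_closest_first_assignment(self):
        # red spot is closer to the second farred spot
        tables = {"farred": table([[0, 0], [400, 0]]), "red": table([[300, 0]])}
        records, _ = classify_cooccurrence(tables)
        doubles = [r for r in records if len(r.members) == 2]
        assert len(doubles) == 1
        assert ("farred", 1) in doubles[0].members

    def test_conservation_on_random_fields(self):
        # the per-channel totals assertion inside classify_cooccurrence runs
        for seed in range(5):
            tables = random_instance(seed + 50, extent=2000.0)
            records, summary = classify_cooccurrence(tables)
            n_members = sum(len(r.members) for r in records)
            assert n_members == int(summary["total"].sum())

    def test_rejected_spots_excluded(self):
        t = table([[0, 0], [100, 0]])
        t.loc[1, "accepted"] = False
        records, summary = classify_cooccurrence({"farred": t, "red": table([[80, 0]])})
        assert summary.loc["farred", "total"] == 1

    def test_3d_frame_uses_z(self):
        tables = {"farred": table([[0, 0]], z=[0.0]),
                  "red": table([[0, 0]], z=[900.0])}
        rec2d, _ = classify_cooccurrence(tables, ColocParams(frame="2d"))
        rec3d, _ = classify_cooccurrence(tables, ColocParams(frame="3d"))
        assert any(len(r.members) == 2 for r in rec2d)
        assert all(len(r.members) == 1 for r in rec3d)

    def test_radius_monotonicity(self):
        tables = random_instance(7, extent=2500.0)
        grouped = []
        for radius in (200.0, 500.0, 900.0):
            records, _ = classify_cooccurrence(tables, ColocParams(coloc_radius=radius))
            grouped.append(sum(len(r.members) for r in records if len(r.members) > 1))
        assert grouped[0] <= grouped[1] <= grouped[2]


class TestPairCandidates:
    def test_distance_computation(self):
        pairs = pair_candidates(table([[0, 0]]), table([[300, 400]]))
        assert len(pairs) == 1
        assert pairs.loc[0, "distance_nm"] == pytest.approx(500.0)

    def test_square_window_limits(self):
        params = ColocParams()
        a = table([[0, 0]])
        b = table([[1900, 1900], [2000, 0]])
        pairs = pair_candidates(a, b, params)
        # (1900, 1900) fits the square window; (2000, 0) exceeds the halfwidth
        assert len(pairs) == 1
        assert pairs.loc[0, "dx_nm"] == pytest.approx(-1900.0)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(11)
        a_xy = rng.uniform(0, 8000, (60, 2))
        b_xy = rng.uniform(0, 8000, (70, 2))
        params = ColocParams()
        pairs = pair_candidates(table(a_xy), table(b_xy), params)
        want = {(i, j) for i in range(60) for j in range(70)
                if np.max(np.abs(a_xy[i] - b_xy[j])) <= params.search_halfwidth}
        got = set(zip(pairs["idx_a"], pairs["idx_b"]))
        assert got == want


class TestColocFraction:
    def _records(self):
        tables = {"farred": table([[0, 0], [5000, 5000]]), "red": table([[100, 0]])}
        records, _ = classify_cooccurrence(tables)
        return records

    def test_fraction(self):
        records = self._records()
        assert coloc_fraction(records, "farred", ["red"]) == pytest.approx(0.5)
        assert coloc_fraction(records, "red", ["farred"]) == pytest.approx(1.0)

    def test_empty_channel_is_nan_with_warning(self):
        records = self._records()
        with pytest.warns(UserWarning, match="undefined"):
            out = coloc_fraction(records, "green", ["red"])
        assert np.isnan(out)


class TestExpectedRandom:
    def test_model_a_worked_example(self):
        # 10 and 10 spots over 100 cells: 10*10/100 = 1 expected co-active cell
        out = expected_random_coloc({"a": 10, "b": 10}, n_cells=100, seed=0)
        assert out["model_a"]["double:a,b"] == pytest.approx(1.0)

    def test_model_a_triple(self):
        out = expected_random_coloc({"a": 10, "b": 20, "c": 30}, n_cells=100, seed=0)
        assert out["model_a"]["triple"] == pytest.approx(10 * 20 * 30 / 100 ** 2)

    def test_zero_counts_give_zero_expectation(self):
        out = expected_random_coloc({"a": 0, "b": 10}, n_cells=50, seed=0)
        assert out["model_a"]["double:a,b"] == 0.0
        assert out["model_b"]["double:a,b"]["expected"] == 0.0

    def test_geometric_probability_against_direct_mc(self):
        params = ColocParams(frame="3d")
        out = expected_random_coloc({"a": 5, "b": 5}, n_cells=100, params=params,
                                    n_mc=200_000, seed=1)
        rng = np.random.default_rng(99)
        def ball(n):
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            return v * rng.uniform(size=(n, 1)) ** (1 / 3) * params.nuclear_radius
        p_direct = float(np.mean(np.linalg.norm(ball(200_000) - ball(200_000), axis=1)
                                 <= params.coloc_radius))
        assert out["p_pair"] == pytest.approx(p_direct, abs=6 * out["p_pair_se"] + 6e-4)

    def test_huge_radius_recovers_model_a(self):
        params = ColocParams(search_halfwidth=20_000.0, coloc_radius=30_000.0,
                             nuclear_radius=3000.0, frame="3d")
        out = expected_random_coloc({"a": 8, "b": 9}, n_cells=40, params=params, seed=2)
        assert out["p_pair"] == 1.0
        assert out["model_b"]["double:a,b"]["expected"] == pytest.approx(
            out["model_a"]["double:a,b"])

    def test_interval_brackets_expectation(self):
        out = expected_random_coloc({"a": 30, "b": 30}, n_cells=60, n_null=4000, seed=3)
        lo, hi = out["model_b"]["double:a,b"]["interval"]
        assert lo <= out["model_b"]["double:a,b"]["expected"] <= hi

    def test_overfull_channel_warns(self):
        with pytest.warns(UserWarning, match="two alleles"):
            expected_random_coloc({"a": 50, "b": 5}, n_cells=10, seed=4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_random_coloc({"a": 5}, n_cells=0)
        with pytest.raises(ValueError):
            expected_random_coloc({"a": -1, "b": 2}, n_cells=10)
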