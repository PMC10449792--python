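import numpy as np
import pandas as pd
import pytest

from synspan import (DiffConfig, EventTable, cluster_frequencies,
                     frequency_tests, per_cluster_differential,
                     pseudobulk_differential, pseudobulk_table)
from synspan.diffstats import benjamini_hochberg


def brute_force_bh(p):
    """Step-up BH by hand: sort, scale by m/rank, enforce monotonicity."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestBH:
    def test_hand_worked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(7)
            np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p),
                                       atol=1e-12)

    def test_monotone_in_raw_p(self):
        p = np.array([0.001, 0.01, 0.2, 0.5, 0.04])
        adj = benjamini_hochberg(p)
        assert (np.argsort(adj, kind="stable") == np.argsort(p, kind="stable")).all()


def labeled_metadata(assignments):
    """(subject, species, cluster) triples -> labels + metadata frame."""
    rows = [{"species": sp, "subject": subj} for subj, sp, _ in assignments]
    labels = np.array([c for _, _, c in assignments])
    return labels, pd.DataFrame(rows)


class TestClusterFrequencies:
    def test_simple_proportions(self):
        labels, meta = labeled_metadata(
            [("s1", "A", "x"), ("s1", "A", "x"), ("s1", "A", "y"), ("s1", "A", "y"),
             ("s2", "B", "x"), ("s2", "B", "y")])
        prof = cluster_frequencies(labels, meta)
        assert prof.freq.loc["s1"].tolist() == [0.5, 0.5]

    def test_frequency_floor_filters(self):
        # species A: mean freq 0.005 in cluster "rare" -> filtered;
        # 0.02 -> retained (the 0.01 noise floor, exact behaviour)
        rng = np.random.default_rng(0)
        rows = []
        for subj in ("a1", "a2"):
            rows += [("%s" % subj, "A", "rare")] * 5 + [(subj, "A", "common")] * 995
        for subj in ("b1", "b2"):
            rows += [(subj, "B", "rare")] * 20 + [(subj, "B", "common")] * 980
        labels, meta = labeled_metadata(rows)
        prof = cluster_frequencies(labels, meta, DiffConfig(freq_floor=0.01))
        assert not prof.retained.loc["A", "rare"]
        assert prof.retained.loc["B", "rare"]
        assert prof.retained.loc["A", "common"]
        assert prof.species_mean_freq.loc["A", "rare"] == pytest.approx(0.005)

    def test_mean_over_subjects_retains_split_cluster(self):
        labels, meta = labeled_metadata(
            [("s1", "A", "x"), ("s2", "A", "y")])
        prof = cluster_frequencies(labels, meta)
        assert prof.species_mean_freq.loc["A"].tolist() == [0.5, 0.5]
        assert prof.retained.loc["A"].all()

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        rows = [(f"s{i%4}", "A", f"c{rng.integers(3)}") for i in range(200)]
        labels, meta = labeled_metadata(rows)
        prof = cluster_frequencies(labels, meta)
        np.testing.assert_allclose(prof.freq.sum(axis=1), 1.0, atol=1e-12)


class TestFrequencyTests:
    def make_profile(self, freq_a, freq_b):
        rows = []
        for i, f in enumerate(freq_a):
            n_c = int(round(f * 1000))
            rows += [(f"a{i}", "A", "c")] * n_c + [(f"a{i}", "A", "other")] * (1000 - n_c)
        for i, f in enumerate(freq_b):
            n_c = int(round(f * 1000))
            rows += [(f"b{i}", "B", "c")] * n_c + [(f"b{i}", "B", "other")] * (1000 - n_c)
        labels, meta = labeled_metadata(rows)
        return cluster_frequencies(labels, meta)

    def test_exact_rank_sum_worked_example(self):
        # complete separation of 3 vs 3 subjects: two-sided exact p = 2/20 = 0.1
        prof = self.make_profile([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        res = frequency_tests(prof)
        p = res.loc[res["cluster"] == "c", "p"].iloc[0]
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_frequencies_p_one(self):
        prof = self.make_profile([0.2, 0.3], [0.2, 0.3])
        res = frequency_tests(prof)
        assert (res["p"] == 1.0).all()


class TestPseudobulk:
    def make_table(self, subjects=6):
        rng = np.random.default_rng(0)
        frames = []
        for sp in ("A", "B"):
            for s in range(subjects):
                frames.append(pd.DataFrame({
                    "m1": rng.normal(1.0, 0.1, 50),
                    "m2": rng.normal(1.0, 0.1, 50),
                    "species": sp, "subject": f"{sp}{s}",
                }))
        return EventTable(pd.concat(frames, ignore_index=True))

    def test_single_subject_mean(self):
        df = pd.DataFrame({"m": [1.0, 3.0], "species": "A", "subject": "s"})
        pb = pseudobulk_table(EventTable(df))
        assert pb.loc["s", "m"] == 2.0

    def test_order_invariance(self):
        table = self.make_table()
        shuffled = EventTable(table.data.sample(frac=1.0, random_state=5)
                              .reset_index(drop=True))
        pd.testing.assert_frame_equal(pseudobulk_table(table),
                                      pseudobulk_table(shuffled))

    def test_subject_weighted_differs_from_event_pooled(self):
        # one subject contributes 10x the events with a different mean:
        # pooling over events is dragged toward it, subject means are not
        df = pd.concat([
            pd.DataFrame({"m": np.full(1000, 10.0), "species": "A", "subject": "s1"}),
            pd.DataFrame({"m": np.full(100, 1.0), "species": "A", "subject": "s2"}),
        ], ignore_index=True)
        pb = pseudobulk_table(EventTable(df))
        subject_weighted = pb["m"].mean()
        event_pooled = df["m"].mean()
        assert subject_weighted == pytest.approx(5.5)
        assert abs(event_pooled - subject_weighted) > 3

    def test_no_hits_for_identical_groups(self):
        table = self.make_table()
        pb = pseudobulk_table(table)
        pb.loc[:, "m1"] = 1.0
        pb.loc[:, "m2"] = 2.0
        res = pseudobulk_differential(pb, "A", "B")
        assert res["hit"].sum() == 0

    def test_planted_shift_is_unique_hit(self):
        # 6 vs 6 subjects: complete separation gives exact p = 2/924,
        # which survives BH across the 2-marker family
        table = self.make_table(subjects=6)
        pb = pseudobulk_table(table)
        pb.loc[pb["species"] == "A", "m1"] *= 2.0  # |log2FC| = 1 > 0.5
        res = pseudobulk_differential(pb, "A", "B")
        assert res.loc[res["marker"] == "m1", "hit"].iloc[0]
        assert res["hit"].sum() == 1

    def test_kruskal_three_identical_groups(self):
        rng = np.random.default_rng(0)
        rows = []
        for sp in ("A", "B", "C"):
            for s in range(3):
                rows.append({"species": sp, "m": 1.0})
        pb = pd.DataFrame(rows, index=[f"s{i}" for i in range(9)])
        res = pseudobulk_differential(pb, "A", "B", extra_groups=["C"])
        assert res["kruskal_p"].iloc[0] == 1.0

    def test_consistency_pair_blocks_hit(self):
        # the combined "primate" group differs from B, but the two primate
        # subgroups also differ from each other -> consistency filter
        # removes the would-be hit on m1
        rng = np.random.default_rng(4)
        pb2 = pd.DataFrame({
            "species": ["P1"] * 6 + ["P2"] * 6 + ["B"] * 6,
            "m1": np.r_[rng.normal(8.0, 0.1, 6), rng.normal(2.0, 0.1, 6),
                        rng.normal(1.0, 0.1, 6)],
            "m2": rng.normal(1.0, 0.1, 18),
        }, index=[f"s{i}" for i in range(18)])
        res = pseudobulk_differential(pb2, ["P1", "P2"], "B",
                                      consistency_pair=("P1", "P2"))
        row = res.set_index("marker").loc["m1"]
        assert row["consistency_p"] < 0.05 and not row["hit"]
        # with concordant subgroups the same contrast is a hit
        pb3 = pb2.copy()
        pb3.loc[pb3["species"] == "P1", "m1"] -= 6.0
        res2 = pseudobulk_differential(pb3, ["P1", "P2"], "B",
                                       consistency_pair=("P1", "P2"))
        assert res2.set_index("marker").loc["m1", "hit"]


class TestPerClusterDifferential:
    def make_table(self, shift_cluster=None, shift_marker=None, factor=2.0,
                   subjects=7):
        rng = np.random.default_rng(2)
        frames = []
        markers = [f"m{i}" for i in range(8)]
        for sp in ("A", "B"):
            for s in range(subjects):
                for cluster in ("c0", "c1", "c2", "c3"):
                    X = rng.lognormal(0.0, 0.2, size=(60, len(markers)))
                    df = pd.DataFrame(X, columns=markers)
                    if sp == "A" and cluster == shift_cluster:
                        df[shift_marker] *= factor
                    df["species"] = sp
                    df["subject"] = f"{sp}{s}"
                    df["cluster"] = cluster
                    frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        labels = df.pop("cluster").to_numpy()
        return EventTable(df), labels

    def test_planted_shift_flagged(self):
        table, labels = self.make_table(shift_cluster="c3", shift_marker="m7")
        res = per_cluster_differential(table, labels, "A", "B")
        hits = res[res["hit"]]
        assert len(hits) == 1
        assert hits.iloc[0]["cluster"] == "c3" and hits.iloc[0]["marker"] == "m7"

    def test_null_has_no_hits(self):
        table, labels = self.make_table()
        res = per_cluster_differential(table, labels, "A", "B")
        assert res["hit"].sum() == 0

    def test_bh_family_is_joint(self):
        table, labels = self.make_table()
        res = per_cluster_differential(table, labels, "A", "B")
        assert len(res) == 4 * 8  # every tested (cluster, marker) pair in one family
        np.testing.assert_allclose(
            res["p_adj"], benjamini_hochberg(res["p"].to_numpy()), atol=1e-12)
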