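import numpy as np
import pandas as pd
import pytest

from mutblot.downstream import (
    cluster_patients,
    elbow_k,
    gene_mb_survival_groups,
    group_compare,
    km_curve,
    logrank,
    mb_composition,
    spectrum_summary,
)
from mutblot.encoding import CanonicalSubstitution


def labeling_frame(barcodes, mbs, genes=None):
    n = len(barcodes)
    return pd.DataFrame(
        {
            "sample_barcode": barcodes,
            "chromosome": ["chr1"] * n,
            "position": range(1, n + 1),
            "ref_allele": ["C"] * n,
            "alt_allele": ["A"] * n,
            "gene_symbol": genes if genes is not None else ["G1"] * n,
            "mb": mbs,
        }
    )


class TestComposition:
    def test_half_half_patient(self):
        df = labeling_frame(["P-1-A"] * 4, ["MB 1", "MB 1", "MB 2", "MB 2"])
        comp = mb_composition(df)
        assert comp.loc["P-1-A", "MB 1"] == pytest.approx(0.5)
        assert comp.loc["P-1-A", "MB 2"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        barcodes = [f"P-{i % 7}-X" for i in range(200)]
        mbs = [f"MB {k}" for k in rng.integers(1, 11, size=200)]
        comp = mb_composition(labeling_frame(barcodes, mbs))
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(comp.to_numpy() >= 0)

    def test_matches_planted_mixture_at_large_n(self):
        """500 SBSs per patient drawn from a (0.6, 0.4) mixture recover
        the mixture within binomial Monte-Carlo error."""
        rng = np.random.default_rng(1)
        rows = []
        for p in range(20):
            draws = rng.random(500) < 0.6
            rows += [(f"P-{p:02d}-T", "MB 1" if d else "MB 2") for d in draws]
        df = labeling_frame([r[0] for r in rows], [r[1] for r in rows])
        comp = mb_composition(df)
        se = np.sqrt(0.6 * 0.4 / 500)
        assert np.all(np.abs(comp["MB 1"] - 0.6) < 4 * se)

    def test_aliquots_merged_to_patient(self):
        df = labeling_frame(["TCGA-A-1-01A", "TCGA-A-1-01B"], ["MB 1", "MB 2"])
        comp = mb_composition(df)
        assert list(comp.index) == ["TCGA-A-1"]
        assert comp.iloc[0].tolist() == [0.5, 0.5]


class TestSpectrum:
    def test_single_type_class(self):
        subs = [CanonicalSubstitution("C>A", "AT", "GC") for _ in range(5)]
        type_df, pos_df = spectrum_summary(["MB 1"] * 5, subs)
        assert type_df.loc["MB 1"].tolist() == [1.0, 0, 0, 0, 0, 0]

    def test_position_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        subs = [
            CanonicalSubstitution(
                "T>C",
                "".join(rng.choice(list("ACGTN"), 4)),
                "".join(rng.choice(list("ACGTN"), 4)),
            )
            for _ in range(50)
        ]
        _, pos_df = spectrum_summary(["MB 1"] * 50, subs)
        sums = pos_df.groupby("position")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert set(pos_df["position"]) == {-4, -3, -2, -1, 1, 2, 3, 4}

    def test_planted_enrichment_recovered(self):
        """80% T at position -1 in 2000 draws is recovered within 3%."""
        rng = np.random.default_rng(3)
        subs = []
        for _ in range(2000):
            last = "T" if rng.random() < 0.8 else rng.choice(list("ACG"))
            subs.append(CanonicalSubstitution("C>T", "A" + last, "GG"))
        _, pos_df = spectrum_summary(["MB 1"] * 2000, subs)
        row = pos_df[(pos_df["position"] == -1) & (pos_df["base"] == "T")]
        assert row["fraction"].iloc[0] == pytest.approx(0.8, abs=0.03)


class TestClusterPatients:
    def comp_matrix(self, archetypes, n_per, noise, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in archetypes:
            for _ in range(n_per):
                v = np.maximum(a + rng.normal(0, noise, len(a)), 1e-6)
                rows.append(v / v.sum())
        return pd.DataFrame(
            rows, columns=[f"MB {i + 1}" for i in range(len(archetypes[0]))]
        )

    def test_k1_single_class(self):
        comp = self.comp_matrix([np.ones(4) / 4], 10, 0.01)
        pc = cluster_patients(comp, K=1)
        assert set(pc.classes) == {1}

    def test_default_k_is_seven(self):
        comp = self.comp_matrix([np.ones(8) / 8], 30, 0.05)
        pc = cluster_patients(comp)
        assert pc.chosen_k == 7
        assert set(pc.classes) <= set(range(1, 8))

    def test_elbow_selects_three_planted_archetypes(self):
        archetypes = [
            np.array([0.8, 0.1, 0.05, 0.05]),
            np.array([0.05, 0.8, 0.1, 0.05]),
            np.array([0.05, 0.1, 0.05, 0.8]),
        ]
        comp = self.comp_matrix(archetypes, 40, 0.02)
        pc = cluster_patients(comp, K="auto", k_range=range(2, 11), seed=0)
        assert pc.chosen_k == 3

    def test_patient_order_invariance(self):
        comp = self.comp_matrix(
            [np.array([0.7, 0.2, 0.1]), np.array([0.1, 0.2, 0.7])], 15, 0.03
        )
        pc1 = cluster_patients(comp, K=2, seed=1)
        perm = np.random.default_rng(4).permutation(len(comp))
        pc2 = cluster_patients(comp.iloc[perm], K=2, seed=1)
        joined = pd.crosstab(pc1.classes.iloc[perm].to_numpy(),
                             pc2.classes.to_numpy())
        # one-to-one mapping between labelings
        assert (joined.to_numpy() > 0).sum() == 2

    def test_k_exceeding_patients_rejected(self):
        comp = self.comp_matrix([np.ones(3) / 3], 4, 0.01)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_patients(comp, K=10)

    def test_elbow_on_synthetic_curve(self):
        wcss = pd.Series({2: 100.0, 3: 20.0, 4: 15.0, 5: 12.0})
        assert elbow_k(wcss) == 3


class TestGroupCompare:
    def test_identical_groups_zero_t(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        grp = ["a"] * 3 + ["b"] * 3
        res = group_compare(vals, grp)
        assert res.test_name == "t-test"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_three_groups_dispatch_anova(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=30)
        grp = ["a", "b", "c"] * 10
        res = group_compare(vals, grp)
        assert res.test_name == "anova"

    def test_chi_square_matches_hand_computation(self):
        """2x2 table [[10,20],[20,10]] gives 5.4 with Yates correction."""
        vals = ["x"] * 10 + ["y"] * 20 + ["x"] * 20 + ["y"] * 10
        grp = ["g1"] * 30 + ["g2"] * 30
        res = group_compare(vals, grp)
        assert res.test_name == "chi-square"
        assert res.statistic == pytest.approx(5.4, abs=1e-10)

    def test_missing_rows_dropped_and_counted(self):
        vals = pd.Series([1.0, np.nan, 2.0, 3.0, 4.0, np.nan])
        grp = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = group_compare(vals, grp)
        assert res.dropped_rows == 2
        assert res.group_sizes == {"a": 2, "b": 2}

    def test_emptied_group_raises(self):
        vals = pd.Series([np.nan, np.nan, 1.0, 2.0])
        grp = pd.Series(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="non-empty"):
            group_compare(vals, grp)


def brute_force_logrank(groups):
    """Observed-vs-expected tabulation over pooled risk sets."""
    data = []
    for gi, (t, e) in enumerate(groups.values()):
        data += [(float(tt), int(ee), gi) for tt, ee in zip(t, e)]
    k = len(groups)
    event_times = sorted({t for t, e, _ in data if e == 1})
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = np.array(
            [sum(1 for t, _, g in data if t >= et and g == gi) for gi in range(k)]
        )
        deaths = np.array(
            [sum(1 for t, e, g in data if t == et and e == 1 and g == gi)
             for gi in range(k)]
        )
        n, d = at_risk.sum(), deaths.sum()
        O += deaths
        E += d * at_risk / n
        for i in range(k):
            for j in range(k):
                delta = 1.0 if i == j else 0.0
                if n > 1:
                    V[i, j] += (
                        d * (at_risk[i] / n) * (delta - at_risk[j] / n)
                        * (n - d) / (n - 1)
                    )
    z = (O - E)[:-1]
    stat = float(z @ np.linalg.solve(V[:-1, :-1], z))
    return stat


class TestLogrank:
    def test_agrees_with_risk_set_oracle(self):
        """Statistic matches an explicit risk-set tabulation to 1e-10
        on small instances."""
        rng = np.random.default_rng(6)
        for trial in range(5):
            groups = {
                "a": (rng.integers(1, 30, 8).astype(float), rng.integers(0, 2, 8)),
                "b": (rng.integers(1, 30, 7).astype(float), rng.integers(0, 2, 7)),
                "c": (rng.integers(1, 30, 5).astype(float),
                      np.ones(5, dtype=int)),
            }
            res = logrank(groups)
            assert res.statistic == pytest.approx(
                brute_force_logrank(groups), abs=1e-10
            )

    def test_type_one_error_calibrated(self):
        """Two groups from one exponential law: rejection rate at
        alpha=0.05 stays within [0.01, 0.10] over 50 seeds."""
        rejections = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t1, t2 = rng.exponential(500, 100), rng.exponential(500, 100)
            res = logrank({"a": (t1, np.ones(100, int)),
                           "b": (t2, np.ones(100, int))})
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / 50 <= 0.10

    def test_power_at_hazard_ratio_three(self):
        """Hazard ratio 3 with n=200 is detected in >= 90% of 50 seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t1, t2 = rng.exponential(300, 100), rng.exponential(900, 100)
            res = logrank({"a": (t1, np.ones(100, int)),
                           "b": (t2, np.ones(100, int))})
            hits += res.p_value < 0.05
        assert hits / 50 >= 0.90

    def test_fully_censored_group_allowed(self):
        res = logrank({
            "a": ([5.0, 10.0, 15.0], [1, 1, 0]),
            "b": ([4.0, 12.0, 20.0], [0, 0, 0]),
        })
        assert 0 <= res.p_value <= 1

    def test_no_events_anywhere_raises(self):
        with pytest.raises(ValueError, match="events"):
            logrank({"a": ([1.0], [0]), "b": ([2.0], [0])})


class TestGeneSurvivalGroups:
    def clinical(self):
        return pd.DataFrame(
            {
                "survival_time": [100.0, 200.0, 300.0],
                "event": [1, 0, 1],
            },
            index=pd.Index(["P-1-A", "P-2-A", "P-3-A"], name="sample_barcode"),
        )

    def frame(self):
        return labeling_frame(
            ["P-1-A-x", "P-1-A-x", "P-2-A-x", "P-3-A-x"],
            ["MB 1", "MB 2", "MB 1", "MB 2"],
            genes=["TP53"] * 4,
        )

    def test_multi_mb_patient_in_every_group_by_default(self):
        groups = gene_mb_survival_groups(self.frame(), self.clinical(), "TP53")
        assert sorted(groups) == ["MB 1", "MB 2"]
        assert len(groups["MB 1"][0]) == 2  # P-1 and P-2
        assert len(groups["MB 2"][0]) == 2  # P-1 and P-3

    def test_exclusive_mode_drops_multi_mb_patients(self):
        groups = gene_mb_survival_groups(
            self.frame(), self.clinical(), "TP53", mode="exclusive"
        )
        assert len(groups["MB 1"][0]) == 1
        assert len(groups["MB 2"][0]) == 1

    def test_unknown_gene_raises(self):
        with pytest.raises(ValueError, match="KRAS"):
            gene_mb_survival_groups(self.frame(), self.clinical(), "KRAS")


class TestKMCurve:
    def test_step_function_boundaries(self):
        sf = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        assert sf["survival"].iloc[0] == 1.0
        assert np.all(np.diff(sf["survival"]) <= 0)
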