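"""Association engine: closed-form OLS agreement, type-I error calibration,
IVW meta-analysis identities, thresholds, peak grouping, and variance
explained."""

import numpy as np
import pandas as pd
import pytest

from sibface.gwas import (
    group_peaks,
    ivw_meta,
    recode_x_males,
    regress,
    regress_many,
    residualize_genotypes,
    significance_thresholds,
    variance_explained,
)


class TestRegress:
    def test_exact_linear_phenotype(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, size=100).astype(float)
        out = regress(2.0 * x, x)
        assert out["beta"] == pytest.approx(2.0)
        assert out["p"] <= np.finfo(float).tiny * 10

    def test_matches_closed_form_and_matrix_solver(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = 0.3 * x + rng.normal(size=80)
        out = regress(y, x)
        X = np.column_stack([np.ones(80), x])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(res[0])
        se = np.sqrt(rss / 78 / np.sum((x - x.mean()) ** 2))
        assert out["beta"] == pytest.approx(coef[1], abs=1e-10)
        assert out["se"] == pytest.approx(se, abs=1e-10)

    def test_vectorized_engine_matches_scalar(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        Y = rng.normal(size=(60, 3))
        table = regress_many(Y, X)
        for _, row in table.iterrows():
            single = regress(Y[:, int(row["trait_id"])], X[:, int(row["snp_index"])])
            assert row["beta"] == pytest.approx(single["beta"], abs=1e-10)
            assert row["se"] == pytest.approx(single["se"], abs=1e-10)
            assert row["p"] == pytest.approx(single["p"], rel=1e-8)

    def test_type_one_error_calibrated(self):
        # 2,000 null tests at alpha = 0.05: rejection rate within 3 sigma
        rng = np.random.default_rng(3)
        n, m = 200, 2000
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        table = regress_many(y, X)
        rate = (table["p"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress(np.random.default_rng(0).normal(size=20), np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            regress(np.ones(5), np.ones(5))


class TestResidualization:
    def test_independent_covariates_leave_genotypes_centered(self):
        rng = np.random.default_rng(4)
        n = 2000
        G = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        C = pd.DataFrame({"age": rng.uniform(5, 15, n), "sex": rng.integers(0, 2, n)})
        resid, tested = residualize_genotypes(G, C)
        assert tested.all()
        for j in range(5):
            r = np.corrcoef(resid[:, j], G[:, j] - G[:, j].mean())[0, 1]
            assert r > 0.99

    def test_male_x_recoding(self):
        G = np.array([[0.0, 1.0], [1.0, 2.0], [1.0, 0.0]])
        chrom = np.array(["X", "1"])
        out = recode_x_males(G, chrom, is_male=np.array([True, False, True]))
        np.testing.assert_array_equal(out[:, 0], [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(out[:, 1], G[:, 1])

    def test_monomorphic_snp_flagged(self):
        rng = np.random.default_rng(5)
        G = np.column_stack([np.ones(50), rng.binomial(2, 0.4, 50)]).astype(float)
        C = pd.DataFrame({"age": rng.uniform(5, 15, 50)})
        with pytest.warns(UserWarning):
            _, tested = residualize_genotypes(G, C)
        assert not tested[0] and tested[1]


class TestMeta:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_single_cohort_passthrough(self):
        rows = [{"snp_id": "s1", "trait_id": 1, "beta": 0.4, "se": 0.1, "p": 1e-4, "n": 100, "cohort": "a", "chrom": "1", "pos": 10}]
        meta = ivw_meta(self._frame(rows))
        assert meta["beta_meta"].iloc[0] == pytest.approx(0.4)
        assert meta["se_meta"].iloc[0] == pytest.approx(0.1)

    def test_equal_cohorts_shrink_se_sqrt2(self):
        rows = [
            {"snp_id": "s1", "trait_id": 1, "beta": 0.4, "se": 0.1, "p": 1e-4, "n": 100, "cohort": c, "chrom": "1", "pos": 10}
            for c in ("a", "b")
        ]
        meta = ivw_meta(self._frame(rows))
        assert meta["beta_meta"].iloc[0] == pytest.approx(0.4)
        assert meta["se_meta"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))

    def test_k_copies_shrink_se_sqrt_k(self):
        K = 5
        rows = [
            {"snp_id": "s1", "trait_id": 1, "beta": 0.2, "se": 0.05, "p": 1e-4, "n": 100, "cohort": f"c{k}", "chrom": "1", "pos": 10}
            for k in range(K)
        ]
        meta = ivw_meta(self._frame(rows))
        assert meta["se_meta"].iloc[0] == pytest.approx(0.05 / np.sqrt(K), abs=1e-12)

    def test_hand_computed_weights(self):
        rows = [
            {"snp_id": "s1", "trait_id": 1, "beta": 0.5, "se": 0.1, "p": 1e-4, "n": 100, "cohort": "a", "chrom": "1", "pos": 10},
            {"snp_id": "s1", "trait_id": 1, "beta": 0.1, "se": 0.2, "p": 0.3, "n": 100, "cohort": "b", "chrom": "1", "pos": 10},
        ]
        meta = ivw_meta(self._frame(rows))
        assert meta["beta_meta"].iloc[0] == pytest.approx(0.42)
        assert meta["se_meta"].iloc[0] == pytest.approx(1 / np.sqrt(125))

    def test_stouffer_option(self):
        rows = [
            {"snp_id": "s1", "trait_id": 1, "beta": 0.5, "se": 0.1, "p": 1e-4, "n": 100, "cohort": "a", "chrom": "1", "pos": 10},
            {"snp_id": "s1", "trait_id": 1, "beta": 0.4, "se": 0.1, "p": 1e-3, "n": 200, "cohort": "b", "chrom": "1", "pos": 10},
        ]
        meta = ivw_meta(self._frame(rows), method="stouffer")
        assert 0 < meta["p_meta"].iloc[0] < 1e-3


class TestThresholds:
    def test_meff_322_reproduces_study_wide(self):
        gw, sw = significance_thresholds(322)
        assert gw == 5e-8
        assert float(f"{sw:.3g}") == pytest.approx(1.55e-10)

    @pytest.mark.parametrize("meff,expected", [(1, 5e-8), (10, 5e-9)])
    def test_simple_divisions(self, meff, expected):
        assert significance_thresholds(meff)[1] == pytest.approx(expected)


class TestPeaks:
    def _meta(self, entries):
        return pd.DataFrame(
            [
                {"snp_id": s, "chrom": c, "pos": p, "trait_id": t, "p_meta": pv}
                for s, c, p, t, pv in entries
            ]
        )

    def test_single_snp_single_peak(self):
        peaks = group_peaks(self._meta([("s1", "1", 1000, 1, 1e-9)]))
        assert len(peaks) == 1 and peaks[0].lead_snp == "s1"

    def test_greedy_window_grouping(self):
        meta = self._meta(
            [
                ("a", "1", 1_000_000, 1, 1e-9),
                ("b", "1", 1_400_000, 1, 1e-10),
                ("c", "1", 3_000_000, 1, 1e-9),
            ]
        )
        peaks = group_peaks(meta)
        assert len(peaks) == 2
        assert peaks[0].lead_snp == "b"
        assert set(peaks[0].member_snps) == {"a", "b"}

    def test_chromosomes_never_share_peaks(self):
        meta = self._meta([("a", "1", 100, 1, 1e-9), ("b", "2", 100, 1, 1e-9)])
        peaks = group_peaks(meta)
        assert len(peaks) == 2

    def test_order_invariance_and_idempotence(self):
        entries = [
            ("a", "1", 1_000_000, 1, 1e-9),
            ("b", "1", 1_400_000, 2, 1e-10),
            ("c", "2", 500_000, 1, 1e-12),
            ("d", "2", 600_000, 1, 1e-8 / 2),
        ]
        meta = self._meta(entries)
        shuffled = meta.sample(frac=1, random_state=3).reset_index(drop=True)
        p1 = group_peaks(meta)
        p2 = group_peaks(shuffled)
        assert [(p.lead_snp, tuple(sorted(p.member_snps))) for p in p1] == [
            (p.lead_snp, tuple(sorted(p.member_snps))) for p in p2
        ]

    def test_subthreshold_snps_ignored(self):
        peaks = group_peaks(self._meta([("a", "1", 100, 1, 1e-6)]))
        assert peaks == []


class TestVarianceExplained:
    def test_noiseless_phenotype_r2_one(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.4, 200).astype(float)
        r2, joint = variance_explained(1.5 * x, x[:, None])
        assert r2[0] == pytest.approx(1.0)
        assert joint == pytest.approx(1.0)

    def test_planted_one_percent_variance(self):
        rng = np.random.default_rng(7)
        n = 5000
        maf = 0.3
        x = rng.binomial(2, maf, n).astype(float)
        xs = (x - x.mean()) / x.std()
        y = np.sqrt(0.01) * xs + np.sqrt(0.99) * rng.normal(size=n)
        r2, _ = variance_explained(y, x[:, None])
        assert 0.005 <= r2[0] <= 0.015

    def test_joint_at_least_max_single(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.3, size=(300, 4)).astype(float)
        y = X @ np.array([0.2, 0.0, 0.1, -0.3]) + rng.normal(size=300)
        r2, joint = variance_explained(y, X)
        assert joint >= r2.max() - 1e-10


class TestPlantedSignalRecovery:
    def test_causal_snp_is_top_hit(self):
        # a SNP explaining ~3% of trait variance at n = 3,000 should be the
        # most significant of 300 SNPs in (nearly) every replicate
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n, m = 3000, 300
            G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
            causal = 37
            xs = (G[:, causal] - G[:, causal].mean()) / G[:, causal].std()
            y = np.sqrt(0.03) * xs + np.sqrt(0.97) * rng.normal(size=n)
            table = regress_many(y, G)
            best = table.loc[table["p"].idxmin(), "snp_index"]
            hits += best == causal
        assert hits >= reps - 1
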