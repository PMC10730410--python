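"""Variant QC rules, logistic association vs oracles, lambda, BH, clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

import regeqtl as rq

from conftest import make_dataset


def carrier_dataset(n_case_carrier, n_case, n_ctrl_carrier, n_ctrl):
    """Binary-carrier dosage with the given 2x2 composition."""
    dosage = np.r_[
        np.ones(n_case_carrier), np.zeros(n_case - n_case_carrier),
        np.ones(n_ctrl_carrier), np.zeros(n_ctrl - n_ctrl_carrier),
    ]
    status = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
    return dosage, status


def logistic_mle_oracle(dosage, status, covariates=None):
    """Independent oracle: direct likelihood maximization via Nelder-Mead."""
    x = dosage[:, None] if covariates is None else np.column_stack(
        [dosage, covariates]
    )
    x = np.column_stack([x, np.ones(len(dosage))])

    def nll(beta):
        eta = x @ beta
        return float(np.sum(np.logaddexp(0, eta)) - status @ eta)

    best = minimize(nll, np.zeros(x.shape[1]), method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return best.x[0]


class TestVariantQC:
    def test_maf_at_threshold_fails(self):
        # MAF 0.04 <= 0.05 -> fail
        dose = np.r_[np.ones(8), np.zeros(92)][:, None]
        ds = make_dataset(dose, phenotype=np.r_[np.ones(50), np.zeros(50)])
        records, _ = rq.variant_qc(ds)
        assert records[0].maf == pytest.approx(0.04)
        assert "maf" in records[0].reasons and not records[0].passed

    def test_maf_just_above_threshold_passes(self):
        dose = np.r_[np.ones(12), np.zeros(88)][:, None]
        ds = make_dataset(dose, phenotype=np.r_[np.ones(50), np.zeros(50)])
        records, _ = rq.variant_qc(ds)
        assert records[0].maf == pytest.approx(0.06)
        assert records[0].passed

    def test_dp_masking_drives_call_rate_failure(self, rng):
        # 100 samples, 11 calls masked by DP=19 -> missing 0.11 > 0.1 -> fail
        dose = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        dp = np.full((100, 1), 40)
        dp[:11, 0] = 19
        gq = np.full((100, 1), 99)
        ds = make_dataset(dose, dp=dp, gq=gq)
        records, masked = rq.variant_qc(ds)
        assert np.isnan(masked.dosage[:11, 0]).all()
        assert records[0].call_rate == pytest.approx(0.89)
        assert "call_rate" in records[0].reasons

    def test_boundary_dp20_gq31_retained_gq30_masked(self, rng):
        dose = rng.binomial(2, 0.3, size=(4, 1)).astype(float)
        dp = np.array([[20], [19], [20], [20]])
        gq = np.array([[31], [31], [30], [99]])
        masked = rq.apply_call_mask(make_dataset(dose, dp=dp, gq=gq))
        assert not np.isnan(masked.dosage[0, 0])  # DP=20, GQ=31 kept
        assert np.isnan(masked.dosage[1, 0])      # DP=19 masked
        assert np.isnan(masked.dosage[2, 0])      # GQ=30 masked (strict >30)
        assert not np.isnan(masked.dosage[3, 0])

    def test_clean_common_variant_passes(self, rng):
        dose = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        ds = make_dataset(dose)
        records, _ = rq.variant_qc(ds)
        assert records[0].passed and records[0].reasons == ()

    def test_missing_quality_passthrough_warns(self, rng):
        ds = make_dataset(rng.binomial(2, 0.3, size=(50, 2)).astype(float))
        with pytest.warns(UserWarning, match="masking skipped"):
            rq.apply_call_mask(ds)


class TestLogisticFit:
    def test_two_by_two_closed_form_odds_ratio(self):
        # cases 30/70 carriers vs controls 15/85: OR = (30*85)/(70*15)
        dose, status = carrier_dataset(30, 100, 15, 100)
        res = rq.fit_additive_logistic(dose, status)
        expected_or = (30 * 85) / (70 * 15)
        assert res.or_ == pytest.approx(expected_or, abs=1e-6)
        assert res.beta == pytest.approx(np.log(expected_or), abs=1e-6)
        assert res.ci95[0] < res.or_ < res.ci95[1]

    def test_matches_likelihood_grid_oracle(self, rng):
        dose = rng.binomial(2, 0.3, size=300).astype(float)
        cov = rng.normal(size=(300, 2))
        eta = -0.3 + 0.5 * dose + 0.2 * cov[:, 0]
        status = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        res = rq.fit_additive_logistic(dose, status, cov)
        oracle_beta = logistic_mle_oracle(dose, status, cov)
        assert abs(res.beta - oracle_beta) < 1e-6

    def test_null_large_n_or_near_one(self, rng):
        dose = rng.binomial(2, 0.3, size=10_000).astype(float)
        status = rng.binomial(1, 0.5, size=10_000).astype(float)
        res = rq.fit_additive_logistic(dose, status)
        assert res.or_ == pytest.approx(1.0, abs=0.1)

    def test_perfect_separation_flagged(self):
        dose, status = carrier_dataset(50, 50, 0, 50)
        res = rq.fit_additive_logistic(dose, status)
        assert res.separation

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rq.fit_additive_logistic(
                np.ones(40), np.r_[np.ones(20), np.zeros(20)]
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rq.fit_additive_logistic(np.r_[np.ones(5), np.zeros(5)], np.ones(10))

    def test_missing_dosage_dropped(self, rng):
        dose, status = carrier_dataset(30, 100, 15, 100)
        dose_with_nan = np.r_[dose, [np.nan, np.nan]]
        status_ext = np.r_[status, [1.0, 0.0]]
        res = rq.fit_additive_logistic(dose_with_nan, status_ext)
        assert res.or_ == pytest.approx((30 * 85) / (70 * 15), abs=1e-6)


class TestInflation:
    def test_all_half_pvalues_give_lambda_one(self):
        stat = rq.genomic_inflation(np.full(101, 0.5))
        assert stat.lambda_gc == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null_lambda_near_one(self, rng):
        stat = rq.genomic_inflation(rng.uniform(size=100_000))
        assert stat.lambda_gc == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self, rng):
        p = rng.uniform(0.01, 1, size=5001)
        chi2 = stats.chi2.isf(p, 1)
        doubled_p = stats.chi2.sf(2 * chi2, 1)
        lam = rq.genomic_inflation(p).lambda_gc
        lam2 = rq.genomic_inflation(doubled_p).lambda_gc
        assert lam2 == pytest.approx(2 * lam, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rq.genomic_inflation(np.array([]))


class TestBHFDR:
    def test_hand_computed_step_up(self):
        # p*m/rank = [.04,.04,.04,.04] after cumulative minimum from the top
        q = rq.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_mixed(self):
        p = np.array([0.005, 0.04, 0.03, 0.9])
        # ranks by sorted p: .005*4/1=.02, .03*4/2=.06, .04*4/3=.0533->min .06? no:
        # sorted: .005,.03,.04,.9 -> adj .02,.06,.05333,.9 -> monotone from top:
        # .02,.05333,.05333,.9 ; mapped back to input order
        np.testing.assert_allclose(
            rq.bh_fdr(p), [0.02, 0.05333333, 0.05333333, 0.9], atol=1e-6
        )

    def test_single_and_degenerate_inputs(self):
        assert rq.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(rq.bh_fdr(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rq.bh_fdr(np.array([0.1, 1.5]))


class TestPairwiseR2:
    def test_identical_vectors(self, rng):
        a = rng.binomial(2, 0.4, 100).astype(float)
        assert rq.pairwise_r2(a, a) == pytest.approx(1.0)

    def test_allele_flip_sign_free(self, rng):
        a = rng.binomial(2, 0.4, 100).astype(float)
        assert rq.pairwise_r2(a, 2 - a) == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        a = rng.binomial(2, 0.4, 10_000).astype(float)
        b = rng.binomial(2, 0.4, 10_000).astype(float)
        assert rq.pairwise_r2(a, b) == pytest.approx(0.0, abs=0.01)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rq.pairwise_r2(np.ones(10), np.arange(10, dtype=float))


def results_frame(ds, pvals):
    return pd.DataFrame(
        {
            "variant_id": ds.variants["variant_id"],
            "contig": ds.variants["contig"],
            "pos": ds.variants["pos"],
            "alt": ds.variants["alt"],
            "beta": 0.1,
            "se": 0.1,
            "z": 1.0,
            "p": pvals,
        }
    )


class TestLDClump:
    def test_correlated_pair_one_clump_lowest_p_index(self, rng):
        a = rng.binomial(2, 0.4, 200).astype(float)
        ds = make_dataset(np.column_stack([a, a]))
        res = rq.ld_clump(results_frame(ds, [1e-6, 1e-5]), ds)
        assert res["clump_id"].nunique() == 1
        assert res.loc[res["p"] == 1e-6, "is_index"].all()
        assert not res.loc[res["p"] == 1e-5, "is_index"].any()

    def test_uncorrelated_all_indices(self, rng):
        dose = rng.binomial(2, 0.4, size=(2000, 4)).astype(float)
        ds = make_dataset(dose)
        res = rq.ld_clump(results_frame(ds, [0.1, 0.2, 0.3, 0.4]), ds)
        assert res["is_index"].all()
        assert res["clump_id"].nunique() == 4

    def test_greedy_chain_assignment(self, rng):
        # A-B r2 ~ 0.7, B-C r2 ~ 0.7, A-C low; p(A)<p(B)<p(C) -> {A,B}, {C}
        n = 5000
        a = rng.binomial(2, 0.5, n).astype(float)
        flip = rng.random(n) < 0.84
        b = np.where(flip, a, rng.binomial(2, 0.5, n)).astype(float)
        c = np.where(rng.random(n) < 0.84, b, rng.binomial(2, 0.5, n)).astype(float)
        assert rq.pairwise_r2(a, b) > 0.6 and rq.pairwise_r2(b, c) > 0.6
        assert rq.pairwise_r2(a, c) < 0.6
        ds = make_dataset(np.column_stack([a, b, c]))
        res = rq.ld_clump(results_frame(ds, [1e-8, 1e-6, 1e-4]), ds)
        assert res["clump_id"].tolist()[0] == res["clump_id"].tolist()[1]
        assert res["clump_id"].tolist()[2] != res["clump_id"].tolist()[0]
        assert res["is_index"].tolist() == [True, False, True]

    def test_fdr_computed_over_indices_only_after_clumping(self, rng):
        a = rng.binomial(2, 0.4, 500).astype(float)
        dose = np.column_stack([a, a, rng.binomial(2, 0.4, 500)])
        ds = make_dataset(dose.astype(float))
        res = rq.ld_clump(results_frame(ds, [1e-4, 5e-4, 0.9]), ds)
        idx = res[res["is_index"]]
        assert np.isnan(res.loc[~res["is_index"], "q"]).all()
        # BH over the 2 index p-values only (m=2, not 3)
        np.testing.assert_allclose(
            sorted(idx["q"]), sorted(rq.bh_fdr(idx["p"].to_numpy()))
        )
        assert (idx["q"] < 0.1).sum() == 1

    def test_output_invariant_to_input_row_order(self, rng):
        dose = rng.binomial(2, 0.4, size=(300, 6)).astype(float)
        dose[:, 1] = dose[:, 0]
        ds = make_dataset(dose)
        frame = results_frame(ds, [0.5, 1e-5, 0.2, 0.8, 1e-3, 0.4])
        res1 = rq.ld_clump(frame, ds).sort_values("variant_id")
        shuffled = frame.sample(frac=1, random_state=7)
        res2 = rq.ld_clump(shuffled, ds).sort_values("variant_id")
        assert res1["is_index"].tolist() == res2["is_index"].tolist()
        assert res1["significant"].tolist() == res2["significant"].tolist()
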