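"""LD pruning, PCA/ancestry, and relatedness estimation."""

import numpy as np
import pandas as pd
import pytest

import regeqtl as rq
from regeqtl import SimConfig
from regeqtl.sample_qc import pairwise_ibd

from conftest import make_dataset


class TestLDPrune:
    def test_duplicate_variants_keep_exactly_one(self, rng):
        a = rng.binomial(2, 0.4, size=50).astype(float)
        ds = make_dataset(np.column_stack([a, a]))
        kept = rq.ld_prune(ds, r2_threshold=0.2, window_size=10, step=5)
        assert len(kept) == 1

    def test_independent_variants_all_retained(self, rng):
        dose = rng.binomial(2, 0.4, size=(500, 8)).astype(float)
        ds = make_dataset(dose)
        kept = rq.ld_prune(ds, r2_threshold=0.2, window_size=8, step=4)
        assert len(kept) == 8

    def test_retained_block_matches_brute_force_pair_check(self, rng):
        # 5-variant block with induced correlation
        base = rng.binomial(2, 0.5, size=200).astype(float)
        dose = np.column_stack([
            base,
            np.where(rng.random(200) < 0.9, base, rng.binomial(2, 0.5, 200)),
            rng.binomial(2, 0.5, size=200),
            np.where(rng.random(200) < 0.8, base, rng.binomial(2, 0.5, 200)),
            rng.binomial(2, 0.5, size=200),
        ]).astype(float)
        ds = make_dataset(dose)
        kept = rq.ld_prune(ds, r2_threshold=0.2, window_size=5, step=5)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert rq.pairwise_r2(dose[:, a], dose[:, b]) <= 0.2

    def test_window_smaller_than_step_rejected(self, rng):
        ds = make_dataset(rng.binomial(2, 0.4, size=(20, 4)).astype(float))
        with pytest.raises(ValueError):
            rq.ld_prune(ds, window_size=2, step=5)


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        cfg = SimConfig(n_cases=5, n_controls=5, n_variants=500, n_genes=2, seed=0)
        panel = rq.simulate_reference_panel(cfg, n_per_pop=40,
                                            labels=("EUR", "AFR"), fst=0.3)
        scores, _ = rq.compute_pca(panel, k=2)
        pc1 = scores["PC1"].to_numpy()
        lab = panel.samples["population"].to_numpy()
        a, b = pc1[lab == "EUR"], pc1[lab == "AFR"]
        # zero overlap between the two label clusters at this divergence
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_projection_reproduces_training_scores(self, rng):
        dose = rng.binomial(2, rng.uniform(0.1, 0.5, 30),
                            size=(40, 30)).astype(float)
        ds = make_dataset(dose)
        scores, loadings = rq.compute_pca(ds, k=3)
        proj = rq.project(dose[5], scores, loadings)
        np.testing.assert_allclose(proj[0], scores.iloc[5].to_numpy(), atol=1e-8)

    def test_k_exceeding_samples_rejected(self, rng):
        ds = make_dataset(rng.binomial(2, 0.4, size=(5, 20)).astype(float))
        with pytest.raises(ValueError):
            rq.compute_pca(ds, k=10)

    def test_monomorphic_variants_dropped_with_warning(self, rng):
        dose = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        dose[:, 2] = 0.0  # monomorphic
        ds = make_dataset(dose)
        with pytest.warns(UserWarning, match="monomorphic"):
            scores, loadings = rq.compute_pca(ds, k=2)
        assert loadings.shape[0] == 4


class TestAncestry:
    @staticmethod
    def _reference(rng, k=10, n_per_pop=30, spread=0.05):
        labels = ["EUR", "AFR", "EAS", "AMR", "SAS"]
        cents = np.eye(5)[:, :5] @ np.eye(5, k) * 3.0
        rows, labs = [], []
        for i, lab in enumerate(labels):
            rows.append(cents[i] + rng.normal(0, spread, size=(n_per_pop, k)))
            labs.extend([lab] * n_per_pop)
        ref = pd.DataFrame(np.vstack(rows))
        return ref, pd.Series(labs), cents

    def test_sample_at_centroid_gets_weight_near_one(self, rng):
        ref, labels, cents = self._reference(rng)
        sample = pd.DataFrame([cents[0]], index=["X"])
        ests, retained = rq.estimate_ancestry(sample, ref, labels)
        assert ests[0].weight("EUR") > 0.99
        assert "X" in retained

    def test_midpoint_admixture_gets_half_half(self, rng):
        ref, labels, cents = self._reference(rng)
        mid = (cents[0] + cents[1]) / 2
        ests, _ = rq.estimate_ancestry(pd.DataFrame([mid], index=["X"]), ref, labels)
        assert ests[0].weight("EUR") == pytest.approx(0.5, abs=0.02)
        assert ests[0].weight("AFR") == pytest.approx(0.5, abs=0.02)

    def test_weights_form_a_distribution(self, rng):
        ref, labels, cents = self._reference(rng)
        pt = cents[0] * 0.7 + cents[2] * 0.4  # off-simplex target
        ests, _ = rq.estimate_ancestry(pd.DataFrame([pt], index=["X"]), ref, labels)
        w = np.array(list(ests[0].proportions.values()))
        assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)

    def test_european_weight_below_threshold_excluded(self, rng):
        ref, labels, cents = self._reference(rng)
        # construct a point whose EUR weight lands just below 0.90
        pt = 0.89 * cents[0] + 0.11 * cents[1]
        ests, retained = rq.estimate_ancestry(
            pd.DataFrame([pt], index=["X"]), ref, labels
        )
        assert ests[0].weight("EUR") == pytest.approx(0.89, abs=0.005)
        assert "X" not in retained

    def test_singular_covariance_suggests_ridge(self, rng):
        ref, labels, _ = self._reference(rng, spread=0.0)  # zero variance
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            rq.estimate_ancestry(pd.DataFrame([np.zeros(10)]), ref, labels)


class TestRelatedness:
    def test_duplicated_sample_pihat_near_one_and_removed(self, rng):
        afs = rng.uniform(0.2, 0.5, 2000)
        dose = rng.binomial(2, afs, size=(6, 2000)).astype(float)
        dose[5] = dose[0]  # duplicate
        ds = make_dataset(dose)
        retained, flagged = rq.remove_relateds(ds, seed=1, freqs=afs)
        dup = [e for e in flagged if {e.sample_a, e.sample_b} == {"S000", "S005"}]
        assert dup and dup[0].pihat > 0.9
        assert len(retained) == 5
        assert {"S000", "S005"} - set(retained)  # exactly one copy removed

    def test_parent_offspring_pihat_half(self, rng):
        m = 10_000
        afs = rng.uniform(0.2, 0.5, m)
        parent1 = rng.binomial(2, afs, size=m).astype(float)
        parent2 = rng.binomial(2, afs, size=m).astype(float)
        # Mendelian transmission: one allele from each parent
        child = (
            (rng.random(m) < parent1 / 2).astype(float)
            + (rng.random(m) < parent2 / 2).astype(float)
        )
        ds = make_dataset(np.vstack([parent1, child]))
        est = pairwise_ibd(ds, freqs=afs)[0]
        assert est.pihat == pytest.approx(0.5, abs=0.05)

    def test_unrelated_samples_pihat_near_zero(self, rng):
        afs = rng.uniform(0.2, 0.5, 5000)
        dose = rng.binomial(2, afs, size=(4, 5000)).astype(float)
        ds = make_dataset(dose)
        for est in pairwise_ibd(ds, freqs=afs):
            assert est.pihat == pytest.approx(0.0, abs=0.05)

    def test_no_retained_pair_exceeds_threshold(self, rng):
        # small pedigree: two founders, their child, one unrelated
        m = 4000
        afs = rng.uniform(0.2, 0.5, m)
        p1 = rng.binomial(2, afs, size=m).astype(float)
        p2 = rng.binomial(2, afs, size=m).astype(float)
        child = (
            (rng.random(m) < p1 / 2).astype(float)
            + (rng.random(m) < p2 / 2).astype(float)
        )
        other = rng.binomial(2, afs, size=m).astype(float)
        ds = make_dataset(np.vstack([p1, p2, child, other]))
        retained, _ = rq.remove_relateds(ds, pihat_threshold=0.12, seed=0,
                                         freqs=afs)
        sub = ds.subset_samples(retained)
        for est in pairwise_ibd(sub, freqs=afs):
            assert est.pihat <= 0.12

    def test_fewer_than_two_samples_noop(self, rng):
        ds = make_dataset(rng.binomial(2, 0.3, size=(1, 50)).astype(float))
        retained, flagged = rq.remove_relateds(ds)
        assert list(retained) == ["S000"] and flagged == []
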