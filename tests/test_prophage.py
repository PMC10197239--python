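"""Insulation borders, prophage refinement, 3D signatures, classification."""

import numpy as np
import pytest

import phicmap as pm
from phicmap.contact import ContactMatrix, ice_balance
from phicmap.prophage import (
    Border,
    InsulationProfile,
    ProphageRecord,
    SignatureThresholds,
    classify_prophage,
    detect_borders,
    insulation_profile,
    refine_prophage,
    signature_scores,
)
from phicmap.synthetic import ProphageSpec, SyntheticTruth, contact_weight_matrix


def balanced_from_weights(truth, bin_size, **kw):
    """Infinite-data limit: balance the exact sampling weights."""
    w = contact_weight_matrix(truth, bin_size, 1.0, **kw)
    m = ContactMatrix("w", bin_size, w, w.sum(), replicon_length=truth.genome_length)
    return ice_balance(m, max_iter=1000, tol=1e-10)


class TestInsulation:
    def test_constant_matrix_all_zero(self, constant_balanced):
        prof = insulation_profile(constant_balanced, window=3)
        assert prof.scores.size == constant_balanced.n_bins
        assert np.allclose(prof.scores, 0.0, atol=1e-12)

    def test_two_domain_boundary_is_minimum(self):
        # block-diagonal: within 2, between 0.5 -> unique minimum at boundary
        n, cut = 40, 20
        a = np.full((n, n), 0.5)
        a[:cut, :cut] = 2.0
        a[cut:, cut:] = 2.0
        m = ContactMatrix("x", 1_000, a, a.sum(), balanced=True)
        prof = insulation_profile(m, window=4)
        # circular wrap joins the two blocks at 0 as well; the interior
        # boundary must be the minimum away from the wrap point
        interior = prof.scores[5 : n - 5]
        assert int(np.argmin(interior)) + 5 == cut

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random((30, 30)) + 0.5
        a = (a + a.T) / 2
        m1 = ContactMatrix("x", 1, a, a.sum(), balanced=True)
        m2 = ContactMatrix("x", 1, 10 * a, 10 * a.sum(), balanced=True)
        p1 = insulation_profile(m1, 3)
        p2 = insulation_profile(m2, 3)
        assert np.allclose(p1.scores, p2.scores)

    def test_window_too_large_rejected(self, constant_balanced):
        with pytest.raises(ValueError, match="window"):
            insulation_profile(constant_balanced, window=constant_balanced.n_bins // 2)

    def test_masked_bins_propagate(self):
        a = np.full((20, 20), 2.0)
        masked = np.zeros(20, dtype=bool)
        masked[7] = True
        m = ContactMatrix("x", 1, a, a.sum(), balanced=True, masked=masked)
        prof = insulation_profile(m, 3)
        assert np.isnan(prof.scores[7])
        assert np.isnan(prof.scores[5])  # window touches the masked bin


class TestDetectBorders:
    def test_constant_profile_empty(self):
        prof = InsulationProfile(np.zeros(50), window=3)
        assert detect_borders(prof, 0.2) == []

    def test_single_v_minimum(self):
        s = np.zeros(50)
        s[20] = -1.0
        s[19] = s[21] = -0.4
        borders = detect_borders(InsulationProfile(s, 3), min_prominence=0.2)
        assert [b.bin for b in borders] == [20]
        assert borders[0].prominence == pytest.approx(1.0)

    def test_prominence_threshold(self):
        s = np.zeros(50)
        s[10] = -0.1  # shallow dip below threshold
        s[30] = -0.8
        borders = detect_borders(InsulationProfile(s, 3), min_prominence=0.2)
        assert [b.bin for b in borders] == [30]

    def test_circular_minimum_at_origin(self):
        s = np.zeros(50)
        s[0] = -1.0
        s[49] = s[1] = -0.3
        borders = detect_borders(InsulationProfile(s, 3), 0.2)
        assert [b.bin for b in borders] == [0]

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 0.05, 80)
        for b in (10, 40, 66):
            s[b] -= 1.0
        r = 23
        b0 = {b.bin for b in detect_borders(InsulationProfile(s, 3), 0.3)}
        b1 = {b.bin for b in detect_borders(InsulationProfile(np.roll(s, r), 3), 0.3)}
        assert b1 == {(b + r) % 80 for b in b0}


class TestRefineProphage:
    BORDERS = [Border(b, 1.0) for b in (95, 110, 190, 205)]

    def test_closest_border_rule(self):
        iv, status, l, r = refine_prophage(
            (100_000, 200_000), self.BORDERS, 1_000, 1_000_000, max_shift=20_000
        )
        assert iv == (95_000, 205_000)
        assert status == "refined" and l and r

    def test_far_borders_keep_prediction(self):
        iv, status, l, r = refine_prophage(
            (100_000, 200_000), [Border(150, 1.0)], 1_000, 1_000_000, max_shift=20_000
        )
        assert iv == (100_000, 200_000)
        assert status == "unrefined" and not l and not r

    def test_idempotent(self):
        iv1, *_ = refine_prophage((100_000, 200_000), self.BORDERS, 1_000, 1_000_000, 20_000)
        iv2, status, *_ = refine_prophage(iv1, self.BORDERS, 1_000, 1_000_000, 20_000)
        assert iv2 == iv1 and status == "refined"

    def test_empty_borders_unrefined(self):
        iv, status, *_ = refine_prophage((10, 20), [], 1_000, 1_000_000)
        assert iv == (10, 20) and status == "unrefined"

    def test_collapse_returns_failed(self):
        # both predicted borders snap to the same detected border
        iv, status, *_ = refine_prophage(
            (99_000, 101_000), [Border(100, 1.0)], 1_000, 1_000_000, max_shift=5_000
        )
        assert status == "failed" and iv == (99_000, 101_000)


class TestSignatureScores:
    def test_constant_matrix_all_one(self, constant_balanced):
        d, l, dep = signature_scores(constant_balanced, (5_000, 15_000))
        assert d == pytest.approx(1.0)
        assert l == pytest.approx(1.0)
        assert dep == pytest.approx(1.0)

    def test_implanted_block_matches_weight_oracle(self):
        # enriched 2x block over unit background; the sampled-matrix score
        # must agree with the infinite-data (exact-weight) oracle
        from phicmap.synthetic import simulate_contact_pairs

        truth = SyntheticTruth(
            genome_length=2_000_000, ori_pos=0, ter_pos=1_000_000,
            domain_boundaries=[900_000, 1_000_000],
        )
        factors = [1.0, 2.0]
        oracle = balanced_from_weights(truth, 10_000, domain_factor=factors)
        d_oracle, *_ = signature_scores(oracle, (900_000, 1_000_000))
        pairs = simulate_contact_pairs(truth, 1_000_000, 1.0, 10_000, seed=0,
                                       domain_factor=factors)
        bal = ice_balance(pm.bin_pairs(pairs, 10_000))
        d_sim, *_ = signature_scores(bal, (900_000, 1_000_000))
        # balancing absorbs part of the block's marginal excess, so the
        # balanced-map contrast sits below the implanted 2x; the sampled
        # matrix must agree with the exact-weight limit
        assert d_oracle > 1.2
        assert d_sim == pytest.approx(d_oracle, rel=0.1)

    def test_implanted_corner_loop(self):
        from phicmap.synthetic import simulate_contact_pairs

        truth = SyntheticTruth(
            genome_length=2_000_000, ori_pos=0, ter_pos=1_000_000,
            prophage_specs=[ProphageSpec(800_000, 850_000, induced=True,
                                         loop_strength=5.0, name="p")],
        )
        pairs = simulate_contact_pairs(truth, 1_000_000, 1.0, 10_000, seed=1)
        bal = ice_balance(pm.bin_pairs(pairs, 10_000))
        _, loop, _ = signature_scores(bal, (800_000, 850_000))
        assert loop > 3.0

    def test_short_interval_rejected(self, constant_balanced):
        with pytest.raises(ValueError, match="2 bins"):
            signature_scores(constant_balanced, (100, 900))


class TestCoverageRatio:
    def test_uniform_coverage_is_one(self):
        cov = pm.coverage_profile(np.arange(0, 100_000, 10), 100_000, 10_000)
        assert pm.coverage_ratio(cov, (20_000, 40_000)) == pytest.approx(1.0)

    def test_doubled_interval_depth(self):
        pos = list(np.arange(0, 100_000, 10)) + list(np.arange(20_000, 40_000, 10))
        cov = pm.coverage_profile(np.array(pos), 100_000, 10_000)
        assert pm.coverage_ratio(cov, (20_000, 40_000)) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 100_000, 20_000)
        cov1 = pm.coverage_profile(pos, 100_000, 10_000)
        cov2 = pm.coverage_profile(np.repeat(pos, 3), 100_000, 10_000)
        r1 = pm.coverage_ratio(cov1, (30_000, 60_000))
        r2 = pm.coverage_ratio(cov2, (30_000, 60_000))
        assert r1 == pytest.approx(r2)

    def test_zero_median_rejected(self):
        cov = pm.coverage_profile([5], 100_000, 1_000)
        with pytest.raises(ValueError, match="median"):
            pm.coverage_ratio(cov, (0, 10_000))


class TestClassify:
    def rec(self, d=1.0, l=1.0, dep=1.0, both=True):
        r = ProphageRecord("c", "p", (0, 10_000))
        r.domain_score, r.loop_score, r.depletion_score = d, l, dep
        r.left_refined = r.right_refined = both
        return r

    def test_neutral_scores_not_functional(self):
        r = classify_prophage(self.rec())
        assert r.signature_labels == set() and not r.functional_call

    def test_domain_with_borders_is_cid_like(self):
        r = classify_prophage(self.rec(d=2.0))
        assert r.signature_labels == {"CID-like"} and r.functional_call

    def test_domain_without_borders_not_cid_like(self):
        r = classify_prophage(self.rec(d=2.0, both=False))
        assert "CID-like" not in r.signature_labels

    def test_loop_and_depletion_thresholds(self):
        r = classify_prophage(self.rec(l=2.5, dep=0.5))
        assert r.signature_labels == {"loop", "depletion"}

    def test_custom_thresholds(self):
        t = SignatureThresholds(t_domain=3.0, t_loop=10.0, t_depletion=0.1)
        r = classify_prophage(self.rec(d=2.0, l=2.5), t)
        assert not r.functional_call

    def test_consortium_calls_match_truth(self, consortium):
        truth = consortium["truth"]
        bal = consortium["balanced"]
        borders = consortium["borders"]
        length = truth.genome_length
        calls = {}
        for p in truth.prophage_specs:
            iv, status, l_ok, r_ok = refine_prophage(
                (p.start, p.end), borders, consortium["bin_size"], length, max_shift=20_000
            )
            r = ProphageRecord("c", p.name, (p.start, p.end), refined=iv,
                               refine_status=status, left_refined=l_ok, right_refined=r_ok)
            r.domain_score, r.loop_score, r.depletion_score = signature_scores(bal, r.interval)
            classify_prophage(r)
            calls[p.name] = r.functional_call
        expected = {p.name: (p.induced or p.loop_strength > 1) for p in truth.prophage_specs}
        assert calls == expected
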