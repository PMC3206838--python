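"""Weight fit and the Information Ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irstab import (
    IRResult,
    WeightModel,
    fit_lambda,
    information_ratio,
    ir_dimension_scan,
    ir_for_contrast,
)
from irstab.diffexpr import DifferentialResult
from irstab.io_prep import ValidationError
from irstab.simdata import SimConfig, simulate_study

from conftest import make_contrast, noise_study


def de_from_lp(lp_proj, lp_resid, lp_orig=None, name="toy"):
    lp_proj = np.asarray(lp_proj, float)
    lp_resid = np.asarray(lp_resid, float)
    lp_orig = np.zeros_like(lp_proj) if lp_orig is None else np.asarray(lp_orig, float)
    return DifferentialResult(
        gene_ids=[f"g{i}" for i in range(lp_proj.size)],
        p_orig=10.0**lp_orig, p_proj=10.0**lp_proj, p_resid=10.0**lp_resid,
        lp_orig=lp_orig, lp_proj=lp_proj, lp_resid=lp_resid,
        method="welch_t", contrast_name=name,
    )


def wm_from_weights(w):
    w = np.asarray(w, float)
    return WeightModel(lambda_=0.0, n_bins=50, bin_edges=np.array([0.0, 1.0]),
                       bin_ratios=np.array([1.0]), weights=w)


class TestFitLambda:
    def test_exact_on_geometric_histogram(self):
        # counts halve per bin over 5 equidistant bins of width 0.9, so the
        # log-ratio is exactly linear with slope -ln(2)/0.9
        vals = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        counts = np.array([256, 128, 64, 32, 16])
        lp = -np.repeat(vals, counts)
        wm = fit_lambda(lp, n_bins=5)
        assert wm.lambda_ == pytest.approx(np.log(2) / 0.9, abs=1e-10)
        assert np.allclose(wm.weights, np.exp(wm.lambda_ * np.abs(lp)))

    def test_recovers_exponential_rate(self):
        rng = np.random.default_rng(42)
        lp = -rng.exponential(1 / 1.5, 20000)
        lam = fit_lambda(lp).lambda_
        assert 1.35 <= lam <= 1.65

    def test_bin_ratios_sum_to_one(self):
        rng = np.random.default_rng(1)
        wm = fit_lambda(-rng.exponential(1.0, 500))
        assert np.sum(wm.bin_ratios) == pytest.approx(1.0, abs=1e-12)

    def test_single_occupied_bin_errors(self):
        with pytest.raises(ValidationError, match="occupied"):
            fit_lambda(np.full(200, -2.0))

    def test_all_p_one_errors(self):
        with pytest.raises(ValidationError, match="undefined"):
            fit_lambda(np.zeros(200))

    def test_too_few_genes(self):
        with pytest.raises(ValidationError, match="100 genes"):
            fit_lambda(-np.ones(50))

    def test_positive_lp_rejected(self):
        with pytest.raises(ValidationError):
            fit_lambda(np.array([0.1] + [-1.0] * 200))

    def test_weight_per_bin_roughly_constant(self):
        """Matched exponential weights equalize total weight across bins."""
        rng = np.random.default_rng(7)
        lam = 1.2
        lp = -rng.exponential(1 / lam, 50000)
        wm = fit_lambda(lp)
        a = np.abs(lp)
        idx = np.clip(np.digitize(a, wm.bin_edges) - 1, 0, wm.n_bins - 1)
        totals = np.bincount(idx, weights=wm.weights, minlength=wm.n_bins)
        # compare bins holding the bulk of the distribution
        core = totals[:25]
        assert core.max() / core.min() < 1.0 + 0.2 * 2  # within ~20% of flat


class TestInformationRatio:
    def test_equal_lp_gives_half(self):
        de = de_from_lp([-2, -1, -3], [-2, -1, -3])
        assert information_ratio(de, wm_from_weights([5, 1, 2])).ir == pytest.approx(0.5)

    def test_all_information_projected_gives_zero(self):
        de = de_from_lp([-3, -5, -2], [0, 0, 0])
        res = information_ratio(de, wm_from_weights([1, 1, 1]))
        assert res.ir == 0.0
        assert res.type_label == "type1_low"

    def test_all_information_residual_gives_one(self):
        de = de_from_lp([0, 0, 0], [-3, -5, -2])
        res = information_ratio(de, wm_from_weights([1, 1, 1]))
        assert res.ir == 1.0
        assert res.type_label == "type2_3_high"

    def test_hand_computed_toy(self):
        de = de_from_lp([-4, -1, 0], [-1, -1, -2])
        res = information_ratio(de, wm_from_weights([2, 1, 1]))
        assert res.ir == pytest.approx(0.475)

    def test_uninformative_genes_excluded(self):
        de = de_from_lp([-4, 0, 0], [-1, 0, 0])
        res = information_ratio(de, wm_from_weights([1, 100, 100]))
        assert res.ir == pytest.approx(0.2)
        assert res.n_genes_used == 1

    def test_all_uninformative_errors(self):
        de = de_from_lp([0, 0], [0, 0])
        with pytest.raises(ValidationError, match="no informative"):
            information_ratio(de, wm_from_weights([1, 1]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ir_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 50)
        lp_p = -rng.exponential(1.0, n)
        lp_r = -rng.exponential(1.0, n)
        w = rng.uniform(0.1, 10.0, n)
        de = de_from_lp(lp_p, lp_r)
        ir = information_ratio(de, wm_from_weights(w)).ir
        assert 0.0 <= ir <= 1.0
        # swapping the spaces reflects the statistic
        ir_swap = information_ratio(de_from_lp(lp_r, lp_p), wm_from_weights(w)).ir
        assert ir_swap == pytest.approx(1.0 - ir, abs=1e-12)
        # uniform weight rescaling is a no-op
        ir_scaled = information_ratio(de, wm_from_weights(w * 37.5)).ir
        assert ir_scaled == pytest.approx(ir, abs=1e-12)


class TestIRPipeline:
    def test_subspace_signal_low_ir(self):
        study, contrast, _ = simulate_study(SimConfig(signal_mode="subspace", seed=1))
        res = ir_for_contrast(study, contrast, n=4)
        assert res.ir <= 0.25
        assert res.type_label == "type1_low"

    def test_residual_signal_high_ir(self):
        study, contrast, _ = simulate_study(SimConfig(signal_mode="residual", seed=1))
        res = ir_for_contrast(study, contrast, n=4)
        assert res.ir >= 0.5
        assert res.type_label == "type2_3_high"

    def test_no_signal_ir_away_from_extremes(self):
        """With no class signal, neither space dominates completely.

        The residual space holds most sample-space directions, so the null IR
        sits above one half; Monte-Carlo over 20 seeds of label-free noise
        puts it between roughly 0.55 and 0.9.
        """
        irs = []
        for seed in range(1, 21):
            st = noise_study(2000, 100, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            labels = rng.permutation([1, 2] * 50)
            irs.append(ir_for_contrast(st, make_contrast(st, labels), n=4).ir)
        irs = np.array(irs)
        assert np.all((irs > 0.3) & (irs < 0.95))
        assert 0.55 <= irs.mean() <= 0.9

    def test_scan_single_n_matches_direct_call(self):
        study, contrast, _ = simulate_study(
            SimConfig(signal_mode="subspace", n_genes=400, n_samples=40, seed=3))
        scan = ir_dimension_scan(study, contrast, [4])
        direct = ir_for_contrast(study, contrast, n=4)
        assert len(scan) == 1 and scan[0][0] == 4
        assert scan[0][1].ir == pytest.approx(direct.ir, abs=1e-12)

    def test_scan_on_noise_is_total(self):
        st = noise_study(500, 40, seed=31)
        labels = np.array([1, 2] * 20)
        scan = ir_dimension_scan(st, make_contrast(st, labels), range(1, 6))
        assert [n for n, _ in scan] == [1, 2, 3, 4, 5]
        assert all(np.isfinite(r.ir) for _, r in scan)

    def test_scan_rejects_excessive_n(self):
        st = noise_study(100, 10, seed=32)
        labels = np.array([1, 2] * 5)
        with pytest.raises(ValidationError, match="exceeds"):
            ir_dimension_scan(st, make_contrast(st, labels), [12])

    def test_weight_source_option(self):
        study, contrast, _ = simulate_study(
            SimConfig(signal_mode="residual", n_genes=500, n_samples=60, seed=4))
        r1 = ir_for_contrast(study, contrast, n=4, weight_source="orig")
        r2 = ir_for_contrast(study, contrast, n=4, weight_source="min_pr_pp")
        assert 0 <= r1.ir <= 1 and 0 <= r2.ir <= 1
        assert r1.ir != r2.ir  # different weighting bases
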