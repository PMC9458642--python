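import numpy as np
import pytest

from clonosurv import (
    FitOptions,
    IRModel,
    IRParams,
    LQParams,
    ParamEstimate,
    SurvivalDataset,
    fit_ir_single,
    fit_lq,
    lq_survival,
    run_ir_cascade,
    select_lq_subset,
    weights_from_whiskers,
)
from clonosurv.fitting import sigmas_from_whiskers

from conftest import TRUTH_IR


def _dataset(doses, sf, half=None, **kw):
    doses = np.asarray(doses, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if half is None:
        return SurvivalDataset.from_arrays(doses, sf, **kw)
    half = np.broadcast_to(np.asarray(half, dtype=float), sf.shape)
    return SurvivalDataset.from_arrays(doses, sf, sf - half, sf + half, **kw)


class TestSelectLQSubset:
    def test_points_above_one_gray(self):
        ds = _dataset([0.2, 0.5, 1.5, 2, 4], [0.9, 0.8, 0.5, 0.4, 0.1])
        idx = select_lq_subset(ds)
        assert [ds.points[i].dose for i in idx] == [1.5, 2, 4]

    def test_three_highest_fallback_below_one_gray(self):
        ds = _dataset([0.1, 0.3, 0.5, 0.8], [0.95, 0.9, 0.85, 0.8])
        idx = select_lq_subset(ds)
        assert [ds.points[i].dose for i in idx] == [0.3, 0.5, 0.8]

    def test_fallback_engaged_with_two_high_points(self):
        ds = _dataset([0.5, 1.2, 3.0], [0.9, 0.6, 0.2])
        idx = select_lq_subset(ds)
        assert [ds.points[i].dose for i in idx] == [0.5, 1.2, 3.0]


class TestWhiskerWeights:
    def test_half_span_inverse_variance(self):
        ds = _dataset([1, 2, 3], [0.5, 0.4, 0.3], half=0.10)
        assert np.allclose(weights_from_whiskers(ds), 100.0)

    def test_uniform_scaling_leaves_fit_unchanged(self, noisy_dataset):
        fit_a = fit_lq(noisy_dataset, FitOptions(weighting="whiskers"))
        scaled = SurvivalDataset.from_arrays(
            noisy_dataset.dose,
            noisy_dataset.sf,
            noisy_dataset.sf - 3 * (noisy_dataset.sf - noisy_dataset.whisker_min),
            noisy_dataset.sf + 3 * (noisy_dataset.whisker_max - noisy_dataset.sf),
        )
        fit_b = fit_lq(scaled, FitOptions(weighting="whiskers"))
        for name in ("alpha", "beta"):
            assert fit_a.params[name] == pytest.approx(fit_b.params[name], rel=1e-6)

    def test_zero_span_point_gets_median_sigma(self):
        ds = SurvivalDataset.from_arrays(
            [1.0, 2.0, 3.0],
            [0.5, 0.4, 0.3],
            [0.45, 0.40, 0.26],
            [0.55, 0.40, 0.34],
        )
        sigma = sigmas_from_whiskers(ds)
        assert sigma[1] == pytest.approx(np.median([0.05, 0.04]))

    def test_all_zero_spans_rejected(self):
        ds = SurvivalDataset.from_arrays(
            [1.0, 2.0, 3.0], [0.5, 0.4, 0.3], [0.5, 0.4, 0.3], [0.5, 0.4, 0.3]
        )
        with pytest.raises(ValueError):
            weights_from_whiskers(ds)


class TestLQFit:
    def test_noise_free_recovery(self):
        truth = LQParams(0.3, 0.05)
        doses = np.arange(1.5, 6.5, 0.5)
        ds = _dataset(doses, lq_survival(doses, truth))
        fit = fit_lq(ds, FitOptions(weighting="none"))
        assert fit.converged
        assert fit.params["alpha"] == pytest.approx(0.3, rel=1e-6)
        assert fit.params["beta"] == pytest.approx(0.05, rel=1e-6)

    def test_underdetermined_subset_rejected(self):
        ds = _dataset([2.0, 3.0, 4.0], [0.5, 0.3, 0.15])
        with pytest.raises(ValueError):
            fit_lq(ds, FitOptions(weighting="none"), subset=[0, 1])

    def test_point_order_invariance(self, noisy_dataset):
        shuffled = SurvivalDataset(
            points=tuple(reversed(noisy_dataset.points)), meta=noisy_dataset.meta
        )
        a = fit_lq(noisy_dataset)
        b = fit_lq(shuffled)
        assert a.params == pytest.approx(b.params)

    def test_matches_brute_force_grid_oracle(self, small_lq_dataset):
        """The weighted LQ optimum agrees with an independent
        grid-refinement minimizer of the same chi-square objective."""
        ds = small_lq_dataset
        fit = fit_lq(ds, FitOptions(weighting="whiskers"), subset="all")
        assert fit.converged

        sigma = (ds.whisker_max - ds.whisker_min) / 2.0
        d, y = ds.dose, ds.sf

        def objective(a, b):
            return np.sum(((np.exp(-a * d - b * d * d) - y) / sigma) ** 2)

        a_lo, a_hi, b_lo, b_hi = -1.0, 1.0, -0.5, 0.5
        best = None
        for _ in range(12):
            grid_a = np.linspace(a_lo, a_hi, 41)
            grid_b = np.linspace(b_lo, b_hi, 41)
            vals = np.array([[objective(a, b) for b in grid_b] for a in grid_a])
            ia, ib = np.unravel_index(np.argmin(vals), vals.shape)
            best = (grid_a[ia], grid_b[ib])
            da = (a_hi - a_lo) / 40
            db = (b_hi - b_lo) / 40
            a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
            b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
        assert fit.params["alpha"] == pytest.approx(best[0], abs=1e-3)
        assert fit.params["beta"] == pytest.approx(best[1], abs=1e-3)


class TestIRSingleFit:
    def test_noise_free_recovery_from_anchor_init(self, noise_free_dataset):
        model = IRModel(noise_free_dataset)
        _, init, options = model.cascade_plan(published=None)[0]
        fit = model.fit(init, options)
        assert fit.converged
        for name, truth in TRUTH_IR.as_dict().items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-4)

    def test_log_and_linear_space_agree_on_noise_free_data(self, noise_free_dataset):
        lin = fit_ir_single(noise_free_dataset, TRUTH_IR, FitOptions(weighting="none"))
        log = fit_ir_single(
            noise_free_dataset, TRUTH_IR, FitOptions(weighting="none", space="log")
        )
        for name in TRUTH_IR.as_dict():
            assert lin.params[name] == pytest.approx(log.params[name], rel=1e-6)

    def test_fixed_parameter_contract(self, noisy_dataset):
        fit = fit_ir_single(noisy_dataset, TRUTH_IR, FitOptions(fixed={"beta": 0.0}))
        assert fit.params["beta"] == 0.0
        assert fit.bse["beta"] is None

    def test_odr_backend_recovers_noise_free_truth(self, noise_free_dataset):
        fit = fit_ir_single(
            noise_free_dataset, TRUTH_IR, FitOptions(weighting="none", algorithm="odr")
        )
        assert fit.converged
        for name, truth in TRUTH_IR.as_dict().items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-3)

    def test_too_few_points_rejected(self):
        doses = [0.5, 1.0, 2.0, 4.0]
        ds = _dataset(doses, [0.8, 0.6, 0.35, 0.1])
        with pytest.raises(ValueError):
            fit_ir_single(ds, TRUTH_IR, FitOptions(weighting="none"))


class TestCascade:
    def test_truth_reproducible_at_step_one(self, noise_free_dataset):
        published = {
            k: ParamEstimate.from_se(v, 0.05 * abs(v))
            for k, v in TRUTH_IR.as_dict().items()
        }
        result = run_ir_cascade(noise_free_dataset, published)
        assert result.step_reached == 1
        assert result.reproduced is True

    def test_without_published_first_converged_is_canonical(self, noise_free_dataset):
        result = run_ir_cascade(noise_free_dataset)
        assert result.reproduced is None
        assert result.step_reached == 1
        assert result.canonical_fit.converged
        # only published-independent variants may appear in the plan
        labels = [label for label, _ in result.attempts]
        assert all(label in ("1", "3", "5") or label.startswith(("7.", "8.")) for label in labels)

    def test_irreproducible_published_reports_false(self, noisy_dataset):
        published = {
            k: ParamEstimate.from_se(v * 10 + 5.0, 1e-6)
            for k, v in TRUTH_IR.as_dict().items()
        }
        result = run_ir_cascade(noisy_dataset, published)
        assert result.reproduced is False
        assert result.canonical_fit is not None
        # canonical falls back to the first converged attempt
        first_converged = next(
            label for label, fit in result.attempts if fit.converged
        )
        assert result.canonical_fit.step == first_converged

    def test_cascade_stops_at_first_reproducing_step(self, noise_free_dataset):
        """If the step-1 attempt fails reproduction but step 2 passes,
        the cascade must stop at step 2 (ordering contract)."""
        published = {
            k: ParamEstimate.from_se(v, 0.05 * abs(v))
            for k, v in TRUTH_IR.as_dict().items()
        }

        class RiggedIRModel(IRModel):
            calls = 0

            def fit(self, start, options=None):
                result = super().fit(start, options)
                type(self).calls += 1
                if type(self).calls == 1:
                    # pretend the first attempt converged far from truth
                    bad = {
                        k: ParamEstimate.from_se(v.value + 100.0, 1e-9)
                        for k, v in result.estimates.items()
                    }
                    from dataclasses import replace

                    return replace(result, estimates=bad)
                return result

        result = RiggedIRModel(noise_free_dataset).fit_cascade(published)
        assert result.step_reached == 2
        assert result.reproduced is True

    def test_plan_order_follows_protocol(self, noisy_dataset):
        published = {
            k: ParamEstimate.from_se(v, 0.1) for k, v in TRUTH_IR.as_dict().items()
        }
        plan = IRModel(noisy_dataset).cascade_plan(published)
        labels = [label for label, _, _ in plan]
        assert labels[:6] == ["1", "2", "3", "4", "5", "6"]
        assert labels[6:12] == [f"7.{i}" for i in range(1, 7)]
        assert labels[12:] == [f"8.{i}" for i in range(1, 13)]
        # ODR block mirrors the LM block's options
        for (label_lm, _, opt_lm), (label_odr, _, opt_odr) in zip(plan[:6], plan[6:12]):
            assert opt_odr.algorithm == "odr"
            assert (opt_odr.weighting, opt_odr.space) == (opt_lm.weighting, opt_lm.space)
        # step-8 block fixes exactly one parameter
        for _, _, opt in plan[12:]:
            assert opt.fixed is not None and len(opt.fixed) == 1

    def test_weight_rescaling_leaves_estimates_unchanged(self, noisy_dataset):
        model = IRModel(noisy_dataset)
        _, init, options = model.cascade_plan(None)[0]
        fit_a = model.fit(init, options)
        scaled = SurvivalDataset.from_arrays(
            noisy_dataset.dose,
            noisy_dataset.sf,
            noisy_dataset.sf - 2 * (noisy_dataset.sf - noisy_dataset.whisker_min),
            noisy_dataset.sf + 2 * (noisy_dataset.whisker_max - noisy_dataset.sf),
        )
        fit_b = IRModel(scaled).fit(init, options)
        for name in TRUTH_IR.as_dict():
            assert fit_a.params[name] == pytest.approx(fit_b.params[name], rel=1e-5)
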