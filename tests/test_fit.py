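"""Δχ-tensor fitting: exact recovery, oracle equivalence, diagnostics,
Monte-Carlo errors and leave-one-methyl-out sensitivity."""

import numpy as np
import pytest

from pcsassign.fit import (
    FitOptions,
    fit_tensor,
    leave_out_refit,
    monte_carlo_errors,
    q_factor,
    regression_stats,
    tensor_at_metal,
)
from pcsassign.peaks import PCSRecord
from pcsassign.tensor import ChiTensor, euler_zyz_to_axes, pcs_forward


def make_records(tensor, methyls, nuclei=("H", "C"), noise=(0.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for m in methyls:
        for nuc in nuclei:
            point = m.proton_position if nuc == "H" else m.carbon_position
            sigma = noise[0] if nuc == "H" else noise[1]
            tol = 0.008 if nuc == "H" else 0.05
            records.append(
                PCSRecord(
                    dataset_id="sim",
                    peak_id=None,
                    nucleus=nuc,
                    value=pcs_forward(tensor, point) + float(rng.normal(0, sigma)),
                    tolerance=tol,
                    status="measured",
                    methyl_id=m.methyl_id,
                )
            )
    return records


@pytest.fixture()
def truth(bundle_methyls):
    from scipy.spatial.transform import Rotation

    axes = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    metal = np.array([14.0, 6.0, 20.0])
    return ChiTensor(-24.0, -4.0, metal, axes, "Dy", "B:12")


class TestQFactor:
    def test_identity_zero(self):
        assert q_factor([0.1, -0.2, 0.3], [0.1, -0.2, 0.3]) == 0.0

    def test_zero_prediction_is_one(self):
        assert q_factor([0.1, -0.2], [0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_example(self):
        # rms([0, -0.1]) / rms([0.1, -0.2]) = 0.0707/0.1581
        assert q_factor([0.1, -0.2], [0.1, -0.1]) == pytest.approx(0.4472, abs=1e-4)

    def test_all_zero_observed_undefined(self):
        with pytest.raises(ValueError):
            q_factor([0.0, 0.0], [0.1, 0.2])


class TestRegressionStats:
    def test_identity_line(self):
        m, y0 = regression_stats([0.1, 0.2, -0.3], [0.1, 0.2, -0.3])
        assert m == pytest.approx(1.0) and y0 == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset(self):
        obs = np.array([0.1, 0.2, -0.3]) + 0.05
        m, y0 = regression_stats(obs, [0.1, 0.2, -0.3])
        assert m == pytest.approx(1.0) and y0 == pytest.approx(0.05)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        calc = rng.normal(size=100)
        obs = 0.7 * calc + 0.02 + rng.normal(size=100) * 0.1
        m, y0 = regression_stats(obs, calc)
        # textbook OLS
        mx, my = calc.mean(), obs.mean()
        slope = ((calc - mx) * (obs - my)).sum() / ((calc - mx) ** 2).sum()
        assert m == pytest.approx(slope, abs=1e-10)
        assert y0 == pytest.approx(my - slope * mx, abs=1e-10)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            regression_stats([0.1, 0.2], [0.5, 0.5])


class TestFitTensor:
    def test_noiseless_exact_recovery(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:30])
        res = fit_tensor(
            records, bundle_methyls,
            FitOptions(initial_metal=truth.metal + np.array([3.0, -2.0, 1.0])),
        )
        assert res.q < 1e-6
        assert res.tensor.dchi_ax == pytest.approx(truth.dchi_ax, abs=1e-4)
        assert res.tensor.dchi_rh == pytest.approx(truth.dchi_rh, abs=1e-4)
        np.testing.assert_allclose(res.tensor.metal, truth.metal, atol=1e-4)

    def test_under_determined_rejected(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:3], nuclei=("H",))
        with pytest.raises(ValueError, match="under-determined"):
            fit_tensor(records, bundle_methyls)

    def test_result_is_utr_and_stable(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:30], noise=(0.008, 0.05))
        opt = FitOptions(initial_metal=truth.metal)
        res = fit_tensor(records, bundle_methyls, opt)
        assert abs(res.tensor.dchi_rh) <= 2 / 3 * abs(res.tensor.dchi_ax) + 1e-9
        # refitting from the found optimum returns the same UTR tensor
        res2 = fit_tensor(
            records, bundle_methyls,
            FitOptions(initial_metal=res.tensor.metal, n_starts=0),
        )
        assert res2.tensor.dchi_ax == pytest.approx(res.tensor.dchi_ax, abs=1e-6)
        np.testing.assert_allclose(res2.tensor.metal, res.tensor.metal, atol=1e-6)

    def test_objective_not_above_truth_for_noiseless(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:25])
        res = fit_tensor(records, bundle_methyls, FitOptions(initial_metal=truth.metal))
        # objective at the reported optimum must not exceed the (zero)
        # objective at the generating parameters
        assert res.objective <= 1e-10

    def test_grid_oracle_equivalence(self, bundle_methyls, truth):
        """With the metal fixed, the fit must equal an exhaustive grid search
        over (Δχ_ax, Δχ_rh, α, β, γ) at the grid's own optimum."""
        methyls = bundle_methyls[:5]
        records = make_records(truth, methyls)  # 10 records
        res = fit_tensor(
            records, bundle_methyls,
            FitOptions(initial_metal=truth.metal, fix_metal=True),
        )
        # coarse oracle grid that contains the generating parameters
        best = np.inf
        points = np.array(
            [
                m.proton_position if r.nucleus == "H" else m.carbon_position
                for r in records
                for m in [next(mm for mm in methyls if mm.methyl_id == r.methyl_id)]
            ]
        )
        obs = np.array([r.value for r in records])
        w = np.array([1.0 / r.tolerance for r in records])
        # derive the truth's ZYZ angles so the grid passes through them
        from scipy.spatial.transform import Rotation

        a0, b0, g0 = Rotation.from_matrix(truth.axes.T).as_euler("ZYZ")
        for ax in np.linspace(truth.dchi_ax - 4, truth.dchi_ax + 4, 5):
            for rh in np.linspace(truth.dchi_rh - 2, truth.dchi_rh + 2, 5):
                for da in np.linspace(-0.4, 0.4, 3):
                    for db in np.linspace(-0.4, 0.4, 3):
                        for dg in np.linspace(-0.4, 0.4, 3):
                            t = ChiTensor(
                                ax, rh, truth.metal,
                                euler_zyz_to_axes(a0 + da, b0 + db, g0 + dg),
                            )
                            resid = (obs - pcs_forward(t, points)) * w
                            best = min(best, float(resid @ resid))
        assert res.objective <= best + 1e-6

    def test_parameter_recovery_under_noise(self, bundle_methyls, truth):
        # stated measurement noise, ~60 records: parameters within MC errors
        records = make_records(
            truth, bundle_methyls[:30], noise=(0.008, 0.05), seed=42
        )
        opt = FitOptions(initial_metal=truth.metal + np.array([2.0, 2.0, -1.0]))
        res = fit_tensor(records, bundle_methyls, opt)
        mc = monte_carlo_errors(records, bundle_methyls, n_samples=40, seed=1,
                                options=opt, base=res)
        assert abs(res.tensor.dchi_ax - truth.dchi_ax) < 4 * max(mc["dchi_ax"], 0.05)


class TestTensorAtMetal:
    def test_exact_at_true_metal(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:10])
        t = tensor_at_metal(records, bundle_methyls, truth.metal)
        assert t.dchi_ax == pytest.approx(truth.dchi_ax, abs=1e-8)
        assert t.dchi_rh == pytest.approx(truth.dchi_rh, abs=1e-8)

    def test_too_few_records(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:2], nuclei=("H",))
        assert tensor_at_metal(records, bundle_methyls, truth.metal) is None


class TestMonteCarlo:
    def test_zero_noise_gives_zero_spread(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:30])
        mc = monte_carlo_errors(
            records, bundle_methyls, n_samples=20, seed=0,
            options=FitOptions(initial_metal=truth.metal),
        )
        assert mc["dchi_ax"] < 1e-6
        assert mc["dchi_rh"] < 1e-6
        assert mc["n_samples"] == 20

    def test_deterministic_under_seed(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:20], noise=(0.008, 0.05))
        opt = FitOptions(initial_metal=truth.metal)
        a = monte_carlo_errors(records, bundle_methyls, n_samples=15, seed=7, options=opt)
        b = monte_carlo_errors(records, bundle_methyls, n_samples=15, seed=7, options=opt)
        assert a == b

    def test_default_protocol(self, bundle_methyls, truth):
        import inspect

        sig = inspect.signature(monte_carlo_errors)
        assert sig.parameters["n_samples"].default == 100
        assert sig.parameters["omit_fraction"].default == 0.2

    def test_noise_gives_positive_spread(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:25], noise=(0.008, 0.05))
        mc = monte_carlo_errors(
            records, bundle_methyls, n_samples=25, seed=3,
            options=FitOptions(initial_metal=truth.metal),
        )
        assert mc["dchi_ax"] > 0


class TestLeaveOut:
    def test_large_pcs_methyl_perturbs_more(self, bundle_methyls, truth):
        methyls = bundle_methyls[:25]
        records = make_records(truth, methyls, noise=(0.008, 0.05), seed=5)
        by_size = {}
        for m in methyls:
            vals = [abs(r.value) for r in records if r.methyl_id == m.methyl_id]
            by_size[m.methyl_id] = max(vals)
        small = min(by_size, key=by_size.get)
        large = max(by_size, key=by_size.get)
        opt = FitOptions(initial_metal=truth.metal)
        d_small, _ = leave_out_refit(records, bundle_methyls, small, opt)
        d_large, _ = leave_out_refit(records, bundle_methyls, large, opt)
        perturb_small = abs(d_small["d_dchi_ax"]) + d_small["d_metal"]
        perturb_large = abs(d_large["d_dchi_ax"]) + d_large["d_metal"]
        assert perturb_large > perturb_small

    def test_held_out_prediction_error_reasonable(self, bundle_methyls, truth):
        methyls = bundle_methyls[:30]
        records = make_records(truth, methyls, noise=(0.008, 0.05), seed=9)
        opt = FitOptions(initial_metal=truth.metal)
        mid = methyls[10].methyl_id
        delta, refit = leave_out_refit(records, bundle_methyls, mid, opt)
        errs = delta["held_out_errors"]
        # held-out prediction errors stay within a few measurement sigmas on
        # well-determined data
        assert np.all(np.abs(errs) < 6 * 0.05)

    def test_missing_methyl_rejected(self, bundle_methyls, truth):
        records = make_records(truth, bundle_methyls[:20])
        with pytest.raises(ValueError):
            leave_out_refit(records, bundle_methyls, "Z:999:d1")
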