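"""SECR likelihood, fitting, information criteria, and prediction."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import beardensity as bd
from beardensity.secr import SecrDesign, negloglik, _density_design
from conftest import flat_truth, tiny_instance, trap_grid, uniform_population
from _oracle import brute_negloglik, single_animal_history_prob


class TestDetectionFunction:
    @pytest.mark.parametrize(
        "d, lam0, sigma, expected",
        [
            (0.0, 0.7, 2.0, 0.7),
            (2.0 * np.sqrt(2 * np.log(2)), 0.7, 2.0, 0.35),  # half-hazard d
            (3.0, 0.7, 1e9, 0.7),  # sigma -> inf recovers lam0
        ],
    )
    def test_hazard_closed_forms(self, d, lam0, sigma, expected):
        assert bd.hazard(d, lam0, sigma) == pytest.approx(expected, rel=1e-9)

    def test_hazard_decreasing_in_distance(self):
        d = np.linspace(0, 10, 50)
        lam = bd.hazard(d, 0.5, 2.0)
        assert (np.diff(lam) < 0).all()

    @pytest.mark.parametrize(
        "lam, expected",
        [(0.0, 0.0), (np.log(2), 0.5), (10.0, 1 - np.exp(-10.0))],
    )
    def test_hazard_to_prob(self, lam, expected):
        assert bd.hazard_to_prob(lam) == pytest.approx(expected, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bd.hazard(1.0, 0.5, -1.0)
        with pytest.raises(ValueError):
            bd.hazard(1.0, -0.5, 1.0)
        with pytest.raises(ValueError):
            bd.hazard_to_prob(-0.1)


def one_cell_instance():
    mask = bd.MaskGrid(np.array([0.0]), np.array([0.0]), 1.0,
                       pd.DataFrame({"tenure": ["protected"]}))
    det = bd.DetectorArray(np.array(["t"]), np.array([0.0]), np.array([0.0]),
                           np.array(["rub"]), np.ones((1, 1), dtype=np.int8))
    return mask, det


class TestNegloglik:
    def test_hand_worked_single_cell(self):
        # one cell (a=1), D=1, trap at the centroid, one occasion,
        # lam0 = ln 2 so p = 1/2, one animal detected once (Poisson):
        # -logL = -(ln 0.5 - 0.5) = 1.1931
        mask, det = one_cell_instance()
        hist = bd.CaptureHistory(np.array(["a"]), np.array(["F"]),
                                 np.ones((1, 1, 1)))
        des = SecrDesign(bd.ObservationModel((), ()), bd.DensityModel(()),
                         hist, det, mask)
        theta = np.array([0.0, np.log(np.log(2)), 0.0])
        assert negloglik(theta, des) == pytest.approx(
            -(np.log(0.5) - 0.5), abs=1e-12
        )

    def test_no_detections_reduces_to_expected_count(self):
        mask, det = one_cell_instance()
        hist = bd.CaptureHistory(np.empty(0, object), np.empty(0, object),
                                 np.zeros((0, 1, 1)))
        des = SecrDesign(bd.ObservationModel((), ()), bd.DensityModel(()),
                         hist, det, mask)
        theta = np.array([0.0, np.log(np.log(2)), 0.0])
        assert negloglik(theta, des) == pytest.approx(0.5, abs=1e-12)

    def test_history_probabilities_sum_to_one(self):
        # 2 cells / 2 traps / 2 occasions: single-animal history
        # probabilities over all 2^4 outcomes sum to 1 for each center
        rng = np.random.default_rng(3)
        det_xy = rng.uniform(0, 4, (2, 2))
        mask_xy = rng.uniform(0, 4, (2, 2))
        det_type = np.array(["rub", "fence"])
        usage = np.ones((2, 2), dtype=np.int8)
        thl = np.array([np.log(0.4), -0.3, 0.8])  # intercept, fence, bk
        ths = np.array([np.log(1.5)])
        names_l = ["(Intercept)", "traptype[fence]", "bk"]
        names_s = ["(Intercept)"]
        for m in range(2):
            total = 0.0
            for bits in itertools.product([0, 1], repeat=4):
                om = np.array(bits).reshape(2, 2)
                total += single_animal_history_prob(
                    om, mask_xy[m], det_xy, det_type, usage,
                    thl, names_l, ths, names_s,
                )
            assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("distribution", ["poisson", "binomial"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, distribution):
        rng = np.random.default_rng(100 + seed)
        mask, det, hist, gb, tenure = tiny_instance(rng)
        obs = bd.ObservationModel(("traptype", "bk", "T", "GB"),
                                  ("traptype", "T"))
        des = SecrDesign(obs, bd.DensityModel(("tenure",)), hist, det, mask)
        theta = rng.normal(scale=0.5, size=des.n_params)
        theta[0] += 3.0  # keep Lambda above n so binomial is defined
        got = negloglik(theta, des, distribution)
        want = brute_negloglik(
            theta, hist.detections, det.coords, det.det_type, det.usage,
            mask.coords, mask.cell_area, des.d_names, des.l_names,
            des.s_names, mask_cov={"tenure": tenure}, gb=gb,
            distribution=distribution,
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_relabeling_and_detector_order(self):
        rng = np.random.default_rng(42)
        mask, det, hist, gb, tenure = tiny_instance(rng, max_traps=3)
        obs = bd.ObservationModel(("traptype", "bk"), ())
        dm = bd.DensityModel(())
        des = SecrDesign(obs, dm, hist, det, mask)
        theta = rng.normal(scale=0.4, size=des.n_params)
        base = negloglik(theta, des)

        # permute individuals
        perm_i = rng.permutation(hist.n_individuals)
        hist_p = bd.CaptureHistory(hist.ids[perm_i], hist.sex[perm_i],
                                   hist.detections[perm_i])
        assert negloglik(theta, SecrDesign(obs, dm, hist_p, det, mask)) == \
            pytest.approx(base, abs=1e-10)

        # permute detectors (history columns follow)
        perm_k = rng.permutation(det.n_detectors)
        det_p = bd.DetectorArray(
            det.ids[perm_k], det.x[perm_k], det.y[perm_k],
            det.det_type[perm_k], det.usage[perm_k],
            time_varying={"GB": det.time_varying["GB"][perm_k]},
        )
        hist_k = bd.CaptureHistory(hist.ids, hist.sex,
                                   hist.detections[:, perm_k, :])
        assert negloglik(theta, SecrDesign(obs, dm, hist_k, det_p, mask)) == \
            pytest.approx(base, abs=1e-10)


class TestAICc:
    def test_published_model_rows(self):
        # step-1 top male model and step-2 top female model, 2013
        assert bd.aicc(-1750.67, 8, 126) == pytest.approx(3518.58, abs=0.02)
        assert bd.aicc(-940.50, 9, 101) == pytest.approx(1900.97, abs=0.02)

    def test_large_n_limit_is_aic(self):
        assert bd.aicc(-100.0, 4, 10**9) == pytest.approx(208.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bd.aicc(-10.0, 5, 6)

    def test_weights_sum_to_one_and_best_leads(self):
        w = bd.akaike_weights([100.0, 101.2, 104.0])
        assert w.sum() == pytest.approx(1.0)
        assert w.argmax() == 0

    def test_published_delta_set_gives_leading_weight(self):
        from beardensity.survey_tables import MALE_2013_STEP2_DAICC

        w = bd.akaike_weights(MALE_2013_STEP2_DAICC)
        assert w[0] == pytest.approx(0.60, abs=0.01)


def _mini_fit(seed=0, **kw):
    from conftest import recovery_replicate

    return recovery_replicate(
        seed, n_side=5, spacing=3.0, n_occasions=5, buffer=6.0,
        mask_spacing=2.0, d=0.1, lam0=0.2, **kw,
    )


class TestFitting:
    def test_empty_history_rejected(self):
        mask, det = one_cell_instance()
        hist = bd.CaptureHistory(np.empty(0, object), np.empty(0, object),
                                 np.zeros((0, 1, 1)))
        with pytest.raises(ValueError, match="empty"):
            bd.fit_secr(bd.ObservationModel((), ()), bd.DensityModel(()),
                        hist, det, mask)

    def test_flat_model_recovers_truth_roughly(self):
        fit = _mini_fit(seed=5)
        rp = fit.real_params()
        assert fit.converged
        assert 0.03 < rp["D"]["estimate"] < 0.3
        assert 1.0 < rp["sigma"]["estimate"] < 4.0
        assert rp["D"]["lcl"] < rp["D"]["estimate"] < rp["D"]["ucl"]

    def test_binomial_close_to_poisson(self):
        fit_p = _mini_fit(seed=7)
        det = trap_grid(5, 3.0, n_occasions=5)
        # refit same data under the binomial count distribution
        rng = np.random.default_rng(7)
        mask = bd.build_mask(det, 6.0, 2.0)
        pop = uniform_population(mask, 0.1, rng)
        hist = bd.simulate_captures(pop, det, flat_truth(0.1, 0.2, 2.0),
                                    seed=7 + 100_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_b = bd.fit_secr(
                bd.ObservationModel((), ()), bd.DensityModel(()),
                hist, det, mask, distribution="binomial", n_starts=1,
            )
        d_p = fit_p.real_params()["D"]["estimate"]
        d_b = fit_b.real_params()["D"]["estimate"]
        assert d_b == pytest.approx(d_p, rel=0.15)

    def test_lambda0_sigma_compensation_ridge(self):
        """Profile over lambda0: sigma compensates inversely while the
        density estimate stays nearly flat along the ridge."""
        det = trap_grid(6, 3.0, n_occasions=6)
        rng = np.random.default_rng(11)
        mask = bd.build_mask(det, 6.0, 2.0)
        pop = uniform_population(mask, 0.08, rng)
        hist = bd.simulate_captures(pop, det, flat_truth(0.08, 0.15, 2.0),
                                    seed=200)
        obs, dm = bd.ObservationModel((), ()), bd.DensityModel(())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mle = bd.fit_secr(obs, dm, hist, det, mask, n_starts=1,
                              compute_se=False)
            center = mle.beta[mle.pD]
            sigmas, dens = [], []
            for delta in (-0.3, 0.0, 0.3):
                fit = bd.fit_secr(
                    obs, dm, hist, det, mask, n_starts=1, compute_se=False,
                    fixed={"lambda0.(Intercept)": center + delta},
                )
                rp = fit.real_params()
                sigmas.append(rp["sigma"]["estimate"])
                dens.append(rp["D"]["estimate"])
        assert sigmas[0] > sigmas[1] > sigmas[2]  # inverse relationship
        spread = (max(dens) - min(dens)) / dens[1]
        assert spread < 0.05

    def test_two_step_single_candidates_and_tie_break(self):
        det = trap_grid(5, 3.0, n_occasions=5)
        rng = np.random.default_rng(21)
        mask = bd.build_mask(det, 6.0, 2.0)
        mask.covariates = pd.DataFrame(
            {"tenure": np.where(mask.x < 27, "private", "protected")}
        )
        pop = uniform_population(mask, 0.1, rng)
        hist = bd.simulate_captures(pop, det, flat_truth(0.1, 0.2, 2.0),
                                    seed=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            two = bd.run_two_step(
                [bd.ObservationModel((), ())],
                [bd.DensityModel(())],
                hist, det, mask, n_starts=1,
            )
        assert two.base_obs == bd.ObservationModel((), ())
        assert two.best_fit.dens == bd.DensityModel(())
        assert len(two.step1_table) == 1 and len(two.step2_table) == 1
        # AICc tie resolves toward fewer parameters
        a = two.step2_fits[0]
        import copy

        b = copy.deepcopy(a)
        b.K = a.K + 2
        b.aicc = a.aicc
        tab = bd.model_table([b, a], names=["big", "small"])
        assert tab["model"].iloc[0] == "small"

    def test_model_table_rejects_mixed_datasets(self):
        a = _mini_fit(seed=1)
        b = _mini_fit(seed=2)
        if a.n == b.n:  # force a mismatch
            b.n += 1
        with pytest.raises(ValueError, match="different n"):
            bd.model_table([a, b])


class TestPrediction:
    def _tenure_fit(self):
        """Hand-assembled fit with a known tenure density model."""
        dm = bd.DensityModel(("tenure",))
        beta = np.array([np.log(0.1), -0.4, -1.0, np.log(0.1), np.log(2.0)])
        names = ["D.(Intercept)", "D.tenure[private]", "D.tenure[crown]",
                 "lambda0.(Intercept)", "sigma.(Intercept)"]
        vcov = np.diag(np.full(5, 1e-3))
        return bd.FitResult(
            obs=bd.ObservationModel((), ()), dens=dm, names=names,
            beta=beta, se=np.sqrt(np.diag(vcov)), vcov=vcov, ll=-10.0,
            K=5, n=40, aicc=31.8, converged=True, distribution="poisson",
            pD=3, pl=1, ps=1, mask_area=400.0,
        )

    def _tenure_mask(self):
        x, y = np.meshgrid(np.arange(20) + 0.5, np.arange(20) + 0.5,
                           indexing="ij")
        tenure = np.where(
            x.ravel() < 8, "private", np.where(x.ravel() < 14, "crown",
                                               "protected")
        )
        return bd.MaskGrid(x.ravel(), y.ravel(), 1.0,
                           pd.DataFrame({"tenure": tenure}))

    def test_flat_model_gives_constant_surface(self):
        fit = _mini_fit(seed=3)
        det = trap_grid(5, 3.0, n_occasions=5)
        mask = bd.build_mask(det, 6.0, 2.0)
        surf = bd.predict_density(fit, mask)
        assert surf["D"].nunique() == 1
        assert surf["D"].iloc[0] == pytest.approx(
            fit.real_params()["D"]["estimate"]
        )

    def test_tenure_model_gives_three_levels(self):
        surf = bd.predict_density(self._tenure_fit(), self._tenure_mask())
        assert surf["D"].nunique() == 3

    def test_surface_total_matches_expected_abundance(self):
        fit = self._tenure_fit()
        mask = self._tenure_mask()
        surf = bd.predict_density(fit, mask)
        X, _ = _density_design(mask, fit.dens.terms)
        lam_hat = float(np.exp(X @ fit.density_beta).sum() * mask.cell_area)
        assert surf["D"].sum() * mask.cell_area == pytest.approx(lam_hat)

    def test_missing_covariate_rejected(self):
        fit = self._tenure_fit()
        mask = bd.MaskGrid(np.array([0.0]), np.array([0.0]), 1.0,
                           pd.DataFrame({"ndvi": [0.5]}))
        with pytest.raises(ValueError, match="tenure"):
            bd.predict_density(fit, mask)

    def test_region_abundance_partitions_total(self):
        fit = self._tenure_fit()
        mask = self._tenure_mask()
        tab = bd.region_abundance(fit, mask, "tenure", seed=1)
        surf = bd.predict_density(fit, mask)
        total = surf["D"].sum() * mask.cell_area
        assert tab["nhat"].sum() == pytest.approx(total, abs=1e-9)
        assert (tab["lcl"] <= tab["nhat"]).all()
        assert (tab["nhat"] <= tab["ucl"]).all()

    def test_uniform_density_region_count(self):
        # D = 0.05 over a 1,000 km^2 region -> N = 50
        x, y = np.meshgrid(np.arange(25) * 2 + 1, np.arange(10) * 2 + 1,
                           indexing="ij")
        mask = bd.MaskGrid(
            x.ravel(), y.ravel(), 2.0,
            pd.DataFrame({"tenure": ["protected"] * 250}),
        )
        fit = self._tenure_fit()
        flat = bd.FitResult(
            obs=fit.obs, dens=bd.DensityModel(()),
            names=["D.(Intercept)", "lambda0.(Intercept)",
                   "sigma.(Intercept)"],
            beta=np.array([np.log(0.05), 0.0, 0.0]),
            se=np.full(3, 0.01), vcov=np.diag(np.full(3, 1e-4)),
            ll=-1.0, K=3, n=30, aicc=8.9, converged=True,
            distribution="poisson", pD=1, pl=1, ps=1, mask_area=1000.0,
        )
        tab = bd.region_abundance(flat, mask, "tenure", seed=0)
        assert tab["nhat"].iloc[0] == pytest.approx(50.0)

    def test_empty_region_warns_and_zeroes(self):
        fit = self._tenure_fit()
        mask = self._tenure_mask()
        with pytest.warns(UserWarning, match="no mask cells"):
            tab = bd.region_abundance(
                fit, mask, "tenure",
                regions=["private", "crown", "protected", "federal"],
                seed=0,
            )
        assert tab.set_index("region").loc["federal", "nhat"] == 0.0


class TestCoverage:
    def test_ci_coverage_scaled_down(self):
        """Nominal 95% Wald intervals on ln D cover the generating
        density in 90-99 of 100 small replicates (30 traps, 5
        occasions)."""
        from conftest import recovery_replicate

        hits = total = 0
        for seed in range(110):
            fit = recovery_replicate(
                seed, n_side=(5, 6), spacing=3.0, n_occasions=5, buffer=6.0,
                mask_spacing=2.5, d=0.05, lam0=0.15, sigma=2.0,
            )
            if fit is None or not fit.converged:
                continue
            rp = fit.real_params()["D"]
            hits += rp["lcl"] <= 0.05 <= rp["ucl"]
            total += 1
            if total == 100:
                break
        assert total == 100
        assert 90 <= hits <= 99
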