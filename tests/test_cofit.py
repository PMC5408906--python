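"""Multi-contrast co-refinement: chi-squared, fitting, bootstrap, comparison."""

import copy

import numpy as np
import pytest

from slabrefl import (
    FitParameter,
    FitProblem,
    LayerModel,
    NoiseModel,
    ReflectivityCurve,
    bootstrap_errors,
    chi_squared,
    compare_models,
    fit,
    material_preset,
    material_sld,
    solvent_preset,
    volume_fraction,
    VolumeFractionInputs,
    water_sld,
)
from slabrefl import constants as c
from conftest import single_igg_layer_problem


def _noiseless_problem(**kwargs):
    """Problem whose data equal the model exactly, with unit dR."""
    problem, truth = single_igg_layer_problem(
        noise=NoiseModel(relative_error_floor=0.0, background_level=0.0), **kwargs
    )
    for contrast in problem.contrasts:
        model = problem.measured_model(contrast)
        contrast.curve = ReflectivityCurve(
            q=contrast.curve.q, r=model, dr=np.ones_like(model),
            dq=contrast.curve.dq,
        )
    problem._smear_cache.clear()
    return problem, truth


class TestChiSquared:
    def test_zero_at_truth_for_noiseless_data(self):
        problem, _ = _noiseless_problem()
        per, total = chi_squared(problem)
        assert total == pytest.approx(0.0, abs=1e-20)

    def test_unit_offset_gives_unit_chi2(self):
        problem, _ = _noiseless_problem()
        for contrast in problem.contrasts:
            contrast.curve = ReflectivityCurve(
                q=contrast.curve.q,
                r=contrast.curve.r + contrast.curve.dr,  # offset by exactly dR
                dr=contrast.curve.dr,
            )
        problem._smear_cache.clear()
        per, total = chi_squared(problem)
        assert total == pytest.approx(1.0, rel=1e-9)
        assert all(v == pytest.approx(1.0, rel=1e-9) for v in per.values())

    def test_gaussian_noise_gives_chi2_near_one(self):
        """At the generating parameters chi² ≈ 1 within 3/sqrt(N)."""
        totals = []
        for seed in range(6):
            problem, _ = single_igg_layer_problem(seed=seed, n_points=80)
            totals.append(chi_squared(problem)[1])
        n_total = 3 * 80
        assert np.mean(totals) == pytest.approx(1.0, abs=3 / np.sqrt(n_total))

    def test_batch_evaluation_matches_scalar(self):
        """The vectorised population path agrees with per-vector chi²."""
        from slabrefl.cofit import chi_squared_batch

        problem, _ = single_igg_layer_problem(seed=1)
        rng = np.random.default_rng(5)
        free = problem.free_parameters()
        X = np.array([[rng.uniform(*p.bounds) for _ in range(8)] for p in free])
        batch = chi_squared_batch(problem, X)
        scalar = np.array([chi_squared(problem, X[:, s])[1] for s in range(8)])
        np.testing.assert_allclose(batch, scalar, rtol=1e-6)

    def test_missing_dr_instructs_floor(self):
        problem, _ = _noiseless_problem()
        bad = problem.contrasts[0].curve
        problem.contrasts[0].curve = ReflectivityCurve(q=bad.q, r=bad.r, dr=None)
        with pytest.raises(ValueError, match="floor"):
            chi_squared(problem)


class TestSolventCoupling:
    def test_layer_sld_inverts_to_phi_via_eq4(self):
        """The phi-parameterised layer SLD satisfies the volume-fraction
        relation exactly in every contrast."""
        igg = material_preset("IgG4")
        layer = LayerModel(
            "igg",
            thickness=FitParameter.fixed("t", 30.0),
            roughness=FitParameter.fixed("r", 3.0),
            material=igg,
            phi=FitParameter.fixed("phi", 0.37),
        )
        for name in ("D2O", "H2O", "SMW"):
            solvent = solvent_preset(name)
            rho_l = layer.sld_in(solvent)
            out = volume_fraction(
                VolumeFractionInputs(
                    rho_s=water_sld(solvent),
                    rho_l=rho_l,
                    rho_a=material_sld(igg, solvent),
                )
            )
            assert out.phi == pytest.approx(0.37, abs=1e-12)


class TestFit:
    def test_noiseless_fit_from_truth_recovers_truth(self):
        problem, truth = _noiseless_problem()
        result = fit(problem, global_search=False)
        assert result.chi2_total == pytest.approx(0.0, abs=1e-12)
        for k, v in truth.items():
            assert result.params[k] == pytest.approx(v, rel=1e-3)

    def test_global_fit_recovers_single_layer(self):
        problem, truth = single_igg_layer_problem(seed=7)
        result = fit(problem, seed=7, de_maxiter=40, de_popsize=10)
        assert result.params["igg.thickness"] == pytest.approx(
            truth["igg.thickness"], rel=0.05
        )
        assert result.params["igg.phi"] == pytest.approx(truth["igg.phi"], abs=0.03)

    def test_deterministic_given_seed(self):
        p1, _ = single_igg_layer_problem(seed=3)
        p2, _ = single_igg_layer_problem(seed=3)
        r1 = fit(p1, seed=11, de_maxiter=15, de_popsize=6)
        r2 = fit(p2, seed=11, de_maxiter=15, de_popsize=6)
        assert r1.params == r2.params
        assert r1.chi2_total == r2.chi2_total

    def test_no_varying_parameters_rejected(self):
        problem, _ = _noiseless_problem()
        for p in problem.free_parameters():
            p.vary = False
        with pytest.raises(ValueError, match="varying"):
            fit(problem)

    def test_unbounded_varying_parameter_rejected(self):
        problem, _ = _noiseless_problem()
        problem.layers[1].thickness.bounds = (-np.inf, np.inf)
        with pytest.raises(ValueError, match="finite bounds"):
            fit(problem)

    def test_added_contrasts_do_not_add_degenerate_directions(self):
        """Numerical chi² Hessian at truth: the count of near-null directions
        with three contrasts never exceeds the single-contrast count."""

        def null_count(contrasts):
            problem, truth = single_igg_layer_problem(seed=5, contrasts=contrasts)
            x0 = problem.free_values()
            h = 1e-4 * np.maximum(np.abs(x0), 1.0)
            n = x0.size
            hess = np.zeros((n, n))
            f0 = chi_squared(problem, x0)[1]
            for i in range(n):
                for j in range(i, n):
                    xpp = x0.copy(); xpp[[i, j]] += h[[i, j]]
                    xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                    xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                    xmm = x0.copy(); xmm[[i, j]] -= h[[i, j]]
                    hess[i, j] = hess[j, i] = (
                        chi_squared(problem, xpp)[1]
                        - chi_squared(problem, xpm)[1]
                        - chi_squared(problem, xmp)[1]
                        + chi_squared(problem, xmm)[1]
                    ) / (4 * h[i] * h[j])
            eig = np.linalg.eigvalsh(hess)
            return int(np.sum(eig < 1e-6 * eig.max()))

        assert null_count(("D2O", "H2O", "SMW")) <= null_count(("D2O",))


class TestBootstrap:
    def test_zero_noise_intervals_collapse(self):
        problem, truth = _noiseless_problem()
        result = fit(problem, global_search=False)
        intervals = bootstrap_errors(problem, result, n_resamples=10, seed=0)
        for name, (lo, hi) in intervals.items():
            centre = result.params[name]
            assert hi - lo <= 1e-6 * max(abs(centre), 1.0)

    def test_n_resamples_validated(self):
        problem, _ = _noiseless_problem()
        result = fit(problem, global_search=False)
        with pytest.raises(ValueError):
            bootstrap_errors(problem, result, n_resamples=1)

    def test_thickness_interval_covers_truth(self):
        """95 % interval for the layer thickness covers the generating value
        in at least 90 % of 50 seeded repetitions."""
        n_reps, covered = 50, 0
        for seed in range(n_reps):
            problem, truth = single_igg_layer_problem(
                seed=seed, contrasts=("D2O",), n_points=40
            )
            result = fit(problem, seed=seed, global_search=False)
            intervals = bootstrap_errors(
                problem, result, n_resamples=80, seed=seed, nm_maxiter=600
            )
            lo, hi = intervals["igg.thickness"]
            covered += lo <= truth["igg.thickness"] <= hi
        assert covered >= 0.9 * n_reps

    def test_duplicating_points_shrinks_intervals_sqrt2(self):
        """Doubling every point (tiny Q jitter to keep the grid monotone)
        narrows bootstrap widths by about sqrt(2)."""

        def widths(duplicate: bool, seed=4):
            problem, _ = single_igg_layer_problem(seed=seed, contrasts=("D2O",), n_points=60)
            if duplicate:
                for contrast in problem.contrasts:
                    cv = contrast.curve
                    q2 = np.sort(np.concatenate([cv.q, cv.q * (1 + 1e-9)]))
                    r2 = np.repeat(cv.r, 2)
                    dr2 = np.repeat(cv.dr, 2)
                    contrast.curve = ReflectivityCurve(q=q2, r=r2, dr=dr2)
                problem._smear_cache.clear()
            result = fit(problem, seed=seed, global_search=False)
            iv = bootstrap_errors(problem, result, n_resamples=80, seed=seed, nm_maxiter=400)
            return {k: hi - lo for k, (lo, hi) in iv.items()}

        w1, w2 = widths(False), widths(True)
        ratio = w1["igg.thickness"] / w2["igg.thickness"]
        assert 1.15 <= ratio <= 1.8

    def test_single_contrast_intervals_wider_than_three(self):
        """Co-refining three contrasts tightens every shared parameter."""
        seed = 2
        p3, _ = single_igg_layer_problem(seed=seed, contrasts=("D2O", "H2O", "SMW"))
        r3 = fit(p3, seed=seed, global_search=False)
        iv3 = bootstrap_errors(p3, r3, n_resamples=60, seed=seed, nm_maxiter=400)

        p1, _ = single_igg_layer_problem(seed=seed, contrasts=("D2O",))
        r1 = fit(p1, seed=seed, global_search=False)
        iv1 = bootstrap_errors(p1, r1, n_resamples=60, seed=seed, nm_maxiter=400)

        for name in iv3:
            w3 = iv3[name][1] - iv3[name][0]
            w1 = iv1[name][1] - iv1[name][0]
            assert w1 > w3, f"{name}: single-contrast width {w1} !> {w3}"


def _model_variant(n_layers, experiments, igg):
    """1- or 2-layer protein model over fixed SiO2, for model comparison."""
    layers = [
        LayerModel(
            "sio2",
            thickness=FitParameter.fixed("sio2.thickness", 10.0),
            roughness=FitParameter.fixed("sio2.roughness", 3.0),
            sld=FitParameter.fixed("sio2.sld", c.SLD_SILICA),
        )
    ]
    for i in range(n_layers):
        layers.append(
            LayerModel(
                f"p{i}",
                thickness=FitParameter(f"p{i}.thickness", 30.0, (2.0, 120.0), vary=True),
                roughness=FitParameter.fixed(f"p{i}.roughness", 4.0),
                material=igg,
                phi=FitParameter(f"p{i}.phi", 0.2, (0.0, 0.8), vary=True),
            )
        )
    return FitProblem(
        layers,
        copy.deepcopy(experiments),
        backing_roughness=FitParameter.fixed("backing_roughness", 4.0),
    )


class TestCompareModels:
    @pytest.fixture(scope="class")
    def one_layer_data(self):
        problem, _ = single_igg_layer_problem(seed=9, contrasts=("D2O", "H2O"))
        return [copy.deepcopy(x) for x in problem.contrasts]

    def test_nested_tie_prefers_fewer_layers(self, one_layer_data):
        igg = material_preset("IgG4")
        ranked = compare_models(
            {
                "two_layer": _model_variant(2, one_layer_data, igg),
                "one_layer": _model_variant(1, one_layer_data, igg),
            },
            seed=1,
            de_maxiter=30,
            de_popsize=8,
        )
        assert ranked[0]["label"] == "one_layer"

    def test_identical_variants_identical_chi2(self, one_layer_data):
        igg = material_preset("IgG4")
        ranked = compare_models(
            {
                "a": _model_variant(1, one_layer_data, igg),
                "b": _model_variant(1, one_layer_data, igg),
            },
            seed=3,
            de_maxiter=15,
            de_popsize=6,
        )
        assert ranked[0]["chi2_total"] == ranked[1]["chi2_total"]

    def test_three_layer_truth_beats_two_layer(self):
        from slabrefl import simulate_scenario
        from slabrefl.scenarios import recovery_problem

        exps = simulate_scenario(
            "igg_silica_ph62", NoiseModel(seed=6), contrasts=("D2O", "H2O")
        )
        igg = material_preset("IgG4")
        three, _ = recovery_problem("igg_silica_ph62", [copy.deepcopy(x) for x in exps], vary_sio2=False)
        two = _model_variant(2, exps, igg)
        # align roughness with the generating scenario so only layer count differs
        for layer in two.layers[1:]:
            layer.roughness.value = 8.0
        two.backing_roughness.value = 8.0
        for x in two.contrasts:  # background fixed at generating level
            x.background.value = 1e-6
        ranked = compare_models(
            {"three": three, "two": two}, seed=6, de_maxiter=40, de_popsize=8
        )
        assert ranked[0]["label"] == "three"

    def test_different_data_rejected(self):
        pa, _ = single_igg_layer_problem(seed=1, contrasts=("D2O",))
        pb, _ = single_igg_layer_problem(seed=2, contrasts=("D2O",))
        with pytest.raises(ValueError, match="different data"):
            compare_models({"a": pa, "b": pb})
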