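"""Screening logic, implant masks, gradient-porosity structures."""

import numpy as np
import pytest

from spinodal import CHParams, GridSpec, ValidationError
from spinodal.cahn_hilliard import simulate
from spinodal.design import (DesignTarget, ImplantDesignSpec, ScreeningFailure,
                             ScreeningSampler, design_gradient_implant,
                             lever_rule_porosity, make_shape_mask, screen,
                             zone_porosity, SPINODAL_MU_LIMIT)
from spinodal.fields import GradientInitSpec, init_gradient
from spinodal.morphology import filter_artifacts, threshold_extract

NINE = (20.0, 8.0, 7.0, 18.0, 6.0, 16.0, 5.0, 5.5, 6.0)


class TestDesignTarget:
    def test_deviation_norms(self):
        t = DesignTarget(NINE, epsilon=0.1)
        c = np.asarray(NINE) + 0.05
        assert t.deviation(c) == pytest.approx(0.05)
        t_mean = DesignTarget(NINE, epsilon=0.1, norm="mean")
        c2 = np.asarray(NINE).copy()
        c2[0] += 0.9
        assert t_mean.deviation(c2) == pytest.approx(0.1)

    @pytest.mark.parametrize("kwargs", [
        {"c_target": (1.0,) * 8},
        {"c_target": NINE, "epsilon": 0.0},
        {"c_target": (1.0, 5.0, 5.0, 1.0, 5.0, 1.0, 1.0, 1.0, 1.0)},  # not psd
    ])
    def test_invalid_targets_rejected(self, kwargs):
        kwargs.setdefault("c_target", NINE)
        with pytest.raises(ValidationError):
            DesignTarget(**kwargs)


class TestSampler:
    def test_draws_are_deterministic_and_valid(self):
        s = ScreeningSampler(seed=13)
        a, b = s.draw(5), s.draw(5)
        assert a == b
        for k in range(10):
            spec = s.draw(k)
            assert -0.3 <= spec.base.mu <= 0.3
            assert 0 < spec.c <= 0.015
            assert np.linalg.norm(spec.r) == pytest.approx(1.0, abs=1e-9)

    def test_different_indices_differ(self):
        s = ScreeningSampler(seed=13)
        assert s.draw(0) != s.draw(1)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValidationError):
            ScreeningSampler(mu_range=(-0.9, 0.0))
        with pytest.raises(ValidationError):
            ScreeningSampler(c_range=(0.0, 0.015))


def _stub_pipeline(c_by_candidate):
    """Generator/predictor/verifier stubs driven by a candidate counter."""
    from spinodal.fields import init_uniform, UniformInitSpec
    from spinodal.cahn_hilliard import Trajectory, CHParams as _P
    from spinodal.grids import PhaseField

    state = {"k": -1}

    def generator(init, n_steps):
        state["k"] += 1
        # a fixed mixed-sign field: every candidate yields a usable
        # (non-degenerate) structure regardless of the sampled noise mean
        vals = np.random.default_rng(1234).standard_normal(init.grid.shape)
        saves = [PhaseField(vals, init.grid, i) for i in range(n_steps + 1)]
        return Trajectory(saves, _P(n_saves=n_steps))

    def predictor(structure):
        return np.asarray(c_by_candidate[min(state["k"],
                                             len(c_by_candidate) - 1)])

    return generator, predictor


class TestScreen:
    def test_vacuous_tolerance_accepts_first_candidate(self):
        target = DesignTarget(NINE, epsilon=1e6)
        sampler = ScreeningSampler(seed=1)
        gen, pred = _stub_pipeline([np.asarray(NINE) + 1.0])
        result = screen(target, sampler, generator=gen, predictor=pred,
                        verifier=pred, max_evaluations=5, save_index=2,
                        grid_shape=(16, 16, 16), min_volume=1)
        assert result.success and result.n_evaluated == 1

    def test_acceptance_requires_verifier_agreement(self):
        """A flattering prediction alone must not accept a candidate."""
        target = DesignTarget(NINE, epsilon=0.05)
        sampler = ScreeningSampler(seed=2)
        calls = {"n": 0}
        gen, _ = _stub_pipeline([NINE])

        def predictor(structure):
            return np.asarray(NINE)          # always claims a perfect match

        def verifier(structure):
            calls["n"] += 1
            if calls["n"] == 1:
                return np.asarray(NINE) + 1.0   # first candidate is a lie
            return np.asarray(NINE)
        result = screen(target, sampler, generator=gen, predictor=predictor,
                        verifier=verifier, max_evaluations=5, save_index=2,
                        grid_shape=(16, 16, 16), min_volume=1)
        assert result.n_evaluated == 2
        assert result.verification["max_deviation"] < 0.05

    def test_unreachable_target_fails_with_best_candidate(self):
        target = DesignTarget(NINE, epsilon=1e-6)
        sampler = ScreeningSampler(seed=3)
        gen, pred = _stub_pipeline([np.asarray(NINE) + 5.0,
                                    np.asarray(NINE) + 2.0,
                                    np.asarray(NINE) + 4.0])
        with pytest.raises(ScreeningFailure) as err:
            screen(target, sampler, generator=gen, predictor=pred,
                   verifier=pred, max_evaluations=3, save_index=2,
                   grid_shape=(16, 16, 16), min_volume=1)
        res = err.value.result
        assert not res.success
        assert res.n_evaluated == 3
        assert res.best_deviation == pytest.approx(2.0)

    def test_screening_reproducible_for_fixed_seed(self):
        target = DesignTarget(NINE, epsilon=0.5)
        gen1, pred1 = _stub_pipeline([np.asarray(NINE) + 3.0,
                                      np.asarray(NINE) + 0.1])
        gen2, pred2 = _stub_pipeline([np.asarray(NINE) + 3.0,
                                      np.asarray(NINE) + 0.1])
        r1 = screen(target, ScreeningSampler(seed=4), generator=gen1,
                    predictor=pred1, verifier=pred1, max_evaluations=5,
                    save_index=2, grid_shape=(16, 16, 16), min_volume=1)
        r2 = screen(target, ScreeningSampler(seed=4), generator=gen2,
                    predictor=pred2, verifier=pred2, max_evaluations=5,
                    save_index=2, grid_shape=(16, 16, 16), min_volume=1)
        assert r1.n_evaluated == r2.n_evaluated == 2
        assert r1.accepted_spec == r2.accepted_spec


class TestShapeMasks:
    def test_cylinder_volume_analytic(self):
        grid = GridSpec((64, 64, 128))
        mask = make_shape_mask("cylinder", {"radius": 20, "height": 100}, grid)
        assert mask.sum() == pytest.approx(np.pi * 20**2 * 100, rel=0.02)

    def test_degenerate_shell_rejected(self):
        grid = GridSpec((32, 32, 32))
        with pytest.raises(ValidationError):
            make_shape_mask("shell", {"outer_radius": 10, "inner_radius": 10},
                            grid)

    def test_zero_taper_stem_equals_cylinder(self):
        grid = GridSpec((48, 48, 64))
        stem = make_shape_mask("stem", {"radius_top": 12, "radius_bottom": 12,
                                        "height": 40}, grid)
        cyl = make_shape_mask("cylinder", {"radius": 12, "height": 40}, grid)
        assert np.array_equal(stem, cyl)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValidationError, match="cylinder"):
            make_shape_mask("torus", {}, GridSpec((16, 16, 16)))

    def test_shell_is_hemispherical(self):
        grid = GridSpec((48, 48, 48))
        mask = make_shape_mask("shell", {"outer_radius": 20,
                                         "inner_radius": 14}, grid)
        assert mask[:, :, 30:].sum() == 0       # nothing above the equator
        # half of a spherical shell volume
        want = 0.5 * 4 / 3 * np.pi * (20**3 - 14**3)
        assert mask.sum() == pytest.approx(want, rel=0.05)


class TestLeverRule:
    def test_values(self):
        assert lever_rule_porosity(0.0) == pytest.approx(0.5)
        assert lever_rule_porosity(-0.5) == pytest.approx(0.75)
        assert lever_rule_porosity(0.7) == 0.0
        assert lever_rule_porosity(-0.7) == 1.0
        assert lever_rule_porosity(SPINODAL_MU_LIMIT + 0.01) == 0.0


class TestGradientImplant:
    def test_constant_profile_is_pipeline_identity(self):
        """Constant mu + full mask must equal the plain pipeline exactly."""
        params = CHParams(n_saves=5)
        shape = (16, 16, 16)
        grid = params.make_grid(shape)
        mu_field = np.full(shape, 0.0)
        gspec = GradientInitSpec(mu_field, seed=21)
        spec = ImplantDesignSpec(np.ones(shape, bool), gspec)
        structure, report = design_gradient_implant(spec, params, min_volume=30)
        manual = filter_artifacts(
            threshold_extract(simulate(init_gradient(grid, gspec), params)[5]),
            min_volume=30)
        assert np.array_equal(structure.solid, manual.solid)

    def test_zone_report_flags_violations(self):
        params = CHParams(n_saves=4)
        shape = (16, 16, 16)
        mu_field = np.full(shape, 0.0)
        spec = ImplantDesignSpec(np.ones(shape, bool),
                                 GradientInitSpec(mu_field, seed=2))
        zones = {"all": np.ones(shape, bool)}
        # claim the whole volume should be dense: a mu=0 run (porosity ~0.5)
        # must trigger the 5-percentage-point warning
        _, report = design_gradient_implant(spec, params, zones=zones,
                                            zone_mu={"all": 0.7},
                                            min_volume=30)
        assert report["warnings"]
        assert report["zone_porosity"]["all"] == pytest.approx(0.5, abs=0.1)

    def test_empty_zone_rejected(self, spinodal32):
        with pytest.raises(ValidationError):
            zone_porosity(spinodal32, {"empty": np.zeros((32, 32, 32), bool)})

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            ImplantDesignSpec(np.zeros((8, 8, 8), bool),
                              GradientInitSpec(np.zeros((8, 8, 8)), seed=0))
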