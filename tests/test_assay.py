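import dataclasses

import numpy as np
import pytest

from bivalbind import presets
from bivalbind.reaction_model import CellLine, RateConstantSet, SpeciesState
from bivalbind.assay import (
    AssayProtocol,
    OccupancySummary,
    combination_occupancy,
    dose_receptor_grid,
    relative_binding,
    restrict_monovalent,
    simulate_assay,
    simulate_combination,
    summarize_occupancy,
    total_bound_antibody,
)

ANALYSIS = AssayProtocol.analysis()


def swap_params(params: RateConstantSet) -> RateConstantSet:
    """Exchange the 6R and 8R roles of every rate constant."""
    return RateConstantSet(
        kon_6R=params.kon_8R,
        kon_8R=params.kon_6R,
        kon_6R_star=params.kon_8R_star,
        kon_8R_star=params.kon_6R_star,
        koff_6R=params.koff_8R,
        koff_8R=params.koff_6R,
        alpha=params.alpha,
    )


class TestProtocol:
    def test_defaults(self):
        p = AssayProtocol.fitting()
        assert p.resolved_washout_time == 7200.0
        assert p.resolved_horizon == 8100.0
        a = AssayProtocol.analysis()
        assert not a.washout
        assert a.resolved_horizon == 86400.0

    def test_washout_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            AssayProtocol(washout=True, washout_time=5000.0, horizon=1000.0)


class TestSimulateAssay:
    def test_no_receptors_no_binding(self, best_fit):
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["parental"], 100.0, best_fit
        )
        assert np.all(res.states[:, 3:] == 0.0)

    def test_no_cognate_receptor_no_binding(self, best_fit):
        res = simulate_assay(
            presets.TOCILIZUMAB, presets.CELL_LINES["IL8R+"], 100.0, best_fit
        )
        assert total_bound_antibody(res.terminal_state) == 0.0

    def test_receptor_conservation_along_trajectory(self, best_fit):
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], 100.0, best_fit
        )
        r1_total = res.states[:, 1] + res.states[:, 3] + res.states[:, 5]
        r2_total = res.states[:, 2] + res.states[:, 4] + res.states[:, 5]
        np.testing.assert_allclose(r1_total, 3.16e5, rtol=1e-6)
        np.testing.assert_allclose(r2_total, 6.18e5, rtol=1e-6)

    def test_antibody_conservation_pre_washout(self, best_fit):
        dose = 10.0
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], dose, best_fit
        )
        # up to and including the first grid point at the washout time
        # (the second one is the post-reset state)
        pre = slice(0, int(np.searchsorted(res.time, 7200.0)) + 1)
        total = res.states[pre, 0] + best_fit.alpha * res.states[pre, 3:].sum(axis=1)
        np.testing.assert_allclose(total, dose, rtol=1e-6)

    def test_ternary_grows_after_washout(self, best_fit):
        # washout frees receptor from binary complexes, which existing binary
        # complexes then cross-link: terminal ternary >= ternary at washout
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], 100.0, best_fit
        )
        at_washout = res.state_at_time(7200.0).ternary
        assert res.terminal_state.ternary >= at_washout

    def test_washout_monotonicity(self, best_fit):
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], 100.0, best_fit
        )
        post = res.time > 7200.0
        bound_ab = res.states[post, 3:].sum(axis=1)
        assert np.all(np.diff(bound_ab) <= 1e-9 * bound_ab[0])
        ternary = res.states[post, 5]
        # non-decreasing up to its plateau, modulo a tiny mass-action
        # transient right after the washout step
        assert np.all(np.diff(ternary) >= -1e-5 * ternary[0])

    def test_clamped_washout_keeps_antibody_at_zero(self, best_fit):
        protocol = AssayProtocol.fitting(clamp_washout=True)
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], 100.0, best_fit, protocol
        )
        post = res.time > 7200.0
        assert np.all(res.states[post, 0] == 0.0)

    def test_saturation_equivalence_mono_vs_bispecific(self, best_fit):
        # with antibody >= 1e3 x KD and sparse receptors, bound antibody per
        # cell converges between the monospecific and the bispecific
        cell = CellLine("sparse", 1e3, 0.0)
        dose = 1e4
        res_mono = simulate_assay(
            presets.TOCILIZUMAB, cell, dose, best_fit, ANALYSIS, points_per_phase=2
        )
        res_bs = simulate_assay(
            presets.BS1, cell, dose, best_fit, ANALYSIS, points_per_phase=2
        )
        n_mono = total_bound_antibody(res_mono.terminal_state)
        n_bs = total_bound_antibody(res_bs.terminal_state)
        assert n_mono == pytest.approx(n_bs, rel=0.05)


class TestOccupancy:
    def test_direct_application(self):
        state = SpeciesState(0.0, 0.0, 0.0, 3.0, 4.0, 5.0)
        cell = CellLine("c", 10.0, 10.0)
        occ = summarize_occupancy(state, cell)
        assert occ.bound_binary == 7.0
        assert occ.bound_ternary == 10.0
        assert occ.bound_total == 17.0

    def test_all_free(self):
        state = SpeciesState(1.0, 10.0, 10.0, 0.0, 0.0, 0.0)
        occ = summarize_occupancy(state, CellLine("c", 10.0, 10.0))
        assert occ.bound_total == 0.0
        assert occ.frac_total == 0.0

    def test_ternary_saturated_fraction_is_one(self):
        n = 1e4
        state = SpeciesState(0.0, 0.0, 0.0, 0.0, 0.0, n)
        occ = summarize_occupancy(state, CellLine("c", n, n))
        assert occ.frac_total == pytest.approx(1.0)
        assert occ.occ_il6r == pytest.approx(1.0)
        assert occ.occ_il8r == pytest.approx(1.0)

    def test_zero_receptor_flagged(self):
        state = SpeciesState(1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        occ = summarize_occupancy(state, CellLine("empty", 0.0, 0.0))
        assert occ.undefined
        assert occ.frac_total == 0.0

    def test_homobivalent_per_receptor_occupancy(self):
        state = SpeciesState(0.0, 4.0, 10.0, 2.0, 0.0, 2.0)
        cell = CellLine("c", 10.0, 10.0)
        occ = summarize_occupancy(state, cell, presets.TOCILIZUMAB)
        # binary holds 1 IL-6R, each ternary holds 2
        assert occ.occ_il6r == pytest.approx(0.6)
        assert occ.occ_il8r == 0.0


class TestTotalBoundAntibody:
    def test_counts(self):
        state = SpeciesState(0.0, 0.0, 0.0, 3.0, 4.0, 5.0)
        assert total_bound_antibody(state) == 12.0
        assert total_bound_antibody(SpeciesState(1.0, 5.0, 5.0, 0, 0, 0)) == 0.0

    def test_conservation_oracle(self, best_fit):
        dose = 10.0
        res = simulate_assay(
            presets.BS1,
            presets.CELL_LINES["IL6R+IL8R+"],
            dose,
            best_fit,
            AssayProtocol.analysis(horizon=7200.0),
        )
        state = res.terminal_state
        expected = dose / best_fit.alpha - state.free_ab / best_fit.alpha
        assert total_bound_antibody(state) == pytest.approx(expected, rel=1e-6)


class TestMonovalentRestriction:
    def test_idempotent(self, best_fit):
        once = restrict_monovalent(best_fit)
        assert restrict_monovalent(once) == once
        assert once.kon_6R_star == 0.0 and once.kon_8R_star == 0.0
        assert once.kon_6R == best_fit.kon_6R

    def test_no_ternary_ever(self, best_fit):
        params = restrict_monovalent(best_fit)
        res = simulate_assay(
            presets.BS1, presets.CELL_LINES["IL6R+IL8R+"], 100.0, params
        )
        assert np.all(res.states[:, 5] == 0.0)

    def test_receptor_level_invariance_with_excess_antibody(self, best_fit):
        params = restrict_monovalent(best_fit)
        levels = [(r, r) for r in np.logspace(2, 5, 7)]
        grid = dose_receptor_grid(presets.BS1, [100.0], levels, params)
        frac = grid["frac_total"].to_numpy()
        assert frac.max() - frac.min() <= 1e-3


class TestGrids:
    def test_bsab_matches_mab_combination_at_equal_receptors(self, best_fit):
        # doses where 24 h reaches near-equilibrium; at low doses the
        # association timescale approaches the horizon and small transient
        # differences between the constructs remain
        doses = [10.0, 1000.0]
        levels = [(1e4, 1e4), (1e5, 1e5)]
        g_bs = dose_receptor_grid(presets.BS1, doses, levels, best_fit)
        g_mab = dose_receptor_grid(
            (presets.TOCILIZUMAB, presets.TENH2), doses, levels, best_fit
        )
        for col in ("frac_total", "frac_binary", "frac_ternary"):
            np.testing.assert_allclose(
                g_bs[col].to_numpy(), g_mab[col].to_numpy(), atol=1e-3
            )

    def test_ternary_fraction_unimodal_in_dose(self, best_fit):
        doses = np.logspace(-2, 4, 19)
        grid = dose_receptor_grid(presets.BS1, doses, [(1e6, 1e6)], best_fit)
        frac = grid["frac_ternary"].to_numpy()
        peak = int(np.argmax(frac))
        assert 0 < peak < frac.size - 1  # rises then falls
        assert np.all(np.diff(frac[: peak + 1]) > 0)
        assert np.all(np.diff(frac[peak:]) < 0)

    def test_total_bound_monotone_in_dose(self, best_fit):
        doses = np.logspace(-2, 3, 11)
        levels = [(1e3, 1e3), (1e5, 1e5)]
        grid = dose_receptor_grid(presets.BS1, doses, levels, best_fit)
        for _, sub in grid.groupby("il6r_per_cell"):
            frac = sub.sort_values("dose_nM")["frac_total"].to_numpy()
            assert np.all(np.diff(frac) >= -1e-9)

    def test_grid_symmetry_under_receptor_swap(self, best_fit):
        swapped = swap_params(best_fit)
        doses = [1.0, 100.0]
        g1 = dose_receptor_grid(presets.BS1, doses, [(1e3, 1e5)], best_fit)
        g2 = dose_receptor_grid(presets.BS1, doses, [(1e5, 1e3)], swapped)
        np.testing.assert_allclose(
            g1["frac_total"].to_numpy(), g2["frac_total"].to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            g1["occ_il6r"].to_numpy(), g2["occ_il8r"].to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            g1["occ_il8r"].to_numpy(), g2["occ_il6r"].to_numpy(), rtol=1e-6
        )


class TestCombination:
    def test_validation(self, best_fit):
        with pytest.raises(ValueError):
            simulate_combination(
                (presets.BS1, presets.TENH2),
                presets.CELL_LINES["IL6R+IL8R+"],
                10.0,
                best_fit,
            )
        with pytest.raises(ValueError):
            simulate_combination(
                (presets.TOCILIZUMAB, presets.TOCILIZUMAB),
                presets.CELL_LINES["IL6R+IL8R+"],
                10.0,
                best_fit,
            )

    def test_dose_split(self, best_fit):
        res_a, res_b = simulate_combination(
            (presets.TOCILIZUMAB, presets.TENH2),
            presets.CELL_LINES["IL6R+IL8R+"],
            10.0,
            best_fit,
            ANALYSIS,
            points_per_phase=2,
        )
        assert res_a.dose == 5.0 and res_b.dose == 5.0


class TestRelativeBinding:
    def _occ(self, **kwargs):
        base = dict(
            bound_binary=0.0, bound_ternary=0.0, bound_total=0.0,
            frac_binary=0.0, frac_ternary=0.0, frac_total=0.0,
            occ_il6r=0.0, occ_il8r=0.0,
        )
        base.update(kwargs)
        return OccupancySummary(**base)

    def test_identical_summaries_give_unity(self):
        occ = self._occ(frac_total=0.5, occ_il6r=0.4, occ_il8r=0.6)
        rel = relative_binding(occ, occ)
        assert rel.overall == rel.il6r == rel.il8r == 1.0
        assert rel.flags == ()

    def test_zero_over_zero_flagged(self):
        rel = relative_binding(self._occ(), self._occ())
        assert rel.overall == 1.0
        assert "overall:0/0" in rel.flags

    def test_infinite_ratio(self):
        rel = relative_binding(self._occ(frac_total=0.1), self._occ())
        assert rel.overall == np.inf

    def test_equal_receptor_ratio_overall_near_unity(self, best_fit):
        cell = CellLine("sym", 5e4, 5e4)
        res = simulate_assay(
            presets.BS1, cell, 10.0, best_fit, ANALYSIS, points_per_phase=2
        )
        occ_bs = summarize_occupancy(res.terminal_state, cell, presets.BS1)
        res_a, res_b = simulate_combination(
            (presets.TOCILIZUMAB, presets.TENH2), cell, 10.0, best_fit,
            ANALYSIS, points_per_phase=2,
        )
        occ_mab = combination_occupancy(res_a, res_b, cell)
        rel = relative_binding(occ_bs, occ_mab)
        assert rel.overall == pytest.approx(1.0, abs=5e-3)

    def test_bispecific_favors_limiting_receptor(self, best_fit):
        cell = CellLine("skew", 1e3, 1e6)
        res = simulate_assay(
            presets.BS1, cell, 10.0, best_fit, ANALYSIS, points_per_phase=2
        )
        occ_bs = summarize_occupancy(res.terminal_state, cell, presets.BS1)
        res_a, res_b = simulate_combination(
            (presets.TOCILIZUMAB, presets.TENH2), cell, 10.0, best_fit,
            ANALYSIS, points_per_phase=2,
        )
        occ_mab = combination_occupancy(res_a, res_b, cell)
        rel = relative_binding(occ_bs, occ_mab)
        assert rel.il6r > 1.0  # limited receptor: bispecific binds more
        assert rel.il8r < 1.0  # excess receptor: combination binds more
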