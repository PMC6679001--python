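"""Local beat asymmetry, difference curves, pointwise ANOVA and regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flagbeat.asymmetry import (
    AsymmetryProfile,
    asymmetry_profile,
    difference_curve,
    pointwise_anova,
    significant_regions,
)
from flagbeat.kinematics import CurvatureField
from flagbeat.synthetic import (
    WaveformParams,
    arc_offset,
    generate_waveform,
    simulate_asymmetry_profiles,
)


def field_from_truth(truth):
    """Ground-truth curvature field wrapped as a CurvatureField."""
    theta = truth.curvature_angle.copy()
    valid = np.isfinite(theta)
    theta[~valid] = 0.0
    return CurvatureField(
        s_um=truth.s_um, t_s=truth.t_s, theta_rad=theta, valid=valid,
        frame_rate_hz=truth.params.frame_rate_hz,
    )


def make_profile(s, a, sperm_id="x", condition="c"):
    a = np.asarray(a, dtype=float)
    return AsymmetryProfile(
        s_um=np.asarray(s, dtype=float), a_deg=a,
        valid=np.isfinite(a), n_frames=400, sperm_id=sperm_id, condition=condition,
    )


class TestAsymmetryProfile:
    def test_symmetric_beat_exactly_zero(self):
        """Perfectly symmetric beat over integer cycles: a(s) = 0."""
        p = WaveformParams(beat_freq_hz=20, n_frames=400)
        prof = asymmetry_profile(field_from_truth(generate_waveform(p)))
        assert np.nanmax(prof.a_deg[prof.valid]) <= 1e-6

    def test_static_arc_offset_recovered_in_degrees(self):
        """0.2 rad static curvature offset -> a(s) = 11.459 degrees."""
        p = WaveformParams(beat_freq_hz=20, n_frames=400, asym_offset=arc_offset(0.2))
        field = field_from_truth(generate_waveform(p))
        prof = asymmetry_profile(field)
        interior = prof.valid & (field.s_um >= 15) & (field.s_um <= 60)
        np.testing.assert_allclose(prof.a_deg[interior], np.degrees(0.2), atol=0.06)

    def test_sign_flip_invariance(self, beat_field):
        import dataclasses

        p1 = asymmetry_profile(beat_field)
        flipped = dataclasses.replace(beat_field, theta_rad=-beat_field.theta_rad)
        p2 = asymmetry_profile(flipped)
        np.testing.assert_allclose(p1.a_deg[p1.valid], p2.a_deg[p2.valid])

    def test_time_reversal_invariance(self, beat_field):
        import dataclasses

        rev = dataclasses.replace(
            beat_field, theta_rad=beat_field.theta_rad[:, ::-1],
            valid=beat_field.valid[:, ::-1],
        )
        p1 = asymmetry_profile(beat_field)
        p2 = asymmetry_profile(rev)
        np.testing.assert_allclose(p1.a_deg[p1.valid], p2.a_deg[p2.valid])

    def test_sparse_positions_masked(self, beat_field):
        import dataclasses

        valid = beat_field.valid.copy()
        valid[3, : valid.shape[1] // 2 + 1] = False  # > 50 % missing
        prof = asymmetry_profile(dataclasses.replace(beat_field, valid=valid))
        assert not prof.valid[3]


class TestDifferenceCurve:
    def test_self_difference_zero(self):
        s = np.arange(10.0)
        g = [make_profile(s, np.arange(10) + i, sperm_id=f"s{i}") for i in range(3)]
        comp = difference_curve(g, g, paired=True)
        np.testing.assert_allclose(comp.delta_mean_deg, 0.0)
        np.testing.assert_allclose(comp.delta_sd_deg, 0.0)

    def test_two_sperm_hand_computed(self):
        """Differences +2 and +4 degrees: mean 3, SD sqrt(2)."""
        s = np.arange(5.0)
        a = [make_profile(s, np.full(5, 1.0), "u"), make_profile(s, np.full(5, 2.0), "v")]
        b = [make_profile(s, np.full(5, 3.0), "u"), make_profile(s, np.full(5, 6.0), "v")]
        comp = difference_curve(a, b, paired=True)
        np.testing.assert_allclose(comp.delta_mean_deg, 3.0)
        np.testing.assert_allclose(comp.delta_sd_deg, np.sqrt(2.0))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        s = np.arange(20.0)
        a = [make_profile(s, rng.normal(5, 1, 20), f"s{i}") for i in range(4)]
        b = [make_profile(s, rng.normal(6, 1, 20), f"s{i}") for i in range(4)]
        ab = difference_curve(a, b, paired=True)
        ba = difference_curve(b, a, paired=True)
        np.testing.assert_allclose(ab.delta_mean_deg, -ba.delta_mean_deg)

    def test_unmatched_ids_fall_back_unpaired(self):
        s = np.arange(5.0)
        a = [make_profile(s, np.full(5, 1.0), "u"), make_profile(s, np.full(5, 3.0), "v")]
        b = [make_profile(s, np.full(5, 4.0), "w"), make_profile(s, np.full(5, 6.0), "x")]
        with pytest.warns(UserWarning, match="unpaired"):
            comp = difference_curve(a, b, paired=True)
        assert not comp.paired
        np.testing.assert_allclose(comp.delta_mean_deg, 3.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            difference_curve([], [make_profile(np.arange(3.0), [1, 2, 3])])


class TestPointwiseAnova:
    def test_identical_constants_degenerate(self):
        s = np.arange(8.0)
        g = {
            "A": [make_profile(s, np.full(8, 2.0), f"a{i}") for i in range(3)],
            "B": [make_profile(s, np.full(8, 2.0), f"b{i}") for i in range(3)],
        }
        with pytest.raises(ValueError, match="degenerate|identical"):
            pointwise_anova(g, compute_omnibus=False)

    def test_single_sperm_condition_rejected(self):
        s = np.arange(8.0)
        g = {
            "A": [make_profile(s, np.arange(8.0), "a0")],
            "B": [make_profile(s, np.arange(8.0), f"b{i}") for i in range(3)],
        }
        with pytest.raises(ValueError):
            pointwise_anova(g, compute_omnibus=False)

    def test_deficient_cell_named(self):
        s = np.arange(8.0)
        a0 = np.arange(8.0)
        a1 = a0.copy()
        a1[5] = np.nan  # only one observation left in cell (A, s=5)
        g = {
            "A": [make_profile(s, a0, "a0"), make_profile(s, a1, "a1")],
            "B": [make_profile(s, a0 + 1, "b0"), make_profile(s, a0 + 2, "b1")],
        }
        with pytest.raises(ValueError, match="5"):
            pointwise_anova(g, compute_omnibus=False)

    def test_strong_effect_detected_where_injected(self):
        rng = np.random.default_rng(5)
        a = simulate_asymmetry_profiles(10, condition="A", rng=rng)
        b = simulate_asymmetry_profiles(
            10, effect_deg=lambda s: np.where(s < 30, 3.0, 0.0), condition="B", rng=rng
        )
        comp = pointwise_anova({"A": a, "B": b}, compute_omnibus=False)
        sig_s = comp.s_um[comp.significant]
        assert ((sig_s >= 0) & (sig_s <= 30)).any()
        assert comp.anova_table is None

    def test_omnibus_table_present(self):
        rng = np.random.default_rng(6)
        g = {
            "A": simulate_asymmetry_profiles(4, condition="A", rng=rng),
            "B": simulate_asymmetry_profiles(
                4, effect_deg=lambda s: np.full_like(s, 2.0), condition="B", rng=rng
            ),
        }
        comp = pointwise_anova(g)
        assert comp.anova_table is not None
        assert "C(condition)" in comp.anova_table.index


class TestRegions:
    def test_hand_built_runs(self):
        s = np.arange(10.0)
        p = np.array([0.5, 0.01, 0.02, 0.5, 0.04, 0.5, 0.001, 0.002, 0.003, 0.9])
        regs = significant_regions(s, p, alpha=0.05)
        assert [(r.start_um, r.end_um) for r in regs] == [(1, 2), (4, 4), (6, 8)]
        assert [r.min_p for r in regs] == [0.01, 0.04, 0.001]

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_regions_are_maximal_and_minp_exact(self, pvals):
        p = np.asarray(pvals)
        s = np.arange(len(p), dtype=float)
        regs = significant_regions(s, p, alpha=0.05)
        covered = np.zeros(len(p), dtype=bool)
        for r in regs:
            i, j = int(r.start_um), int(r.end_um)
            assert (p[i : j + 1] < 0.05).all()
            assert r.min_p == p[i : j + 1].min()
            # maximality: neighbors outside the run are not significant
            assert i == 0 or p[i - 1] >= 0.05
            assert j == len(p) - 1 or p[j + 1] >= 0.05
            covered[i : j + 1] = True
        np.testing.assert_array_equal(covered, p < 0.05)
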