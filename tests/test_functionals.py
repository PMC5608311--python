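"""Static, short-term and long-term functionals and vector assembly."""

import numpy as np
import pytest

from dyadvox.corpus import Turn
from dyadvox.frame_features import FEATURE_NAMES
from dyadvox import functionals as fx
from conftest import make_track, make_interaction, make_sample

N = len(FEATURE_NAMES)


def track_with_column(col_values, column=0, n_features=N, fill=1.0, **kw):
    vals = np.full((len(col_values), n_features), fill)
    vals[:, column] = col_values
    return make_track(vals, **kw)


class TestTurnMeans:
    def test_constant_track_constant_means(self):
        track = make_track(np.full((100, N), 5.0))
        turns = [Turn("H", 0.0, 0.5), Turn("W", 0.5, 1.0)]
        series = fx.turn_means(track, turns)
        assert len(series.roles) == 2
        np.testing.assert_allclose(series.means, 5.0)

    def test_small_turn_mean_arithmetic(self):
        track = track_with_column([1.0, 2.0, 3.0])
        series = fx.turn_means(track, [Turn("H", 0.0, 0.03)])
        assert series.means[0, 0] == pytest.approx(2.0)

    def test_unvoiced_pitch_missing_intensity_present(self):
        vals = np.full((30, N), 2.0)
        pitch_col = FEATURE_NAMES.index("pitch")
        vals[:, pitch_col] = np.nan
        series = fx.turn_means(make_track(vals), [Turn("H", 0.0, 0.3)])
        assert np.isnan(series.means[0, pitch_col])
        assert series.means[0, FEATURE_NAMES.index("intensity")] == 2.0

    def test_short_turns_dropped(self):
        track = make_track(np.ones((100, N)))
        series = fx.turn_means(track, [Turn("H", 0.0, 0.015)])  # < 3 frames
        assert len(series.roles) == 0


def series_from(roles, values):
    """One-feature turn series (remaining features constant)."""
    means = np.full((len(roles), N), 0.0)
    means[:, 0] = values
    return fx.TurnMeanSeries(roles=np.asarray(roles, dtype=object),
                             starts=np.arange(len(roles), dtype=float),
                             means=means, feature_names=FEATURE_NAMES)


class TestTurnDeltas:
    def test_successive_h_means(self):
        deltas = fx.turn_deltas(series_from(["H", "H"], [3.0, 7.0]))
        assert deltas["HH"][:, 0].tolist() == [4.0]
        assert len(deltas["WW"]) == 0 and len(deltas["HW"]) == 0

    def test_identical_turns_zero(self):
        deltas = fx.turn_deltas(series_from(["H", "W", "H", "W"], [2.0] * 4))
        for seq in deltas.values():
            np.testing.assert_allclose(seq, 0.0)

    def test_hand_enumerated_sequence(self):
        """H(2), W(5), H(4), W(1): HW=[3,-3], HH=[2], WW=[-4]."""
        deltas = fx.turn_deltas(series_from(["H", "W", "H", "W"],
                                            [2.0, 5.0, 4.0, 1.0]))
        assert deltas["HW"][:, 0].tolist() == [3.0, -3.0]
        assert deltas["HH"][:, 0].tolist() == [2.0]
        assert deltas["WW"][:, 0].tolist() == [-4.0]

    def test_within_speaker_skips_other_speaker(self):
        deltas = fx.turn_deltas(series_from(["H", "W", "W", "H"],
                                            [1.0, 9.0, 9.0, 6.0]))
        assert deltas["HH"][:, 0].tolist() == [5.0]


class TestShortTermFunctionals:
    def test_stat_arithmetic(self):
        deltas = {"HH": np.tile([[4.0], [-4.0]], (1, N)),
                  "HW": np.empty((0, N)), "WW": np.empty((0, N))}
        frag = fx.short_term_functionals(deltas, FEATURE_NAMES)
        feat = FEATURE_NAMES[0]
        assert frag[f"HH.{feat}.mean"] == 0.0
        assert frag[f"HH.{feat}.min"] == -4.0
        assert frag[f"HH.{feat}.max"] == 4.0
        assert np.isnan(frag[f"HW.{feat}.mean"])

    def test_single_element_population_std_zero(self):
        deltas = {"HH": np.full((1, N), 2.0),
                  "HW": np.empty((0, N)), "WW": np.empty((0, N))}
        frag = fx.short_term_functionals(deltas, FEATURE_NAMES)
        assert frag[f"HH.{FEATURE_NAMES[0]}.std"] == 0.0


class TestStaticFunctionals:
    def test_constant_feature(self):
        frag = fx.static_functionals(make_track(np.full((50, N), 3.0)))
        feat = FEATURE_NAMES[0]
        assert frag[f"{feat}.mean"] == 3.0
        assert frag[f"{feat}.median"] == 3.0
        assert frag[f"{feat}.std"] == 0.0
        assert frag[f"{feat}.iqr"] == 0.0

    def test_order_statistics_arithmetic(self):
        frag = fx.static_functionals(track_with_column([1.0, 2.0, 3.0, 4.0]))
        feat = FEATURE_NAMES[0]
        assert frag[f"{feat}.mean"] == 2.5
        assert frag[f"{feat}.median"] == 2.5
        assert frag[f"{feat}.min"] == 1.0
        assert frag[f"{feat}.max"] == 4.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((40, N))
        frag1 = fx.static_functionals(make_track(vals))
        frag2 = fx.static_functionals(make_track(vals[rng.permutation(40)]))
        for k in frag1:
            assert frag1[k] == pytest.approx(frag2[k], abs=1e-12)


def quartered_interaction(quarter_values, couple="c0", timepoint="pre",
                          topic="husband_chosen", frames_per_quarter=10):
    """Interaction whose feature 0 is constant within each of 4 quarters;
    H and W tracks interleave so pooled quarters match per-role quarters."""
    per_q = frames_per_quarter
    tracks = {}
    for ri, role in enumerate(("H", "W")):
        vals = np.full((4 * per_q, N), 0.0)
        for q, v in enumerate(quarter_values):
            vals[q * per_q:(q + 1) * per_q, 0] = v
        t0 = 0.005 * ri  # interleave the two roles on the time axis
        tracks[role] = make_track(vals, hop=0.01, t0=t0)
    return make_interaction(couple, timepoint, topic, tracks)


class TestLongTermFunctionals:
    def test_identical_sessions_all_zero(self):
        pre = quartered_interaction([1.0, 2.0, 3.0, 4.0])
        post = quartered_interaction([1.0, 2.0, 3.0, 4.0], timepoint="26wk")
        frag = fx.long_term_functionals(pre, post)
        assert len(frag) == 592
        vals = np.asarray(list(frag.values()))
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_reversed_quarters_z_score_oracle(self):
        """Quarter means 1..4 vs reversed: deltas follow the z-score oracle."""
        pre = quartered_interaction([1.0, 2.0, 3.0, 4.0])
        post = quartered_interaction([4.0, 3.0, 2.0, 1.0], timepoint="26wk")
        frag = fx.long_term_functionals(pre, post)
        # independent oracle: z-normalize [1,2,3,4] by population stats
        vals = np.asarray([1.0, 2.0, 3.0, 4.0])
        z = (vals - vals.mean()) / vals.std()
        expected = z[::-1] - z
        for q in range(4):
            for role in ("H", "W"):
                got = frag[f"q{q + 1}.{role}.{FEATURE_NAMES[0]}"]
                assert got == pytest.approx(expected[q], abs=0.01)

    def test_antisymmetry_under_session_swap(self):
        rng = np.random.default_rng(1)
        pre = quartered_interaction(rng.uniform(0, 5, 4))
        post = quartered_interaction(rng.uniform(0, 5, 4), timepoint="26wk")
        fwd = fx.long_term_functionals(pre, post)
        post2 = quartered_interaction(
            [pre.tracks["H"].values[i * 10, 0] for i in range(4)], timepoint="26wk")
        # swap: compute with arguments exchanged (topic/couple identical)
        rev = fx.long_term_functionals(post, pre)
        for k in fwd:
            assert fwd[k] == pytest.approx(-rev[k], abs=1e-10)

    def test_affine_rescaling_invariance(self):
        """Per-session gain/offset on a feature leaves deltas unchanged."""
        pre = quartered_interaction([1.0, 2.0, 3.0, 4.0])
        post = quartered_interaction([4.0, 1.0, 3.0, 2.0], timepoint="26wk")
        base = fx.long_term_functionals(pre, post)
        post_scaled = quartered_interaction([4.0 * 7 + 3, 1.0 * 7 + 3,
                                             3.0 * 7 + 3, 2.0 * 7 + 3],
                                            timepoint="26wk")
        scaled = fx.long_term_functionals(pre, post_scaled)
        for k in base:
            assert base[k] == pytest.approx(scaled[k], abs=1e-10)

    def test_degenerate_constant_feature_zero(self):
        pre = quartered_interaction([2.0] * 4)
        post = quartered_interaction([2.0] * 4, timepoint="26wk")
        frag = fx.long_term_functionals(pre, post)
        np.testing.assert_allclose(np.asarray(list(frag.values())), 0.0)


class TestAssembly:
    def _builder(self, value=1.0):
        def build(timepoint, topic, role):
            rng = np.random.default_rng(hash((timepoint, topic, role)) % 2**31)
            return make_track(value + 0.1 * rng.standard_normal((40, N)))
        return build

    def test_static_dimension_3552(self):
        vec = fx.assemble_feature_vector(make_sample(self._builder()), "static")
        assert vec.dimension == 3552

    def test_dynamic_and_composite_dimensions(self):
        sample = make_sample(self._builder())
        dyn = fx.assemble_feature_vector(sample, "dynamic")
        static = fx.assemble_feature_vector(sample, "static")
        acoustic = fx.assemble_feature_vector(sample, "acoustic_all")
        assert acoustic.dimension == static.dimension + dyn.dimension
        # short-term 74*6*3*4 + long-term 74*4*2*2
        assert dyn.dimension == 5328 + 1184

    def test_codes_set_requires_code_features(self):
        with pytest.raises(fx.FeatureAssemblyError):
            fx.assemble_feature_vector(make_sample(self._builder()), "codes")

    def test_unknown_set_rejected(self):
        with pytest.raises(fx.FeatureAssemblyError, match="unknown feature set"):
            fx.assemble_feature_vector(make_sample(self._builder()), "everything")

    def test_canonical_name_order_stable(self):
        sample = make_sample(self._builder())
        v1 = fx.assemble_feature_vector(sample, "static")
        v2 = fx.assemble_feature_vector(sample, "static")
        assert v1.names == v2.names
        np.testing.assert_array_equal(v1.values, v2.values)
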