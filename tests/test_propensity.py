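import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discomorb import (
    CANONICAL,
    PropensityScale,
    ScoringError,
    bvalue_disorder_score,
    compute_profile,
    default_registry,
    fraction_above_threshold,
    protein_score,
    set_mean_fraction,
    set_scores,
)
from .conftest import two_letter_scale, uniform_scale


class TestComputeProfile:
    def test_homopolymer_constant(self, record_factory):
        prof = compute_profile(record_factory("AAAAA"),
                               uniform_scale(0.5), window=3)
        assert np.allclose(prof.values, 0.5)

    def test_alternating_hand_computed(self, record_factory):
        # A=0, V=1 over "AVAVA", window 3, clipped at termini:
        # [ (0+1)/2, (0+1+0)/3, (1+0+1)/3, (0+1+0)/3, (1+0)/2 ]
        scale = two_letter_scale(0.0, 1.0)
        prof = compute_profile(record_factory("AVAVA"), scale, window=3)
        assert np.allclose(prof.values, [0.5, 1 / 3, 2 / 3, 1 / 3, 0.5])

    def test_unscored_residue_skipped_in_windows(self, record_factory):
        prof = compute_profile(record_factory("AXA"),
                               uniform_scale(0.4), window=3)
        assert np.allclose(prof.values, [0.4, 0.4, 0.4])

    def test_all_ambiguous_window_is_missing(self, record_factory):
        prof = compute_profile(record_factory("XXXXA"),
                               uniform_scale(0.4), window=3)
        assert np.isnan(prof.values[0])
        assert np.allclose(prof.values[3:], 0.4)

    @pytest.mark.parametrize("window", [2, 9])
    def test_invalid_window_rejected(self, record_factory, window):
        with pytest.raises(ValueError):
            compute_profile(record_factory("AVAVA"),
                            uniform_scale(0.5), window=window)

    @given(st.text(alphabet=CANONICAL, min_size=5, max_size=40),
           st.sampled_from([1, 3, 5]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reversal_symmetry(self, seq, window):
        """Reversing a sequence exactly reverses its profile."""
        from discomorb import ProteinRecord
        reg = default_registry()
        scale = reg.get("top_idp")
        fwd = compute_profile(ProteinRecord("f", "f", seq), scale, window)
        rev = compute_profile(ProteinRecord("r", "r", seq[::-1]), scale,
                              window)
        assert np.allclose(fwd.values, rev.values[::-1], equal_nan=True)


class TestProteinScore:
    def test_mean_examples(self, record_factory):
        prof = compute_profile(record_factory("AAA"),
                               uniform_scale(0.5), window=1)
        assert protein_score(prof) == pytest.approx(0.5)

    def test_hand_mean(self):
        from discomorb import Profile
        assert protein_score(Profile("p", "s", [0.2, 0.4, 0.9])) \
            == pytest.approx(0.5)
        assert protein_score(Profile("p", "s", [0.0, 1.0])) \
            == pytest.approx(0.5)

    def test_all_missing_raises_with_protein_name(self):
        from discomorb import Profile
        with pytest.raises(ScoringError, match="prot7"):
            protein_score(Profile("prot7", "s", [np.nan, np.nan]))

    @given(st.text(alphabet=CANONICAL, min_size=3, max_size=50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window1_equals_direct_average(self, seq):
        """With window=1 the profile mean is the plain per-residue mean."""
        from discomorb import ProteinRecord
        scale = default_registry().get("kyte_doolittle")
        rec = ProteinRecord("p", "p", seq)
        direct = np.mean([scale.values[a] for a in seq])
        assert protein_score(compute_profile(rec, scale, 1)) \
            == pytest.approx(direct)

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0),
           st.text(alphabet=CANONICAL, min_size=5, max_size=30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_equivariance(self, a, c, seq):
        """Affine rescaling of the scale maps scores by the same affine map
        and leaves fraction_above_threshold invariant under the mapped
        threshold."""
        from dataclasses import replace
        from discomorb import ProteinRecord
        scale = default_registry().get("top_idp")
        scaled = replace(scale, name="aff",
                         values={k: a * v + c
                                 for k, v in scale.values.items()})
        rec = ProteinRecord("p", "p", seq)
        p1 = compute_profile(rec, scale, 3)
        p2 = compute_profile(rec, scaled, 3)
        assert protein_score(p2) == pytest.approx(
            a * protein_score(p1) + c, rel=1e-9, abs=1e-9)
        thr = 0.1
        assert fraction_above_threshold(p2, a * thr + c) == pytest.approx(
            fraction_above_threshold(p1, thr))


class TestBvalueScore:
    def test_constant_above_floor(self, record_factory):
        scale = uniform_scale(0.5)
        scale = PropensityScale("n", "disorder", dict(scale.values),
                                normalized=True)
        assert bvalue_disorder_score(record_factory("MKV"), scale) \
            == pytest.approx(0.5)

    def test_floor_filters_residues(self, record_factory):
        vals = {a: 0.1 for a in CANONICAL}
        vals["W"] = 0.9
        scale = PropensityScale("n", "disorder", vals, normalized=True)
        # A, A below floor; W above -> mean of survivors = 0.9
        assert bvalue_disorder_score(record_factory("AAW"), scale) \
            == pytest.approx(0.9)

    def test_no_survivor_returns_missing(self, record_factory):
        vals = {a: 0.1 for a in CANONICAL}
        scale = PropensityScale("n", "disorder", vals, normalized=True)
        assert math.isnan(bvalue_disorder_score(record_factory("AA"), scale))

    def test_unnormalized_scale_rejected(self, record_factory, registry):
        with pytest.raises(ValueError, match="normalized"):
            bvalue_disorder_score(record_factory("MKV"),
                                  registry.get("top_idp"))


class TestFractionAboveThreshold:
    @pytest.mark.parametrize("values,thr,expect", [
        ([0.1, 0.6, 0.7, 0.2], 0.5, 0.5),
        ([0.1, 0.2], 0.5, 0.0),
        ([0.6, 0.7], 0.5, 1.0),
        ([0.5, 0.5], 0.5, 0.0),   # strictly greater
    ])
    def test_counting(self, values, thr, expect):
        from discomorb import Profile
        assert fraction_above_threshold(Profile("p", "s", values), thr) \
            == pytest.approx(expect)


class TestSetMeanFraction:
    def test_unweighted_mean(self, set_factory):
        # per-protein fractions on a two-letter scale with threshold 0.5:
        # "VVVV" -> 1.0, "AAAA" -> 0.0, "AAVV" windowed w=1 -> 0.5
        scale = two_letter_scale(0.0, 1.0)
        s = set_factory(["VVVV", "AAAA", "AAVV"])
        assert set_mean_fraction(s, scale, 0.5, window=1) \
            == pytest.approx(0.5)

    def test_singleton_identity(self, set_factory):
        scale = two_letter_scale(0.0, 1.0)
        s = set_factory(["VVVV"])
        assert set_mean_fraction(s, scale, 0.5, window=1) == 1.0


class TestScaleRegistry:
    def test_at_least_three_scales_per_class(self, registry):
        from discomorb import FEATURE_CLASSES
        for fc in FEATURE_CLASSES:
            assert len(registry.by_class(fc)) >= 3, fc

    def test_all_scales_cover_canonical_residues(self, registry):
        for s in registry.scales:
            assert set(s.values) >= set(CANONICAL)

    def test_bvalue_is_normalized(self, registry):
        s = registry.get("bvalue")
        assert s.normalized
        vals = list(s.values.values())
        assert min(vals) == 0.0 and max(vals) == 1.0

    def test_normalize_is_affine_order_preserving(self, registry):
        raw = registry.get("bfactor_vihinen")
        norm = registry.get("bvalue")
        order_raw = sorted(CANONICAL, key=raw.values.__getitem__)
        order_norm = sorted(CANONICAL, key=norm.values.__getitem__)
        assert order_raw == order_norm

    def test_tsv_plugin_round_trip(self, tmp_path, registry):
        path = tmp_path / "scale.tsv"
        lines = ["residue\tvalue"] + [f"{a}\t{i / 19:.4f}"
                                      for i, a in enumerate(CANONICAL)]
        path.write_text("\n".join(lines) + "\n")
        from discomorb import ScaleRegistry
        reg = ScaleRegistry()
        sc = reg.add_from_tsv(path, "custom", "disorder", normalized=True)
        assert sc.values["A"] == pytest.approx(
            CANONICAL.index("A") / 19, abs=1e-4)
        with pytest.raises(ValueError, match="duplicate"):
            reg.add(sc)

    def test_unknown_class_rejected(self, registry):
        with pytest.raises(ValueError):
            registry.by_class("solubility")


def test_disorder_biased_sets_score_higher_on_all_disorder_scales(registry):
    """Composition shifted toward disorder-promoting residues raises every
    bundled disorder scale's mean set score (generator ground truth)."""
    from discomorb import composition_preset, generate_set
    dis = generate_set(composition_preset("disordered"), 40, seed=1)
    ordd = generate_set(composition_preset("ordered"), 40, seed=2)
    for scale in registry.by_class("disorder"):
        assert set_scores(dis, scale).mean() > set_scores(ordd, scale).mean()
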