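"""Feature spaces, label encoding, FIR design construction, Gabor bank,
and the serially counterbalanced validation sequence."""

import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from affectencode.feature_space import (
    CATEGORIES,
    ANIMATE_CATEGORIES,
    EXCLUDED,
    FIRSpec,
    FeatureSpace,
    GaborBank,
    ImageLabel,
    build_design,
    build_feature_space,
    fir_expand,
    gabor_feature_matrix,
    gabor_features,
    median_split_arousal,
    resolve_valence,
    type1_index1_sequence,
)


@pytest.mark.parametrize("name,expected", [
    ("CSVA", 126 + 18),
    ("SemanticOnly", 21),
    ("ValenceArousal", 6),
    ("SVAA", 12 * 6 + 9),
    ("SVAI", 9 * 6 + 12),
])
def test_space_sizes(name, expected):
    assert len(build_feature_space(name)) == expected


def test_plants_vehicles_flag_extends_spaces():
    assert len(build_feature_space("CSVA", True)) == 23 * 6 + 18
    assert len(build_feature_space("SemanticOnly", True)) == 23


def test_unknown_model_name_rejected():
    with pytest.raises(ValueError):
        build_feature_space("Gabor")  # image-computed, not label-driven


@pytest.mark.parametrize("cats,expected", [
    ([-1, -1, 1], -1),          # strict mode
    ([-1, 0], 0),               # neutral tie rule
    ([-1, 1], EXCLUDED),        # opposite tie without neutral
    ([1, 1, 1, 1, 1, 1, 1, 1, 1], 1),
    ([0, 0, -1], 0),
    ([-1, -1, 1, 1, 0], EXCLUDED),  # neutral present but not tied
])
def test_resolve_valence(cats, expected):
    assert resolve_valence(cats) == expected


def test_resolve_valence_empty_rejected():
    with pytest.raises(ValueError):
        resolve_valence([])


def test_median_split_arousal():
    assert list(median_split_arousal([1, 5, 9])) == [0, 1, 1]
    # all identical ratings sit at the median -> all high
    assert list(median_split_arousal([4, 4, 4])) == [1, 1, 1]
    # even count: median is the central-order-statistic mean (5)
    assert list(median_split_arousal([2, 2, 8, 8])) == [0, 0, 1, 1]
    out = median_split_arousal({"a": 1, "b": 9})
    assert out == {"a": 0, "b": 1}
    with pytest.raises(ValueError):
        median_split_arousal([])


class TestEncoding:
    def test_one_hot_compound(self, csva_space):
        lab = ImageLabel("i0", "Household-Object", 0, 0)
        v = csva_space.encode(lab)
        assert v.sum() == 1.0
        assert v[csva_space.compound_slice].sum() == 1.0
        f = csva_space.decode_compound(v)
        assert (f.category, f.valence, f.arousal) == ("Household-Object", 0, 0)

    def test_se_bits_independent(self, csva_space):
        lab = ImageLabel("i1", "Human-Body", -1, 1, ("Mutilated humans",))
        v = csva_space.encode(lab)
        assert v[csva_space.compound_slice].sum() == 1.0
        assert v[csva_space.index("Mutilated humans")] == 1.0
        assert v.sum() == 2.0

    def test_excluded_label_rejected(self, csva_space):
        lab = ImageLabel("i2", "Bird", EXCLUDED, 0)
        with pytest.raises(ValueError):
            csva_space.encode(lab)

    def test_unknown_category_rejected(self):
        space = build_feature_space("CSVA", include_plants_vehicles=False)
        with pytest.raises(KeyError):
            space.encode(ImageLabel("i3", "Plants", 0, 0))

    @given(st.integers(0, 20), st.sampled_from([-1, 0, 1]),
           st.integers(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_compound_block_sums_to_one(self, ci, val, aro):
        space = build_feature_space("CSVA")
        v = space.encode(ImageLabel("x", CATEGORIES[ci], val, aro))
        assert v[space.compound_slice].sum() == 1.0
        f = space.decode_compound(v)
        assert (f.category, f.valence, f.arousal) == (CATEGORIES[ci], val, aro)

    @given(st.integers(0, 20), st.sampled_from([-1, 0, 1]),
           st.integers(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_svaa_svai_agree_with_semantic_on_uncrossed(self, ci, val, aro):
        lab = ImageLabel("x", CATEGORIES[ci], val, aro)
        so = build_feature_space("SemanticOnly")
        for name in ("SVAA", "SVAI"):
            sp = build_feature_space(name)
            v = sp.encode(lab)
            f = sp.decode_compound(v)
            crossed = (lab.category in ANIMATE_CATEGORIES) == (name == "SVAA")
            if crossed:
                assert f.kind == "compound" and f.valence == val
            else:
                assert f.kind == "semantic"
                assert f.category == so.decode_compound(so.encode(lab)).category

    def test_manifest_round_trip(self, csva_space, tmp_path):
        p = tmp_path / "space.json"
        csva_space.to_json(p)
        back = FeatureSpace.from_json(p)
        assert back.feature_names == csva_space.feature_names
        lab = ImageLabel("i", "Fish", 1, 1, ("Animal babies",))
        assert np.array_equal(back.encode(lab), csva_space.encode(lab))


class TestFIR:
    def test_single_onset(self):
        ind = np.zeros(20)
        ind[10] = 1
        X = fir_expand(ind)
        for b in range(4):
            assert X[10 + b + 1, b] == 1
        assert X.sum() == 4

    def test_truncation_at_run_end(self):
        ind = np.zeros(5)
        ind[4] = 1
        assert fir_expand(ind).sum() == 0

    def test_overlap_matches_convolution(self, rng):
        ind = np.zeros(30)
        ind[[5, 7]] = 1
        X = fir_expand(ind)
        for b in range(1, 5):
            kernel = np.zeros(b + 1)
            kernel[b] = 1
            expected = np.convolve(ind, kernel)[:30]
            assert np.array_equal(X[:, b - 1], expected)

    def test_linearity(self, rng):
        a = (rng.random(40) < 0.3).astype(float)
        b = (rng.random(40) < 0.3).astype(float)
        assert np.allclose(fir_expand(a + b), fir_expand(a) + fir_expand(b))


class TestBuildDesign:
    def _events(self, rows):
        return pd.DataFrame(rows,
                            columns=["run", "onset_volume", "image_id",
                                     "is_null"])

    def test_empty_events_all_zero(self, csva_space):
        ev = self._events([])
        d = build_design(ev, {}, csva_space, {"r0": 10})
        assert d.values.shape == (10, 144 * 4)
        assert not d.values.any()

    def test_single_image_four_nonzero_columns(self, csva_space):
        ev = self._events([("r0", 2, "a", False)])
        labs = {"a": ImageLabel("a", "Insect", 0, 1)}
        d = build_design(ev, labs, csva_space, {"r0": 12})
        assert (d.values.any(axis=0)).sum() == 4

    def test_column_count_with_motion(self, csva_space):
        ev = self._events([("r0", 0, "a", False)])
        labs = {"a": ImageLabel("a", "Bird", 0, 0)}
        motion = np.zeros((8, 6))
        d = build_design(ev, labs, csva_space, {"r0": 8}, motion=motion)
        assert d.values.shape[1] == 144 * 4 + 6
        assert d.nuisance_names == [f"motion_{i}" for i in range(1, 7)]

    def test_excluded_image_contributes_nothing(self, csva_space):
        ev = self._events([("r0", 1, "a", False)])
        labs = {"a": ImageLabel("a", "Bird", EXCLUDED, 0)}
        d = build_design(ev, labs, csva_space, {"r0": 10})
        assert not d.values.any()

    def test_unlabeled_image_rejected(self, csva_space):
        ev = self._events([("r0", 1, "mystery", False)])
        with pytest.raises(KeyError):
            build_design(ev, {}, csva_space, {"r0": 10})

    def test_no_cross_run_bleed(self, csva_space):
        # onset at the end of run r0 must not reach into run r1
        ev = self._events([("r0", 9, "a", False)])
        labs = {"a": ImageLabel("a", "Bird", 0, 0)}
        d = build_design(ev, labs, csva_space, {"r0": 10, "r1": 10})
        assert not d.values[d.run_index == "r1"].any()


class TestGabor:
    bank = GaborBank(image_size=64)

    def test_constant_image_zero_energy(self):
        e = gabor_features(np.full((64, 64), 3.7), self.bank)
        assert np.allclose(e, 0.0, atol=1e-8)

    def test_grating_peaks_at_matching_filter(self):
        # vertical grating: intensity varies along x at 6 cycles/image
        x = np.arange(64)
        img = np.cos(2 * np.pi * 6 * x / 64)[None, :].repeat(64, axis=0)
        e = gabor_features(img, self.bank)
        best = list(self.bank.filters())[int(np.argmax(e))]
        freq, theta = best[0], best[1]
        assert freq == 6.0
        assert theta in (0.0, 90.0)

    def test_zscore_across_images(self, rng):
        imgs = [rng.random((64, 64)) for _ in range(8)]
        M = gabor_feature_matrix(imgs, self.bank)
        assert np.allclose(M.mean(axis=0), 0, atol=1e-10)
        sd = M.std(axis=0)
        assert np.allclose(sd[sd > 0], 1, atol=1e-10)

    def test_wrong_size_rejected_without_resample(self):
        with pytest.raises(ValueError):
            gabor_features(np.zeros((32, 32)), self.bank, resample=False)

    def test_grid_covers_image(self):
        for f in self.bank.frequencies:
            sd, centers = self.bank.grid(f)
            assert centers.min() >= 0 and centers.max() <= self.bank.image_size
            # spacing is 3 envelope SDs
            if len(centers) > 1:
                assert np.allclose(np.diff(centers), 3 * sd)


class TestType1Index1:
    @pytest.mark.parametrize("m", range(2, 10))
    def test_every_ordered_pair_once(self, m):
        seq = type1_index1_sequence(m, seed=3)
        assert len(seq) == m * m + 1
        pairs = collections.Counter(zip(seq[:-1], seq[1:]))
        assert len(pairs) == m * m
        assert all(c == 1 for c in pairs.values())

    def test_each_condition_appears_m_times_as_source(self):
        seq = type1_index1_sequence(9, seed=0)
        src = collections.Counter(seq[:-1])
        assert all(src[c] == 9 for c in range(9))

    def test_seed_reproducibility(self):
        a = type1_index1_sequence(5, seed=11)
        b = type1_index1_sequence(5, seed=11)
        c = type1_index1_sequence(5, seed=12)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            type1_index1_sequence(1, seed=0)
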