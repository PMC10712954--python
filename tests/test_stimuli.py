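"""Stimulus family, renderer, enumeration and protocol design."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vistrat import stimuli as st
from vistrat.stimuli import (
    DEFAULT_SUBGRID,
    ShapeParams,
    StimulusSpec,
    Transform,
    ValidationError,
)

BASE_T = DEFAULT_SUBGRID.base_target
BASE_D = DEFAULT_SUBGRID.base_distractor


class TestSpecs:
    @pytest.mark.parametrize("kwargs", [
        dict(concavity_level=11, alignment_level=0),
        dict(concavity_level=-1, alignment_level=0),
        dict(concavity_level=0, alignment_level=4),
    ])
    def test_shape_level_ranges(self, kwargs):
        with pytest.raises(ValidationError):
            ShapeParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        dict(rot_x=45), dict(light_location="behind"),
        dict(size_scale=0.5), dict(position="middle"),
    ])
    def test_transform_domains(self, kwargs):
        with pytest.raises(ValidationError):
            Transform(**kwargs)

    def test_concavity_mapping_strictly_monotone(self):
        cfg = st.RenderConfig()
        bulges = [cfg.bulge(c) for c in range(11)]
        assert all(a < b for a, b in zip(bulges, bulges[1:]))
        assert bulges[5] == 0.0

    def test_size_and_position_change_neither_role_nor_shape(self):
        s = BASE_T.with_transform(size_scale=0.6, position="upper_left")
        assert s.role == BASE_T.role
        assert s.shape == BASE_T.shape


class TestRenderer:
    def test_same_spec_renders_bit_identical(self):
        spec = BASE_T.with_transform(rot_y=60, light_location="up")
        a = st.render(spec).pixels
        st._render_cached.cache_clear()
        b = st.render(spec).pixels
        assert np.array_equal(a, b)

    def test_zero_rotation_via_general_path_is_identity(self):
        # rot_x=0 takes the same code path as any other angle
        a = st.render(StimulusSpec(ShapeParams(0, 0)))
        b = st.render(StimulusSpec(ShapeParams(0, 0), Transform(rot_x=0)))
        assert np.array_equal(a.pixels, b.pixels)

    def test_left_right_lights_mirror_a_symmetric_shape(self):
        # alignment 0 is left-right symmetric, so swapping the lateral light
        # must mirror the image
        s = StimulusSpec(ShapeParams(5, 0))
        left = st.render(s.with_transform(light_location="left")).pixels
        right = st.render(s.with_transform(light_location="right")).pixels
        assert np.allclose(left, right[:, ::-1], atol=1e-9)

    def test_image_contract(self):
        img = st.render(BASE_D.with_transform(rot_x=120, rot_z=60))
        assert img.pixels.shape == (100, 100)
        assert np.all(np.isfinite(img.pixels))
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_object_pushed_out_of_frame_raises(self):
        cfg = st.RenderConfig(position_offset=5.0)
        with pytest.raises(ValidationError):
            st.render(BASE_T.with_transform(position="lower_left",
                                            size_scale=0.6), cfg)

    def test_mean_silhouette_width_monotone_in_concavity(self):
        widths = []
        for c in range(11):
            px = st.render(StimulusSpec(ShapeParams(c, 0))).pixels
            rows = (px > 0).sum(axis=1)
            widths.append(rows[rows > 0].mean())
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_distractor_brighter_than_target(self):
        # the convex base catches more light: the known brightness confound
        assert st.brightness(st.render(BASE_D)) > st.brightness(st.render(BASE_T))


class TestImageMetrics:
    def test_brightness_flat_images(self):
        assert st.brightness(np.zeros((100, 100))) == 0.0
        assert st.brightness(np.ones((100, 100))) == 1.0
        checker = np.indices((100, 100)).sum(axis=0) % 2
        assert st.brightness(checker.astype(float)) == 0.5

    def test_dissimilarity_values(self):
        z = np.zeros((100, 100))
        assert st.pixel_dissimilarity(z, z) == 0.0
        assert st.pixel_dissimilarity(z, np.ones((100, 100))) == pytest.approx(100.0)

    def test_dissimilarity_matches_brute_force(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((100, 100)), rng.random((100, 100))
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())))
        assert st.pixel_dissimilarity(a, b) == pytest.approx(brute)

    def test_dissimilarity_shape_mismatch(self):
        with pytest.raises(ValidationError):
            st.pixel_dissimilarity(np.zeros((100, 100)), np.zeros((50, 50)))

    @settings(max_examples=20, derandomize=True)
    @given(hst.integers(0, 2 ** 32 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.random((3, 20, 20))
        dab = st.pixel_dissimilarity(a, b)
        dba = st.pixel_dissimilarity(b, a)
        assert dab >= 0.0
        assert dab == dba
        assert st.pixel_dissimilarity(a, a) == 0.0
        assert dab <= st.pixel_dissimilarity(a, c) + st.pixel_dissimilarity(c, b)


class TestEnumeration:
    def test_full_published_space(self):
        assert st.space_size() == 75_460
        n, it = st.enumerate_space()
        first = next(it)
        assert isinstance(first, StimulusSpec)
        assert n == 75_460

    def test_single_shape_no_axes(self):
        n, it = st.enumerate_space(axes=())
        assert n == 1
        assert len(list(it)) == 1

    def test_subgrid_by_rotation_x(self):
        n, it = st.enumerate_space(axes=("alignment", "concavity", "rot_x"),
                                   values={"concavity": DEFAULT_SUBGRID.concavity_columns})
        specs = list(it)
        assert n == 112
        assert len(specs) == len(set(specs)) == 112

    @settings(max_examples=25, derandomize=True)
    @given(hst.sets(hst.sampled_from(
        ["alignment", "concavity", "rot_x", "rot_y", "rot_z",
         "light_location", "size_scale", "position"]), max_size=4))
    def test_count_is_product_of_cardinalities(self, axes):
        axes = tuple(sorted(axes))
        n, it = st.enumerate_space(axes=axes)
        brute = list(it)
        assert len(brute) == n
        assert len(set(brute)) == n

    def test_unknown_axis(self):
        with pytest.raises(ValidationError):
            st.space_size(axes=("colour",))


class TestSubgrid:
    def test_linear_dissimilarity_gives_even_symmetric_spacing(self):
        # brute-force oracle: when dissimilarity is linear in the concavity
        # index the gaps must be as equal as possible, tie-broken symmetric
        lin = {(i, j): float(j - i) for i in range(11) for j in range(11) if i < j}
        sg = st.select_subgrid(column_dissimilarity=lin)
        assert sg.concavity_columns == (0, 3, 7, 10)

    def test_k_equal_to_grid_width_returns_grid_unchanged(self):
        sg = st.select_subgrid(k=11, column_dissimilarity={})
        assert sg.concavity_columns == tuple(range(11))

    def test_k_too_large_raises(self):
        with pytest.raises(ValidationError):
            st.select_subgrid(k=12)

    def test_role_partition(self):
        from collections import Counter
        roles = Counter(s.role for _, _, s in DEFAULT_SUBGRID.cells())
        assert roles == {"target": 6, "distractor": 6, "ambiguous": 4}

    def test_base_pair_sits_at_extreme_corners(self):
        assert BASE_T.shape == ShapeParams(0, 0)
        assert BASE_D.shape == ShapeParams(10, 3)
        assert BASE_T.role == "target" and BASE_D.role == "distractor"

    def test_default_subgrid_is_the_renderer_selection(self):
        assert st.select_subgrid().concavity_columns == DEFAULT_SUBGRID.concavity_columns


class TestProtocols:
    @pytest.mark.parametrize("name,n", [
        ("training", 1), ("dimension_learning", 2), ("transformations", 25),
        ("rotation_x", 36), ("rotation_y", 36), ("rotation_z", 36),
        ("combination_rotation", 36), ("light_location", 16),
        ("size", 4), ("position", 25),
    ])
    def test_pair_counts(self, name, n):
        proto = st.protocol_pairs(name)
        assert proto.n_pairs == n

    def test_pair_roles(self):
        for name in ("rotation_x", "size", "position", "transformations"):
            for t, d in st.protocol_pairs(name).pairs:
                assert t.role == "target" and d.role == "distractor"

    def test_nine_test_protocols_sum_to_287_pairs(self, informed_protocols):
        total = 0
        for name in st.TEST_PROTOCOLS:
            proto = informed_protocols.get(name) or st.protocol_pairs(name)
            total += proto.n_pairs
        assert total == 287

    def test_informed_protocols_require_selected_pairs(self):
        with pytest.raises(ValidationError):
            st.protocol_pairs("zero_vs_high")

    def test_unknown_protocol(self):
        with pytest.raises(ValidationError):
            st.protocol_pairs("rotation_w")

    def test_dimension_learning_pairs_differ_in_exactly_one_dimension(self):
        (t1, d1), (t2, d2) = st.protocol_pairs("dimension_learning").pairs
        assert t1.shape.alignment_level == d1.shape.alignment_level
        assert t1.shape.concavity_level != d1.shape.concavity_level
        assert t2.shape.concavity_level == d2.shape.concavity_level
        assert t2.shape.alignment_level != d2.shape.alignment_level

    def test_training_stimuli_are_balanced_and_distinct(self):
        specs, labels = st.training_stimuli()
        assert len(specs) == len(set(specs)) == 16
        assert labels.sum() == 0
        assert set(labels) == {-1, 1}
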