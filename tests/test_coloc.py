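import numpy as np
import networkx as nx
import pytest

from synaptopy import match_puncta, pair_overlap, summarize_image
from synaptopy.coloc import ColocPair
from synaptopy.detect import DetectionParams, PunctaSet

from conftest import VOXEL, make_punctum, square_footprint

VOX_VOLUME = VOXEL[0] * VOXEL[1] * VOXEL[2]


def punctaset(channel, puncta, image_id="img"):
    return PunctaSet(
        channel=channel,
        puncta=tuple(puncta),
        image_id=image_id,
        params=DetectionParams(),
        voxel_size=VOXEL,
    )


class TestPairOverlap:
    def test_self_overlap_equals_own_volume(self):
        p = make_punctum(0, {2: square_footprint(4, 4, 3), 3: square_footprint(4, 4, 3)})
        assert pair_overlap(p, p, VOXEL) == pytest.approx(p.volume_um3, rel=1e-15)

    def test_z_disjoint_gives_zero(self):
        a = make_punctum(0, {z: square_footprint(4, 4, 3) for z in (0, 1, 2)})
        b = make_punctum(1, {z: square_footprint(4, 4, 3) for z in (5, 6, 7)})
        assert pair_overlap(a, b, VOXEL) == 0.0

    def test_xy_disjoint_on_shared_z_gives_zero(self):
        a = make_punctum(0, {1: square_footprint(0, 0, 3)})
        b = make_punctum(1, {1: square_footprint(10, 10, 3)})
        assert pair_overlap(a, b, VOXEL) == 0.0

    def test_hand_countable_offset_fixture(self):
        """3x3 footprints offset by 1 px in x on 2 shared slices: the
        intersection is 3x2 = 6 px per slice, 12 voxels total."""
        a = make_punctum(0, {4: square_footprint(10, 10, 3), 5: square_footprint(10, 10, 3)})
        b = make_punctum(1, {4: square_footprint(10, 11, 3), 5: square_footprint(10, 11, 3)})
        assert pair_overlap(a, b, VOXEL) == pytest.approx(12 * VOX_VOLUME, rel=1e-15)

    def test_invalid_voxel_size_rejected(self):
        p = make_punctum(0, {0: square_footprint(0, 0, 2)})
        with pytest.raises(ValueError):
            pair_overlap(p, p, (0.0, 1.0, 1.0))


def random_punctaset(rng, channel, n, image_id="img"):
    puncta = []
    for i in range(n):
        z0 = int(rng.integers(0, 6))
        nz = int(rng.integers(1, 4))
        y0, x0 = int(rng.integers(0, 18)), int(rng.integers(0, 18))
        size = int(rng.integers(2, 5))
        fps = {z: square_footprint(y0, x0, size) for z in range(z0, z0 + nz)}
        puncta.append(make_punctum(i, fps))
    return punctaset(channel, puncta, image_id)


def max_cardinality_pairs(pre_set, post_set):
    """Independent oracle: maximum-cardinality matching on the positive-
    overlap graph."""
    g = nx.Graph()
    for p in pre_set:
        for q in post_set:
            if pair_overlap(p, q, VOXEL) > 0:
                g.add_edge(("pre", p.id), ("post", q.id))
    return len(nx.max_weight_matching(g, maxcardinality=True))


class TestMatchPuncta:
    def test_empty_sets_give_no_pairs(self):
        empty = punctaset("pre", [])
        post = random_punctaset(np.random.default_rng(0), "post", 3)
        assert match_puncta(empty, post) == []
        assert match_puncta(punctaset("pre", [make_punctum(0, {0: square_footprint(0, 0, 2)})]),
                            punctaset("post", [])) == []

    def test_greedy_prefers_larger_overlap(self):
        pre = punctaset("pre", [make_punctum(0, {0: square_footprint(0, 0, 5)})])
        post = punctaset(
            "post",
            [
                make_punctum(0, {0: square_footprint(0, 3, 2)}),  # 2x2 overlap = 4
                make_punctum(1, {0: square_footprint(0, 0, 4)}),  # overlap 4x4 > 4... use sizes
            ],
        )
        # overlaps: post0 = 2 cols x 2 rows = 4 px; post1 = 4x4 = 16 px
        pairs = match_puncta(pre, post)
        assert len(pairs) == 1
        assert pairs[0].post_id == 1

    def test_different_images_rejected(self):
        a = punctaset("pre", [], image_id="img1")
        b = punctaset("post", [], image_id="img2")
        with pytest.raises(ValueError, match="different images"):
            match_puncta(a, b)

    @pytest.mark.parametrize("seed", range(200))
    def test_never_exceeds_maximum_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pre = random_punctaset(rng, "pre", int(rng.integers(0, 7)))
        post = random_punctaset(rng, "post", int(rng.integers(0, 7)))
        pairs = match_puncta(pre, post)
        assert len(pairs) <= max_cardinality_pairs(pre, post)
        assert len(pairs) <= min(len(pre), len(post))
        # one-to-one
        assert len({p.pre_id for p in pairs}) == len(pairs)
        assert len({p.post_id for p in pairs}) == len(pairs)

    @pytest.mark.parametrize("seed", range(50))
    def test_symmetry_of_count_and_total_volume(self, seed):
        rng = np.random.default_rng(1000 + seed)
        pre = random_punctaset(rng, "pre", 5)
        post = random_punctaset(rng, "post", 5)
        fwd = match_puncta(pre, post)
        # swap channel roles
        pre_sw = punctaset("pre", list(post.puncta))
        post_sw = punctaset("post", list(pre.puncta))
        rev = match_puncta(pre_sw, post_sw)
        assert len(fwd) == len(rev)
        assert sum(p.overlap_volume_um3 for p in fwd) == pytest.approx(
            sum(p.overlap_volume_um3 for p in rev)
        )

    def test_overlap_total_bounded_by_channel_volumes(self):
        rng = np.random.default_rng(5)
        pre = random_punctaset(rng, "pre", 6)
        post = random_punctaset(rng, "post", 6)
        pairs = match_puncta(pre, post)
        total = sum(p.overlap_volume_um3 for p in pairs)
        assert total <= min(
            sum(p.volume_um3 for p in pre), sum(p.volume_um3 for p in post)
        ) + 1e-12

    def test_dilating_post_footprints_never_decreases_overlap(self):
        rng = np.random.default_rng(8)
        pre = random_punctaset(rng, "pre", 5)
        post = random_punctaset(rng, "post", 5)
        before = sum(p.overlap_volume_um3 for p in match_puncta(pre, post))
        dilated = []
        for p in post:
            fps = {}
            for z, coords in p.footprints.items():
                pix = {(int(y), int(x)) for y, x in coords}
                grown = set(pix)
                for y, x in pix:
                    grown.update({(y + 1, x), (y - 1, x), (y, x + 1), (y, x - 1)})
                fps[z] = sorted(grown)
            dilated.append(make_punctum(p.id, fps))
        after = sum(
            p.overlap_volume_um3
            for p in match_puncta(pre, punctaset("post", dilated))
        )
        assert after >= before - 1e-12


class TestSummarizeImage:
    def test_empty_sets_zero_counts(self):
        s = summarize_image(punctaset("pre", []), punctaset("post", []), [])
        assert (s.n_pre, s.n_post, s.n_coloc) == (0, 0, 0)
        assert np.isnan(s.mean_intensity_pre) and np.isnan(s.mean_intensity_post)

    def test_counts_reflect_sets_and_pairs(self):
        pre = punctaset(
            "pre", [make_punctum(i, {0: square_footprint(i * 6, 0, 3)}) for i in range(3)]
        )
        post = punctaset(
            "post", [make_punctum(i, {0: square_footprint(i * 6, 1, 3)}) for i in range(2)]
        )
        pairs = match_puncta(pre, post)
        s = summarize_image(pre, post, pairs)
        assert (s.n_pre, s.n_post, s.n_coloc) == (3, 2, 2)

    def test_unknown_pair_id_rejected(self):
        pre = punctaset("pre", [make_punctum(0, {0: square_footprint(0, 0, 3)})])
        post = punctaset("post", [make_punctum(0, {0: square_footprint(0, 0, 3)})])
        bogus = ColocPair(
            pre_id=99, post_id=0, shared_z=(0,), overlap_area_per_slice=(1,),
            overlap_volume_um3=VOX_VOLUME,
        )
        with pytest.raises(ValueError, match="unknown punctum"):
            summarize_image(pre, post, [bogus])

    def test_n_coloc_cannot_exceed_channel_counts(self):
        from synaptopy.coloc import ImageSummary

        with pytest.raises(ValueError, match="exceeds"):
            ImageSummary(
                image_id="x", n_pre=1, n_post=5, n_coloc=2,
                coloc_volume_total_um3=0.0, coloc_volumes_um3=(),
                mean_intensity_pre=0.5, mean_intensity_post=0.5,
            )
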