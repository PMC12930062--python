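"""Object-based volumetric colocalization of pre/post puncta.

A pre-synaptic and a post-synaptic punctum colocalize when their z-extents
overlap and their 2D footprints intersect on at least one shared slice; the
overlap volume integrates the per-slice intersection areas over z using the
known voxel dimensions. Matching is one-to-one and greedy by descending
overlap volume, so "number of colocalized puncta" is well defined and
bounded by both channel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import PunctaSet, Punctum

__all__ = ["ColocPair", "ImageSummary", "pair_overlap", "match_puncta", "summarize_image"]


@dataclass(frozen=True)
class ColocPair:
    """A matched pre/post punctum pair with shared z-extent and overlap."""

    pre_id: int
    post_id: int
    shared_z: tuple[int, ...]
    overlap_area_per_slice: tuple[int, ...]  # pixels, aligned with shared_z
    overlap_volume_um3: float

    def __post_init__(self) -> None:
        if not self.shared_z:
            raise ValueError("ColocPair requires a non-empty shared z-extent")
        if len(self.shared_z) != len(self.overlap_area_per_slice):
            raise ValueError("shared_z and overlap_area_per_slice must align")
        if self.overlap_volume_um3 <= 0:
            raise ValueError("overlap volume must be > 0")

    @property
    def n_shared_z(self) -> int:
        return len(self.shared_z)

    @property
    def overlap_voxels(self) -> int:
        return int(sum(self.overlap_area_per_slice))


@dataclass(frozen=True)
class ImageSummary:
    """Per-image readouts: puncta counts, colocalized count, volumes,
    mean punctum intensities (mean over puncta of the punctum means;
    NaN when a channel has no puncta)."""

    image_id: str
    n_pre: int
    n_post: int
    n_coloc: int
    coloc_volume_total_um3: float
    coloc_volumes_um3: tuple[float, ...]
    mean_intensity_pre: float
    mean_intensity_post: float

    def __post_init__(self) -> None:
        if min(self.n_pre, self.n_post, self.n_coloc) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_coloc > min(self.n_pre, self.n_post):
            raise ValueError(
                f"n_coloc={self.n_coloc} exceeds min(n_pre={self.n_pre}, "
                f"n_post={self.n_post})"
            )


def _footprint_sets(p: Punctum, nx: int | None = None) -> dict[int, set[int]]:
    # flat (y * large + x) pixel keys per slice for fast intersection
    out = {}
    for z, coords in p.footprints.items():
        out[z] = set((coords[:, 0].astype(np.int64) << 21) | coords[:, 1].astype(np.int64))
    return out


def _slice_overlaps(a: Punctum, b: Punctum) -> tuple[list[int], list[int]]:
    """Shared z-slices with non-empty footprint intersection and their areas."""
    z_lo = max(a.z_min, b.z_min)
    z_hi = min(a.z_max, b.z_max)
    if z_lo > z_hi:
        return [], []
    fa = _footprint_sets(a)
    fb = _footprint_sets(b)
    shared, areas = [], []
    for z in range(z_lo, z_hi + 1):
        n = len(fa[z] & fb[z])
        if n:
            shared.append(z)
            areas.append(n)
    return shared, areas


def pair_overlap(
    a: Punctum, b: Punctum, voxel_size: tuple[float, float, float]
) -> float:
    """Overlap volume (µm³) of two puncta from the same image geometry.

    Sum over z-slices present in both of the footprint-intersection pixel
    count, times the voxel volume; 0 when z-ranges or footprints are
    disjoint.
    """
    dz, dy, dx = voxel_size
    if min(dz, dy, dx) <= 0:
        raise ValueError(f"invalid voxel size {voxel_size}")
    _, areas = _slice_overlaps(a, b)
    return float(sum(areas)) * (dz * dy * dx)


def match_puncta(
    pre_set: PunctaSet,
    post_set: PunctaSet,
    min_overlap_voxels: int = 1,
) -> list[ColocPair]:
    """Greedy one-to-one matching of pre/post puncta by overlap volume.

    All cross-channel pairs with >= ``min_overlap_voxels`` intersecting
    voxels are candidates; pairs are accepted in descending overlap-volume
    order (ties: ascending pre id, then post id), each punctum used at most
    once. Deterministic.
    """
    if pre_set.image_id != post_set.image_id:
        raise ValueError(
            f"puncta sets from different images: {pre_set.image_id!r} vs "
            f"{post_set.image_id!r}"
        )
    if pre_set.voxel_size != post_set.voxel_size:
        raise ValueError("puncta sets carry different voxel sizes")
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    dz, dy, dx = pre_set.voxel_size
    vox = dz * dy * dx

    # bounding boxes for cheap rejection
    def bbox(p: Punctum):
        ys = [c[:, 0] for c in p.footprints.values()]
        xs = [c[:, 1] for c in p.footprints.values()]
        ymin = min(int(y.min()) for y in ys)
        ymax = max(int(y.max()) for y in ys)
        xmin = min(int(x.min()) for x in xs)
        xmax = max(int(x.max()) for x in xs)
        return p.z_min, p.z_max, ymin, ymax, xmin, xmax

    post_boxes = [(q, bbox(q)) for q in post_set]
    candidates: list[tuple[float, int, int, ColocPair]] = []
    for p in pre_set:
        pb = bbox(p)
        for q, qb in post_boxes:
            if pb[0] > qb[1] or qb[0] > pb[1]:  # z-disjoint
                continue
            if pb[2] > qb[3] or qb[2] > pb[3] or pb[4] > qb[5] or qb[4] > pb[5]:
                continue
            shared, areas = _slice_overlaps(p, q)
            n_vox = sum(areas)
            if n_vox < min_overlap_voxels:
                continue
            pair = ColocPair(
                pre_id=p.id,
                post_id=q.id,
                shared_z=tuple(shared),
                overlap_area_per_slice=tuple(areas),
                overlap_volume_um3=n_vox * vox,
            )
            candidates.append((pair.overlap_volume_um3, p.id, q.id, pair))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    matched: list[ColocPair] = []
    for _vol, pre_id, post_id, pair in candidates:
        if pre_id in used_pre or post_id in used_post:
            continue
        used_pre.add(pre_id)
        used_post.add(post_id)
        matched.append(pair)
    return matched


def summarize_image(
    pre_set: PunctaSet, post_set: PunctaSet, pairs: list[ColocPair]
) -> ImageSummary:
    """Collapse one image into its count/volume/intensity readouts."""
    pre_ids = {p.id for p in pre_set}
    post_ids = {p.id for p in post_set}
    for pair in pairs:
        if pair.pre_id not in pre_ids or pair.post_id not in post_ids:
            raise ValueError(
                f"pair ({pair.pre_id}, {pair.post_id}) references unknown punctum"
            )
    mean_pre = float(np.mean([p.mean_intensity for p in pre_set])) if len(pre_set) else float("nan")
    mean_post = float(np.mean([p.mean_intensity for p in post_set])) if len(post_set) else float("nan")
    volumes = tuple(p.overlap_volume_um3 for p in pairs)
    return ImageSummary(
        image_id=pre_set.image_id,
        n_pre=len(pre_set),
        n_post=len(post_set),
        n_coloc=len(pairs),
        coloc_volume_total_um3=float(sum(volumes)),
        coloc_volumes_um3=volumes,
        mean_intensity_pre=mean_pre,
        mean_intensity_post=mean_post,
    )


def pairs_table(pairs: list[ColocPair]) -> pd.DataFrame:
    """Pairs as the CSV schema: pre_id, post_id, n_shared_z, overlap_voxels,
    overlap_volume_um3."""
    rows = [
        {
            "pre_id": p.pre_id,
            "post_id": p.post_id,
            "n_shared_z": p.n_shared_z,
            "overlap_voxels": p.overlap_voxels,
            "overlap_volume_um3": p.overlap_volume_um3,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows, columns=["pre_id", "post_id", "n_shared_z", "overlap_voxels", "overlap_volume_um3"]
    )


def summary_table(summaries: list[ImageSummary]) -> pd.DataFrame:
    """Per-image summaries in the documented column order."""
    rows = [
        {
            "image_id": s.image_id,
            "n_pre": s.n_pre,
            "n_post": s.n_post,
            "n_coloc": s.n_coloc,
            "mean_intensity_pre": s.mean_intensity_pre,
            "mean_intensity_post": s.mean_intensity_post,
            "coloc_volume_total": s.coloc_volume_total_um3,
        }
        for s in summaries
    ]
    from .io import IMAGE_SUMMARY_COLUMNS

    return pd.DataFrame(rows, columns=IMAGE_SUMMARY_COLUMNS)
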