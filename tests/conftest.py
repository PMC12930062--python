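import numpy as np
import pytest

from synaptopy import StackGeometry, VoxelGrid, gen_stack
from synaptopy.detect import Punctum

VOXEL = (0.30, 0.06013, 0.06013)


@pytest.fixture(scope="session")
def small_geometry():
    return StackGeometry(nz=10, ny=160, nx=160)


@pytest.fixture(scope="session")
def small_stack(small_geometry):
    """A quick 40+40-puncta stack with half the post puncta colocalized."""
    return gen_stack(
        n_pre=40, n_post=40, coloc_fraction=0.5, snr=5.0,
        geometry=small_geometry, seed=11,
    )


def grid(values, voxel=VOXEL):
    values = np.asarray(values, dtype=float)
    return VoxelGrid(values, dz=voxel[0], dy=voxel[1], dx=voxel[2])


def make_punctum(pid, footprints, voxel=VOXEL, mean_intensity=0.5, peak=1.0):
    """Build a Punctum from {z: [(y, x), ...]} with consistent measurements."""
    fps = {int(z): np.asarray(px, dtype=int).reshape(-1, 2) for z, px in footprints.items()}
    n = sum(len(v) for v in fps.values())
    zs = np.concatenate([np.full(len(v), z, dtype=float) for z, v in fps.items()])
    ys = np.concatenate([v[:, 0].astype(float) for v in fps.values()])
    xs = np.concatenate([v[:, 1].astype(float) for v in fps.values()])
    dz, dy, dx = voxel
    return Punctum(
        id=pid,
        footprints=fps,
        centroid_um=(zs.mean() * dz, ys.mean() * dy, xs.mean() * dx),
        n_voxels=n,
        volume_um3=n * (dz * dy * dx),
        mean_intensity=mean_intensity,
        peak_response=peak,
    )


def square_footprint(y0, x0, size):
    return [(y, x) for y in range(y0, y0 + size) for x in range(x0, x0 + size)]


def greedy_centroid_match(detected_um, truth_vox, voxel=VOXEL, tol_vox=3.0):
    """One-to-one nearest matching of detected centroids to planted centers,
    in voxel units; returns the match count."""
    det = np.asarray(detected_um, dtype=float).reshape(-1, 3) / np.asarray(voxel)
    tru = np.asarray(truth_vox, dtype=float).reshape(-1, 3)
    if len(det) == 0 or len(tru) == 0:
        return 0
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    matched, used_r, used_c = 0, set(), set()
    for i in np.argsort(d, axis=None):
        r, c = divmod(int(i), d.shape[1])
        if d[r, c] > tol_vox:
            break
        if r in used_r or c in used_c:
            continue
        used_r.add(r)
        used_c.add(c)
        matched += 1
    return matched
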