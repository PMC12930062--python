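"""Ground-truth generators for dual-channel puncta stacks and CSLT logs.

The study's raw data are available only on request, so these generators
provide stand-ins with known ground truth. `gen_stack` renders
Gaussian-profile puncta (separable in-plane Gaussian, triangular z-profile)
on a smooth background with shot + read noise, with a controllable fraction
of post-channel puncta planted directly on top of pre-channel partners.
`gen_behavior` draws trial outcomes from an exponential-saturation learning
curve with independent omissions and log-normal latencies, truncated into
30-closed-trial daily sessions.

Geometry defaults follow the confocal acquisition the pipeline targets
(0.30 µm z-step, 60.13 nm pixels); the default frame is a 256x256x15 crop so
simulations run in seconds, with the full 1024x1024x30 frame available via
``full_frame=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .behavior import (
    CLOSED_PER_SESSION,
    STAGES,
    StageSchedule,
    Trial,
    make_schedule,
)
from .io import StackMeta, TwoChannelStack, VoxelGrid

__all__ = [
    "StackGeometry",
    "NoiseModel",
    "PlantedPunctum",
    "StackTruth",
    "gen_stack",
    "LearningCurve",
    "BehaviorTruth",
    "gen_behavior",
]


# ---------------------------------------------------------------------------
# Image generator


@dataclass(frozen=True)
class StackGeometry:
    """Simulated acquisition frame (defaults: 256x256x15 crop at
    0.30 µm z-step and 60.13 nm pixels)."""

    nz: int = 15
    ny: int = 256
    nx: int = 256
    dz: float = 0.30
    dy: float = 0.06013
    dx: float = 0.06013

    @classmethod
    def full_frame(cls) -> "StackGeometry":
        """The full acquisition frame (1024x1024, 30 z-steps)."""
        return cls(nz=30, ny=1024, nx=1024)


@dataclass(frozen=True)
class NoiseModel:
    """Background and noise in photon-count units.

    Background is ``base + gradient`` (linear ramp along x, 0..gradient).
    Shot noise is Poisson on the expected counts; read noise is additive
    Gaussian with SD ``read_sd``. The background noise SD used in the SNR
    definition (punctum peak amplitude / background noise SD) is
    ``sqrt(base + gradient/2 + read_sd**2)``.
    """

    base: float = 20.0
    gradient: float = 10.0
    read_sd: float = 2.0

    @property
    def background_noise_sd(self) -> float:
        return math.sqrt(self.base + self.gradient / 2.0 + self.read_sd**2)


@dataclass(frozen=True)
class PlantedPunctum:
    """Ground truth for one rendered punctum."""

    channel: str  # "pre" | "post"
    center_zyx_um: tuple[float, float, float]
    center_zyx_vox: tuple[float, float, float]
    sigma_xy_px: float
    z_extent: int  # slices
    amplitude: float  # peak photon counts above background


@dataclass(frozen=True)
class StackTruth:
    """Everything known about a generated stack."""

    puncta: tuple[PlantedPunctum, ...]
    pairs: tuple[tuple[int, int], ...]  # (pre index, post index) into puncta
    n_pre: int
    n_post: int
    coloc_fraction: float
    pair_offset_px: float
    snr: float
    geometry: StackGeometry
    noise: NoiseModel
    seed: int

    def centers(self, channel: str) -> np.ndarray:
        """(N, 3) voxel-unit centers for one channel."""
        return np.array(
            [p.center_zyx_vox for p in self.puncta if p.channel == channel]
        ).reshape(-1, 3)


def _place_centers(
    rng: np.random.Generator,
    geometry: StackGeometry,
    n_pre: int,
    n_post: int,
    n_pairs: int,
    pair_offset_px: float,
    min_separation_px: float,
    margin_px: float,
    z_margin: int,
    max_tries: int = 3_000,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Draw punctum centers (voxel units, float).

    All independent centers (pre puncta plus non-colocalized post puncta)
    keep ``min_separation_px`` in-plane distance from each other, so
    ground-truth colocalization labels are unambiguous: a post punctum
    overlaps a pre punctum iff they are a planted pair. Paired post centers
    sit within ``pair_offset_px`` (in-plane) of their pre partner at the
    same z. A jammed configuration triggers a full restart (the rng stream
    continues, so placement stays deterministic per seed).
    """
    # clamp margins so tiny frames remain feasible
    z_lo = min(float(z_margin), (geometry.nz - 1) / 2.0)
    z_hi = max(geometry.nz - 1 - z_margin, z_lo)
    m_y = min(margin_px, (geometry.ny - 1) / 2.0)
    m_x = min(margin_px, (geometry.nx - 1) / 2.0)

    for _attempt in range(20):
        placed: list[tuple[float, float]] = []

        def draw_independent() -> tuple[float, float, float] | None:
            for _ in range(max_tries):
                z = rng.uniform(z_lo, z_hi) if z_hi > z_lo else z_lo
                y = rng.uniform(m_y, geometry.ny - 1 - m_y)
                x = rng.uniform(m_x, geometry.nx - 1 - m_x)
                if all(
                    (y - py) ** 2 + (x - px) ** 2 >= min_separation_px**2
                    for py, px in placed
                ):
                    placed.append((y, x))
                    return z, y, x
            return None

        independent = [draw_independent() for _ in range(n_pre + n_post - n_pairs)]
        if any(c is None for c in independent):
            continue
        pre = np.array(independent[:n_pre]).reshape(-1, 3)
        pairs: list[tuple[int, int]] = []
        post_list: list[tuple[float, float, float]] = []
        paired_pre = (
            rng.choice(n_pre, size=n_pairs, replace=False) if n_pairs else np.array([], int)
        )
        for j, i_pre in enumerate(paired_pre):
            z, y, x = pre[i_pre]
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0, pair_offset_px)
            post_list.append((z, y + r * np.sin(theta), x + r * np.cos(theta)))
            pairs.append((int(i_pre), j))
        post_list.extend(independent[n_pre:])
        post = np.array(post_list).reshape(-1, 3)
        return pre, post, pairs
    raise ValueError(
        "could not place puncta at the requested density after bounded retries"
    )


def _render_channel(
    geometry: StackGeometry,
    centers: np.ndarray,
    sigmas: np.ndarray,
    z_extents: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Sum of separable punctum profiles: in-plane Gaussian, triangular in z."""
    img = np.zeros((geometry.nz, geometry.ny, geometry.nx), dtype=np.float64)
    for (cz, cy, cx), sig, zext, amp in zip(centers, sigmas, z_extents, amplitudes):
        half = (zext - 1) / 2.0
        z_lo = max(0, int(math.floor(cz - half)))
        z_hi = min(geometry.nz - 1, int(math.ceil(cz + half)))
        rad = int(math.ceil(4 * sig))
        y_lo, y_hi = max(0, int(cy) - rad), min(geometry.ny - 1, int(cy) + rad)
        x_lo, x_hi = max(0, int(cx) - rad), min(geometry.nx - 1, int(cx) + rad)
        yy = np.arange(y_lo, y_hi + 1)[:, None]
        xx = np.arange(x_lo, x_hi + 1)[None, :]
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        for z in range(z_lo, z_hi + 1):
            w = max(0.0, 1.0 - abs(z - cz) / (half + 0.5))  # triangular z-profile
            if w > 0:
                img[z, y_lo : y_hi + 1, x_lo : x_hi + 1] += amp * w * g
    return img


def gen_stack(
    n_pre: int = 150,
    n_post: int = 150,
    coloc_fraction: float = 0.5,
    snr: float = 5.0,
    geometry: StackGeometry | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sigma_xy_px: tuple[float, float] = (1.5, 2.5),
    z_extent: tuple[int, int] = (3, 5),
    pair_offset_px: float = 1.5,
    min_separation_px: float = 12.0,
    meta: StackMeta | None = None,
) -> tuple[TwoChannelStack, StackTruth]:
    """Generate a two-channel stack with known puncta ground truth.

    ``floor(coloc_fraction * min(n_pre, n_post))`` post puncta are planted
    within ``pair_offset_px`` (in-plane) of a pre punctum at the same z; all
    other puncta keep a minimum in-plane separation so unpaired cross-channel
    overlap cannot occur. Per-punctum sigma and z-extent are drawn uniformly
    from the given ranges; the peak amplitude is ``snr`` times the background
    noise SD, jittered ±20%. Deterministic given seed.
    """
    if n_pre < 0 or n_post < 0:
        raise ValueError("counts must be >= 0")
    if not 0 <= coloc_fraction <= 1:
        raise ValueError(f"coloc_fraction must be in [0, 1], got {coloc_fraction}")
    geometry = geometry or StackGeometry()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    n_pairs = int(math.floor(coloc_fraction * min(n_pre, n_post)))

    margin = 4 * sigma_xy_px[1]
    pre_c, post_c, pair_idx = _place_centers(
        rng,
        geometry,
        n_pre,
        n_post,
        n_pairs,
        pair_offset_px,
        min_separation_px,
        margin_px=margin,
        z_margin=z_extent[1] // 2,
    )

    amp0 = snr * noise.background_noise_sd

    def draw_props(n: int):
        sig = rng.uniform(*sigma_xy_px, size=n)
        zext = rng.integers(z_extent[0], z_extent[1] + 1, size=n)
        amp = amp0 * rng.uniform(0.8, 1.2, size=n)
        return sig, zext, amp

    pre_sig, pre_z, pre_amp = draw_props(n_pre)
    post_sig, post_z, post_amp = draw_props(n_post)

    yy = np.linspace(0.0, 1.0, geometry.nx)[None, None, :]
    background = noise.base + noise.gradient * yy  # ramp along x
    clean_pre = _render_channel(geometry, pre_c, pre_sig, pre_z, pre_amp) + background
    clean_post = _render_channel(geometry, post_c, post_sig, post_z, post_amp) + background

    def add_noise(clean: np.ndarray) -> np.ndarray:
        shot = rng.poisson(clean).astype(np.float64)
        read = rng.normal(0.0, noise.read_sd, size=clean.shape)
        return np.maximum(shot + read, 0.0)

    pre_grid = VoxelGrid(add_noise(clean_pre), dz=geometry.dz, dy=geometry.dy, dx=geometry.dx)
    post_grid = VoxelGrid(add_noise(clean_post), dz=geometry.dz, dy=geometry.dy, dx=geometry.dx)
    stack = TwoChannelStack(pre=pre_grid, post=post_grid, meta=meta or StackMeta(image_id=f"sim-{seed}"))

    d = np.array([geometry.dz, geometry.dy, geometry.dx])
    planted = [
        PlantedPunctum(
            channel="pre",
            center_zyx_um=tuple(pre_c[i] * d),
            center_zyx_vox=tuple(pre_c[i]),
            sigma_xy_px=float(pre_sig[i]),
            z_extent=int(pre_z[i]),
            amplitude=float(pre_amp[i]),
        )
        for i in range(n_pre)
    ] + [
        PlantedPunctum(
            channel="post",
            center_zyx_um=tuple(post_c[j] * d),
            center_zyx_vox=tuple(post_c[j]),
            sigma_xy_px=float(post_sig[j]),
            z_extent=int(post_z[j]),
            amplitude=float(post_amp[j]),
        )
        for j in range(n_post)
    ]
    pairs = tuple((i, n_pre + j) for i, j in pair_idx)
    truth = StackTruth(
        puncta=tuple(planted),
        pairs=pairs,
        n_pre=n_pre,
        n_post=n_post,
        coloc_fraction=coloc_fraction,
        pair_offset_px=pair_offset_px,
        snr=snr,
        geometry=geometry,
        noise=noise,
        seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Behavior generator


@dataclass(frozen=True)
class LearningCurve:
    """Exponential-saturation learning curve: the probability of a correct
    choice on closed trial t (1-based, cumulative over sessions) is
    ``p_inf - (p_inf - p0) * exp(-t / tau)``."""

    p0: float = 0.5
    p_inf: float = 0.95
    tau: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p0", "p_inf"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def p_correct(self, t: int) -> float:
        return self.p_inf - (self.p_inf - self.p0) * math.exp(-t / self.tau)


@dataclass(frozen=True)
class BehaviorTruth:
    """Generator parameters for one mouse x stage plus the emitted trials."""

    mouse: str
    stage: str
    curve: LearningCurve
    omission_prob: float
    latency_median_s: float
    latency_sigma: float
    seed: int
    trials: tuple[Trial, ...] = field(default_factory=tuple)


def gen_behavior(
    stage: str = "SD",
    curve: LearningCurve | None = None,
    omission_prob: float = 0.01,
    latency_median_s: float = 12.0,
    latency_sigma: float = 0.5,
    max_sessions: int = 5,
    seed: int = 0,
    mouse: str = "sim-mouse",
    schedule_seed: int | None = None,
) -> tuple[list[Trial], BehaviorTruth]:
    """Simulate one mouse's sessions on one stage until criterion or
    ``max_sessions`` days.

    Per closed trial the outcome is an omission with probability
    ``omission_prob``, else correct with the learning-curve probability
    (t counts closed trials cumulatively across sessions). Latencies are
    log-normal (median ``latency_median_s``, log-SD ``latency_sigma``),
    capped at the 120 s choice limit; omissions carry no latency. Sessions
    hold 4 free + up to 30 closed trials; a stage not passed in a session
    resumes the next day. Deterministic given seed.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    if not 0 <= omission_prob <= 1:
        raise ValueError("omission_prob must be in [0, 1]")
    curve = curve or LearningCurve()
    rng = np.random.default_rng(seed)

    from .behavior import detect_criterion  # session-level stop rule

    trials: list[Trial] = []
    t_global = 0
    done = False
    for session in range(1, max_sessions + 1):
        schedule: StageSchedule = make_schedule(
            stage, seed=(schedule_seed if schedule_seed is not None else seed) + session
        )
        for i, _cfg in enumerate(schedule.free, start=1):
            # free trials: outcome at the initial accuracy; no score impact
            correct = rng.random() < curve.p0
            lat = _latency(rng, latency_median_s, latency_sigma)
            trials.append(
                Trial(stage, "free", session, i, "correct" if correct else "incorrect", lat)
            )
        session_outcomes: list[str] = []
        for i, _cfg in enumerate(schedule.closed, start=1):
            t_global += 1
            if rng.random() < omission_prob:
                outcome, lat = "omission", None
            else:
                correct = rng.random() < curve.p_correct(t_global)
                outcome = "correct" if correct else "incorrect"
                lat = _latency(rng, latency_median_s, latency_sigma)
            trials.append(Trial(stage, "closed", session, i, outcome, lat))
            session_outcomes.append(outcome)
            if detect_criterion([session_outcomes]) is not None:
                done = True
                break
        if done:
            break
    truth = BehaviorTruth(
        mouse=mouse,
        stage=stage,
        curve=curve,
        omission_prob=omission_prob,
        latency_median_s=latency_median_s,
        latency_sigma=latency_sigma,
        seed=seed,
        trials=tuple(trials),
    )
    return trials, truth


def _latency(rng: np.random.Generator, median_s: float, sigma: float) -> float:
    return float(min(rng.lognormal(math.log(median_s), sigma), 120.0))
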