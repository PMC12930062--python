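"""Per-mouse/ROI aggregation and ROUT robust outlier flagging.

Each mouse contributes up to four images per region of interest
(2 hemispheres x 2 sections); the per-mouse value of every metric is the
arithmetic mean over available images. Group value lists are screened with
the ROUT procedure (robust fit + FDR-style thresholds) before group
mean/SEM summaries, mirroring the data reduction that precedes inferential
statistics.

ROUT here is the univariate case: the "robust regression" is the constant
model (the median, K = 1 parameter), the robust residual scale is the RSDR
computed from the 68.27th percentile of absolute residuals with an n/(n-K)
small-sample correction, and candidate outliers are tested largest-first
against t-distribution tails at FDR-controlled thresholds
alpha_i = Q * (n - i + 1) / n. Exact agreement with proprietary
implementations is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ImageSummary
from .io import StackMeta

__all__ = [
    "MouseROIRecord",
    "OutlierReport",
    "aggregate_mouse_roi",
    "rout_outliers",
    "group_summary",
]

#: Metrics carried from image summaries into per-mouse records.
AGGREGATE_METRICS = (
    "n_pre",
    "n_post",
    "n_coloc",
    "mean_intensity_pre",
    "mean_intensity_post",
    "coloc_volume_total_um3",
)


@dataclass(frozen=True)
class MouseROIRecord:
    """Per mouse x ROI aggregate over the available images (<= 4)."""

    mouse: str
    group: str
    roi: str
    image_count: int
    values: dict[str, float]
    image_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.image_count < 1:
            raise ValueError("record requires >= 1 image")


@dataclass(frozen=True)
class OutlierReport:
    """ROUT screening result for one value list."""

    values: tuple[float, ...]
    q_percent: float
    flags: tuple[bool, ...]
    robust_location: float
    rsdr: float

    @property
    def n_flagged(self) -> int:
        return int(sum(self.flags))

    def cleaned(self) -> list[float]:
        return [v for v, f in zip(self.values, self.flags) if not f]


def aggregate_mouse_roi(
    summaries: Sequence[ImageSummary],
    metas: Sequence[StackMeta],
) -> MouseROIRecord:
    """Mean each metric over a mouse's images for one ROI.

    All images must share mouse and ROI; missing hemispheres/sections simply
    reduce the replicate count. NaN metric values (e.g. mean intensity of an
    empty channel) are excluded metric-wise.
    """
    if not summaries:
        raise ValueError("aggregate_mouse_roi requires >= 1 image summary")
    if len(summaries) != len(metas):
        raise ValueError("summaries and metas must align")
    mice = {m.mouse for m in metas}
    rois = {m.roi for m in metas}
    if len(mice) != 1 or len(rois) != 1:
        raise ValueError(f"mixed mouse/ROI input: mice={mice}, rois={rois}")
    groups = {m.group for m in metas}
    if len(groups) != 1:
        raise ValueError(f"mixed group labels: {groups}")

    values: dict[str, float] = {}
    for metric in AGGREGATE_METRICS:
        vals = np.array(
            [getattr(s, metric) for s in summaries], dtype=float
        )
        vals = vals[np.isfinite(vals)]
        values[metric] = float(vals.mean()) if vals.size else float("nan")
    return MouseROIRecord(
        mouse=metas[0].mouse,
        group=metas[0].group,
        roi=metas[0].roi or "",
        image_count=len(summaries),
        values=values,
        image_ids=tuple(s.image_id for s in summaries),
    )


def rout_outliers(values: Iterable[float], q_percent: float = 1.0) -> OutlierReport:
    """Flag outliers in a univariate sample with the ROUT procedure.

    Robust location = median; residuals r_i = v_i - median; scale
    RSDR = P68.27(|r|) * n / (n - 1). Residuals are ranked by decreasing
    |r|; rank-i gets a two-tailed t p-value (|r_i| / RSDR, df = n - 1) and
    the rank-i value together with all larger residuals is flagged when
    p_i < alpha_i = (Q/100) * (n - i + 1) / n. Deterministic; identical
    values are never flagged.
    """
    vals = np.asarray(list(values), dtype=float)
    n = vals.size
    if n < 3:
        raise ValueError(f"rout_outliers requires n >= 3, got n={n}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("rout_outliers requires finite inputs")
    if not 0 < q_percent < 100:
        raise ValueError(f"Q must be in (0, 100) percent, got {q_percent}")

    k = 1  # parameters of the constant (median) model
    location = float(np.median(vals))
    resid = vals - location
    abs_resid = np.abs(resid)
    rsdr = float(np.percentile(abs_resid, 68.27) * n / (n - k))

    flags = np.zeros(n, dtype=bool)
    if rsdr == 0.0:
        # all central residuals are exactly zero: any non-zero residual is
        # infinitely many robust SDs out
        flags = abs_resid > 0
        return OutlierReport(
            values=tuple(vals),
            q_percent=float(q_percent),
            flags=tuple(bool(f) for f in flags),
            robust_location=location,
            rsdr=rsdr,
        )

    order = np.argsort(-abs_resid, kind="stable")  # decreasing |r|
    t_stat = abs_resid[order] / rsdr
    p = 2.0 * stats.t.sf(t_stat, df=n - k)
    ranks = np.arange(1, n + 1)
    alpha = (q_percent / 100.0) * (n - (ranks - 1)) / n
    below = np.nonzero(p < alpha)[0]
    if below.size:
        cut = below.max() + 1  # flag this rank and every larger residual
        flags[order[:cut]] = True
    return OutlierReport(
        values=tuple(vals),
        q_percent=float(q_percent),
        flags=tuple(bool(f) for f in flags),
        robust_location=location,
        rsdr=rsdr,
    )


def group_summary(
    records: Sequence[MouseROIRecord],
    metric: str,
    q_percent: float | None = 1.0,
) -> pd.DataFrame:
    """Per group x ROI mean, SEM and n for one metric, after outlier removal.

    ROUT screening (at ``q_percent``) runs independently within each
    group x ROI cell when the cell holds >= 3 values; ``q_percent=None``
    disables screening. ``n`` reflects removals. SEM is the sample standard
    deviation (ddof=1) over sqrt(n); NaN for n < 2.
    """
    if not records:
        raise ValueError("group_summary requires >= 1 record")
    if metric not in records[0].values:
        raise KeyError(
            f"unknown metric {metric!r}; available: {sorted(records[0].values)}"
        )
    rows = []
    cells: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for r in records:
        cells.setdefault((r.group, r.roi), []).append((r.mouse, r.values[metric]))
    for (group, roi), members in sorted(cells.items()):
        vals = np.array([v for _, v in members], dtype=float)
        keep = np.isfinite(vals)
        vals = vals[keep]
        n_removed = 0
        if q_percent is not None and vals.size >= 3:
            report = rout_outliers(vals, q_percent)
            n_removed = report.n_flagged
            vals = np.array(report.cleaned())
        n = int(vals.size)
        mean = float(vals.mean()) if n else float("nan")
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append(
            {
                "group": group,
                "roi": roi,
                "metric": metric,
                "n": n,
                "n_outliers_removed": n_removed,
                "mean": mean,
                "sem": sem,
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "roi", "metric", "n", "n_outliers_removed", "mean", "sem"]
    )


def records_table(records: Sequence[MouseROIRecord]) -> pd.DataFrame:
    """Per-mouse records as a flat table (one row per mouse x ROI)."""
    rows = []
    for r in records:
        row = {"mouse": r.mouse, "group": r.group, "roi": r.roi, "image_count": r.image_count}
        row.update(r.values)
        rows.append(row)
    cols = ["mouse", "group", "roi", "image_count", *AGGREGATE_METRICS]
    return pd.DataFrame(rows, columns=cols)
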