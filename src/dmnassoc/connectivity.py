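"""Seed-based connectivity phenotype construction.

Desk-scale stand-in for the resting-state pipeline downstream of surface
sampling: motion censoring of frames, Pearson correlation between the
posterior-cingulate seed time series and each ROI time series over
retained frames, Fisher-z transform, and equal-weight averaging across
runs.  Also defines ROIs by thresholded clustering of a group p-map.

The stored phenotype is Fisher z = atanh(r); a perfect |r| = 1 signals a
degenerate fixture and raises by default (``cap`` clips instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import SurfaceMesh, components_of
from .containers import COMPONENTS

SEED_ROI = "PCC"


class InsufficientDataError(ValueError):
    """Too few retained frames for a correlation."""


class DegenerateCorrelationError(ValueError):
    """Zero variance or |r| = 1 over retained frames."""


@dataclass
class RoiTimeSeries:
    """One ROI's signal for one subject and run, with censoring flags."""

    subject_id: str
    run_id: str
    roi_id: str
    values: np.ndarray
    frame_flags: np.ndarray | None = None  # True = keep

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_flags is None:
            self.frame_flags = np.ones(len(self.values), dtype=bool)
        else:
            self.frame_flags = np.asarray(self.frame_flags, dtype=bool)
        if len(self.frame_flags) != len(self.values):
            raise ValueError("frame_flags length differs from sample count")

    @property
    def n_retained(self) -> int:
        return int(self.frame_flags.sum())


def censor_frames(
    ts: RoiTimeSeries, motion: np.ndarray, threshold: float
) -> RoiTimeSeries:
    """Flag frames whose displacement exceeds ``threshold`` as censored.

    Values are untouched; existing censoring is preserved (conjunction).
    """
    motion = np.asarray(motion, dtype=float)
    if len(motion) != len(ts.values):
        raise ValueError(
            f"motion length {len(motion)} != sample count {len(ts.values)}"
        )
    flags = ts.frame_flags & (motion <= threshold)
    return RoiTimeSeries(ts.subject_id, ts.run_id, ts.roi_id, ts.values, flags)


def seed_connectivity(
    seed_ts: RoiTimeSeries, roi_ts: RoiTimeSeries, cap: float | None = None
) -> float:
    """Fisher-z correlation between seed and ROI over retained frames.

    Requires shared censoring flags and at least 3 retained frames.  A
    perfect correlation raises :class:`DegenerateCorrelationError` unless
    ``cap`` is given, in which case |r| is clipped to ``1 - cap``.
    """
    if not np.array_equal(seed_ts.frame_flags, roi_ts.frame_flags):
        raise ValueError("seed and ROI time series have different frame flags")
    keep = seed_ts.frame_flags
    x = seed_ts.values[keep]
    y = roi_ts.values[keep]
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} retained frames; need >= 3 for a correlation"
        )
    if x.std() == 0 or y.std() == 0:
        raise DegenerateCorrelationError("zero variance over retained frames")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        if cap is None:
            raise DegenerateCorrelationError(
                f"perfect correlation (r = {r:+.0f}) between seed and ROI"
            )
        r = np.sign(r) * (1.0 - cap)
    return float(np.arctanh(r))


def average_runs(z_values: list[float], weights: list[float] | None = None) -> float:
    """Average per-run Fisher-z values (equal weights by default)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise InsufficientDataError("no runs to average")
    if weights is None:
        return float(z.mean())
    w = np.asarray(weights, dtype=float)
    return float(np.average(z, weights=w))


# ----------------------------------------------------------------------
# Long-format table -> ConnectivityTable


def connectivity_table_from_long(
    long_df: pd.DataFrame,
    motion_threshold: float = 0.5,
    seed_roi: str = SEED_ROI,
    components=COMPONENTS,
    cap: float | None = None,
    frame_weighted: bool = False,
) -> pd.DataFrame:
    """Build the subjects x components connectivity table.

    ``long_df`` has columns (subject, run, roi, frame, value, motion); per
    subject and run, frames over the motion threshold are censored, the
    seed ROI is correlated with each component ROI, and runs are averaged
    in z-space (equal weights, or retained-frame weights when
    ``frame_weighted``).
    """
    required = {"subject", "run", "roi", "frame", "value", "motion"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    rows = []
    for subject, sub_df in long_df.groupby("subject", sort=True):
        per_comp: dict[str, list[float]] = {c: [] for c in components}
        weights: dict[str, list[float]] = {c: [] for c in components}
        for run, run_df in sub_df.groupby("run", sort=True):
            piv = run_df.pivot(index="frame", columns="roi", values="value").sort_index()
            motion = (
                run_df[run_df["roi"] == seed_roi]
                .sort_values("frame")["motion"]
                .to_numpy(dtype=float)
            )
            if seed_roi not in piv.columns:
                raise ValueError(f"seed ROI {seed_roi!r} absent for {subject}/{run}")
            seed = RoiTimeSeries(
                str(subject), str(run), seed_roi, piv[seed_roi].to_numpy()
            )
            seed = censor_frames(seed, motion, motion_threshold)
            for comp in components:
                if comp not in piv.columns:
                    raise ValueError(f"ROI {comp!r} absent for {subject}/{run}")
                roi = RoiTimeSeries(
                    str(subject), str(run), comp, piv[comp].to_numpy(), seed.frame_flags
                )
                z = seed_connectivity(seed, roi, cap=cap)
                per_comp[comp].append(z)
                weights[comp].append(seed.n_retained)
        row = {"subject_id": str(subject)}
        for comp in components:
            row[comp] = average_runs(
                per_comp[comp], weights[comp] if frame_weighted else None
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *components])


# ----------------------------------------------------------------------
# ROI definition from a group map


def define_rois_from_group_map(
    group_p_map: np.ndarray, mesh: SurfaceMesh, threshold_p: float = 1e-20
) -> list[np.ndarray]:
    """Connected suprathreshold clusters of a group p-map, size-descending.

    The ROI-definition analogue: vertices with ``p < threshold_p`` are
    clustered under mesh adjacency.  An empty suprathreshold set yields an
    empty list.
    """
    p = np.asarray(group_p_map, dtype=float)
    if p.shape != (mesh.n_vertices,):
        raise ValueError("p-map length differs from mesh vertex count")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-map values must lie in (0, 1]")
    comps = components_of(mesh, p < threshold_p)
    return sorted(comps, key=len, reverse=True)
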