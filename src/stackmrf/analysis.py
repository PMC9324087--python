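"""Agreement statistics between reconstructions.

Per-ROI means/SDs of the fitted relaxation times, mean absolute percent
error, Pearson correlation of per-ROI means, and the noise (SD) reduction
ratio — the quantities used to compare an accelerated reconstruction
against the unaccelerated reference.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .postprocess import ParameterMaps

__all__ = ["RoiStats", "roi_stats", "agreement_metrics", "pooled_correlation"]


@dataclass
class RoiStats:
    """Per-ROI sample statistics of the T1/T2 maps (sample SD, ddof=1)."""

    labels: list[int]
    n_voxels: dict[int, int]
    t1_mean: dict[int, float]
    t1_sd: dict[int, float]
    t2_mean: dict[int, float]
    t2_sd: dict[int, float]

    def rows(self) -> list[dict]:
        return [
            {
                "label": lab,
                "n_voxels": self.n_voxels[lab],
                "t1_mean": self.t1_mean[lab],
                "t1_sd": self.t1_sd[lab],
                "t2_mean": self.t2_mean[lab],
                "t2_sd": self.t2_sd[lab],
            }
            for lab in self.labels
        ]

    def to_csv(self, path: str | Path, extra: dict | None = None) -> None:
        rows = self.rows()
        fields = list(rows[0].keys()) + list((extra or {}).keys())
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=fields)
            w.writeheader()
            for r in rows:
                w.writerow({**r, **(extra or {})})


def roi_stats(maps: ParameterMaps, label_volume: np.ndarray) -> RoiStats:
    """Mean and sample SD of T1/T2 per ROI label, invalid voxels excluded.

    Empty ROIs (no valid voxels) are reported with n_voxels=0 and NaN
    statistics rather than silently dropped.
    """
    labels_vol = np.asarray(label_volume)
    if labels_vol.shape != maps.t1_ms.shape:
        raise ValueError("label volume does not align with the maps")
    out = RoiStats([], {}, {}, {}, {}, {})
    for lab in np.unique(labels_vol):
        if lab == 0:
            continue
        lab = int(lab)
        mask = (labels_vol == lab) & maps.valid
        out.labels.append(lab)
        n = int(mask.sum())
        out.n_voxels[lab] = n
        if n == 0:
            for d in (out.t1_mean, out.t1_sd, out.t2_mean, out.t2_sd):
                d[lab] = float("nan")
            continue
        t1 = maps.t1_ms[mask]
        t2 = maps.t2_ms[mask]
        out.t1_mean[lab] = float(np.mean(t1))
        out.t2_mean[lab] = float(np.mean(t2))
        out.t1_sd[lab] = float(np.std(t1, ddof=1)) if n > 1 else 0.0
        out.t2_sd[lab] = float(np.std(t2, ddof=1)) if n > 1 else 0.0
    return out


def _mae_percent(ref: np.ndarray, test: np.ndarray) -> float:
    return float(np.mean(100.0 * np.abs(test - ref) / ref))


def agreement_metrics(stats_ref: RoiStats, stats_test: RoiStats) -> dict:
    """Agreement summary between a reference and a test reconstruction.

    Returns mean absolute percent error of the per-ROI means, Pearson
    correlation of the per-ROI means (NaN if fewer than two distinct
    values), and the mean SD ratio reference/test (noise-reduction factor)
    for T1 and T2.  ROI label sets must match.
    """
    if stats_ref.labels != stats_test.labels:
        raise ValueError("ROI label sets differ between the two inputs")
    labs = stats_ref.labels
    if not labs:
        raise ValueError("no ROIs to compare")
    summary: dict[str, float] = {"n_rois": len(labs)}
    for par, mean_ref, mean_test, sd_ref, sd_test in (
        ("t1", stats_ref.t1_mean, stats_test.t1_mean,
         stats_ref.t1_sd, stats_test.t1_sd),
        ("t2", stats_ref.t2_mean, stats_test.t2_mean,
         stats_ref.t2_sd, stats_test.t2_sd),
    ):
        a = np.array([mean_ref[l] for l in labs])
        b = np.array([mean_test[l] for l in labs])
        summary[f"{par}_mae_percent"] = _mae_percent(a, b)
        if len(labs) >= 2 and np.ptp(a) > 0 and np.ptp(b) > 0:
            summary[f"{par}_pearson_r"] = float(scipy.stats.pearsonr(a, b)[0])
        else:
            summary[f"{par}_pearson_r"] = float("nan")
        sr = np.array([sd_ref[l] for l in labs])
        st = np.array([sd_test[l] for l in labs])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(st > 0, sr / st, np.nan)
        summary[f"{par}_sd_ratio"] = float(np.nanmean(ratios))
    return summary


def pooled_correlation(
    maps_ref: ParameterMaps, maps_test: ParameterMaps, label_volume: np.ndarray
) -> dict:
    """Pearson correlation over all valid voxels pooled across ROIs.

    The in-vivo-style analysis: every voxel inside any ROI contributes a
    paired sample.  Also returns the raw paired samples so any statistics
    package can run hypothesis tests on them.
    """
    mask = (np.asarray(label_volume) > 0) & maps_ref.valid & maps_test.valid
    out: dict = {}
    for par, a, b in (
        ("t1", maps_ref.t1_ms, maps_test.t1_ms),
        ("t2", maps_ref.t2_ms, maps_test.t2_ms),
    ):
        x, y = a[mask], b[mask]
        out[f"{par}_pearson_r"] = (
            float(scipy.stats.pearsonr(x, y)[0]) if x.size >= 2 else float("nan")
        )
        out[f"{par}_pairs"] = np.stack([x, y], axis=1)
    return out
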