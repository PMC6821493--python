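"""End-to-end helpers chaining segmentation, classification and standardization.

These functions wire the per-frame operations into the per-movie and
per-cohort analyses: locate the T cell, estimate the interface disc from the
segmented mask, classify every frame relative to tight coupling, and map
cells onto the half-spheroid template for enrichment analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .patterns import PatternThresholds, classify_volume
from .standardize import (HalfSpheroidTemplate, StandardizedCell, _infer_interface_center,
                          segment_t_cell, standardize_shape)
from .synthgen import VolumeSeries

__all__ = [
    "find_cell_seed",
    "estimate_interface",
    "classify_series",
    "standardize_series",
    "classify_cohort",
]


def find_cell_seed(volume: np.ndarray, spacing) -> tuple[int, ...]:
    """Seed voxel inside the brightest cell: global max after light smoothing."""
    sigma = 0.5 / np.asarray(spacing, dtype=float)
    smoothed = ndimage.gaussian_filter(volume.astype(float), sigma=sigma)
    return tuple(int(i) for i in np.unravel_index(np.argmax(smoothed), volume.shape))


def estimate_interface(mask: np.ndarray, spacing) -> tuple[np.ndarray, float]:
    """Interface center (µm) and disc radius from a reoriented cell mask.

    The interface is the top of the mask; its center is the centroid of the
    top masked layer placed on the face above it, and the disc radius is the
    equivalent-circle radius of that layer's area.
    """
    spacing = np.asarray(spacing, dtype=float)
    center = _infer_interface_center(mask, spacing)
    z0 = int(np.flatnonzero(mask.any(axis=(1, 2)))[0])
    area = mask[z0].sum() * spacing[1] * spacing[2]
    return center, float(np.sqrt(area / np.pi))


def classify_series(series: VolumeSeries, coupling_frame: int, cell_id: str = "",
                    condition: str = "", thresholds: PatternThresholds = PatternThresholds(),
                    presmooth_sigma_um: float = 0.3,
                    cell_radius_um: float = 5.0) -> pd.DataFrame:
    """Classify every frame of one cell couple into an interface pattern.

    Returns one row per frame with the time relative to tight coupling
    (``coupling_frame`` is time zero), the assigned label and the geometric
    features of the detected region.
    """
    rows = []
    for t in range(series.n_frames):
        vol = series.data[t]
        seed = find_cell_seed(vol, series.spacing)
        mask = segment_t_cell(vol, seed, spacing=series.spacing,
                              cell_radius_um=cell_radius_um)
        center, radius = estimate_interface(mask, series.spacing)
        label, feats = classify_volume(vol, mask, center, radius,
                                       spacing=series.spacing, thresholds=thresholds,
                                       presmooth_sigma_um=presmooth_sigma_um)
        row = {"cell_id": cell_id, "condition": condition,
               "time_s": (t - coupling_frame) * series.frame_interval_s,
               "label": label}
        if feats is not None:
            row.update({"coverage": feats.coverage, "radial_fraction": feats.radial_fraction,
                        "depth_um": feats.depth_um})
        rows.append(row)
    return pd.DataFrame(rows)


def classify_cohort(dataset, condition: str = "",
                    thresholds: PatternThresholds = PatternThresholds()) -> pd.DataFrame:
    """Classify a cohort of (VolumeSeries, GroundTruth) couples.

    Only the coupling frame is taken from the ground truth (it stands in for
    the manual couple annotation); labels are recomputed from the images.
    """
    calls = []
    for i, (series, truth) in enumerate(dataset):
        coupling = truth.coupling_frame if truth.coupling_frame is not None else 0
        calls.append(classify_series(series, coupling, cell_id=f"cell{i:03d}",
                                     condition=condition, thresholds=thresholds))
    return pd.concat(calls, ignore_index=True) if calls else pd.DataFrame(
        columns=["cell_id", "condition", "time_s", "label"])


def standardize_series(series: VolumeSeries, template: HalfSpheroidTemplate,
                       frames=None, cell_id: str = "",
                       cell_radius_um: float = 5.0) -> list[StandardizedCell]:
    """Map the cell in each (already reoriented) frame onto the template."""
    out = []
    frames = range(series.n_frames) if frames is None else frames
    for t in frames:
        vol = series.data[t]
        seed = find_cell_seed(vol, series.spacing)
        mask = segment_t_cell(vol, seed, spacing=series.spacing,
                              cell_radius_um=cell_radius_um)
        out.append(standardize_shape(vol, mask, template, spacing=series.spacing,
                                     cell_id=cell_id, frame=t))
    return out
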