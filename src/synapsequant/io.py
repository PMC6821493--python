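"""Reading and writing the pipeline's file formats.

Volumes travel as OME-TIFF with physical-spacing metadata; ground truth as a
sidecar JSON of scalar fields; membrane traces and annotations as CSV in µm;
standardized probability vectors as TSV; enrichment regions as JSON index
lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .membrane import MembraneTrace
from .standardize import EnrichmentRegion, StandardizedCell, SynapseAnnotation
from .synthgen import GroundTruth, VolumeSeries

__all__ = [
    "write_volume_series", "read_volume_series",
    "write_ground_truth", "read_ground_truth",
    "write_trace", "read_trace",
    "write_annotations", "read_annotations",
    "write_vectors", "read_vectors",
    "write_region", "read_region",
]


def write_volume_series(path, series: VolumeSeries) -> None:
    dz, dy, dx = series.spacing
    tifffile.imwrite(
        path, series.data.astype(np.float32), ome=True,
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": dx, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "µm",
            "TimeIncrement": series.frame_interval_s, "TimeIncrementUnit": "s",
        })


def read_volume_series(path) -> VolumeSeries:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tifffile.xml2dict(tif.ome_metadata)["OME"]["Image"]["Pixels"]
    if data.ndim == 3:
        data = data[None]
    spacing = (float(meta.get("PhysicalSizeZ", 1.0)),
               float(meta.get("PhysicalSizeY", 1.0)),
               float(meta.get("PhysicalSizeX", 1.0)))
    return VolumeSeries(data=data, spacing=spacing,
                        frame_interval_s=float(meta.get("TimeIncrement", 0.0)))


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Sidecar JSON of the scalar/vector truth fields (masks are not stored)."""
    payload = {}
    for key in ("labels", "coupling_frame", "interface_radius_um", "arc_length_um"):
        val = getattr(truth, key)
        if val is not None:
            payload[key] = val
    for key in ("times_s", "interface_center_um", "axis_into_cell",
                "punctum_volumes_um3", "punctum_centers_um"):
        val = getattr(truth, key)
        if val is not None:
            payload[key] = np.asarray(val).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    kwargs = dict(payload)
    for key in ("times_s", "interface_center_um", "axis_into_cell",
                "punctum_volumes_um3", "punctum_centers_um"):
        if key in kwargs:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    return GroundTruth(**kwargs)


def write_trace(csv_path, trace: MembraneTrace, endpoints_path=None) -> None:
    pd.DataFrame(trace.points, columns=["x_um", "y_um"]).to_csv(csv_path, index=False)
    if endpoints_path is not None:
        Path(endpoints_path).write_text(json.dumps(
            {"endpoints": trace.endpoints.tolist(), "cell_id": trace.cell_id}))


def read_trace(csv_path, endpoints_path=None) -> MembraneTrace:
    pts = pd.read_csv(csv_path)[["x_um", "y_um"]].to_numpy(dtype=float)
    if endpoints_path is not None:
        meta = json.loads(Path(endpoints_path).read_text())
        endpoints = np.asarray(meta["endpoints"], dtype=float)
        cell_id = meta.get("cell_id", "")
    else:
        endpoints = np.array([pts[0], pts[-1]])
        cell_id = ""
    return MembraneTrace(points=pts, endpoints=endpoints, cell_id=cell_id)


def write_annotations(path, annotations: list[SynapseAnnotation]) -> None:
    rows = [{"cell_id": a.cell_id, "coupling_frame": a.coupling_frame,
             "cz": a.interface_center[0], "cy": a.interface_center[1],
             "cx": a.interface_center[2],
             "rz": a.cell_rear[0], "ry": a.cell_rear[1], "rx": a.cell_rear[2]}
            for a in annotations]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path) -> list[SynapseAnnotation]:
    df = pd.read_csv(path)
    return [SynapseAnnotation(coupling_frame=int(r.coupling_frame),
                              interface_center=(r.cz, r.cy, r.cx),
                              cell_rear=(r.rz, r.ry, r.rx),
                              cell_id=str(r.cell_id))
            for r in df.itertuples()]


def write_vectors(path, cells: list[StandardizedCell]) -> None:
    n = cells[0].vector.size
    df = pd.DataFrame([c.vector for c in cells],
                      columns=[f"v{i:04d}" for i in range(n)])
    df.insert(0, "frame", [c.frame for c in cells])
    df.insert(0, "cell_id", [c.cell_id for c in cells])
    df.to_csv(path, sep="\t", index=False)


def read_vectors(path) -> list[StandardizedCell]:
    df = pd.read_csv(path, sep="\t")
    vcols = [c for c in df.columns if c.startswith("v")]
    return [StandardizedCell(vector=row[vcols].to_numpy(dtype=float),
                             cell_id=str(row["cell_id"]), frame=int(row["frame"]))
            for _, row in df.iterrows()]


def write_region(path, region: EnrichmentRegion) -> None:
    Path(path).write_text(json.dumps({"n_voxels": int(region.mask.size),
                                      "indices": region.indices.tolist()}))


def read_region(path) -> EnrichmentRegion:
    payload = json.loads(Path(path).read_text())
    mask = np.zeros(int(payload["n_voxels"]), dtype=bool)
    idx = np.asarray(payload["indices"], dtype=int)
    mask[idx] = True
    return EnrichmentRegion(mask=mask, indices=idx)
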