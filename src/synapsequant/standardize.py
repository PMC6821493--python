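"""Cell-shape standardization onto a half-spheroid template.

Each T cell is segmented, reoriented so the T cell:APC interface faces up,
and its fluorescence distribution is resampled onto a standardized
half-spheroid shape so that cells of different sizes and orientations can be
compared voxel by voxel. On the default anisotropic grid (0.34 µm lateral,
1 µm axial) the template interior holds exactly 6628 voxels, so every cell
becomes a probability vector of length 6628 (fractions of total intensity).
Interface enrichment is the mean probability inside a fixed top-decile
template region divided by the mean probability over the whole cell.

Axis conventions used package-wide: arrays are indexed (z, y, x); ``spacing``
triples are (axial, lateral, lateral) µm in the same order; "up" (toward the
interface) is the direction of decreasing z index. Template voxel centers are
expressed as (depth, y, x) with depth ≥ 0 increasing away from the flat
interface face into the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "NoCellCoupleError",
    "TruncatedCellWarning",
    "SynapseAnnotation",
    "HalfSpheroidTemplate",
    "StandardizedCell",
    "EnrichmentRegion",
    "ReorientedCell",
    "detect_tight_coupling",
    "segment_t_cell",
    "reorient_interface_up",
    "build_template",
    "standardize_shape",
    "compute_enrichment_region",
    "enrichment",
]

DEFAULT_SPACING = (1.0, 0.34, 0.34)  # (z, y, x) µm
TEMPLATE_VOXELS = 6628


class NoCellCoupleError(ValueError):
    """Raised when a movie contains no T cell:APC contact in any frame."""


class TruncatedCellWarning(UserWarning):
    """Emitted when a segmented cell touches the volume border extensively."""


@dataclass(frozen=True)
class SynapseAnnotation:
    """Two-point synapse annotation of one cell couple.

    ``interface_center`` marks the center of the T cell:APC contact,
    ``cell_rear`` the opposite (rear) pole of the T cell; the line between
    them defines the cell's symmetry axis used for reorientation. Points are
    (z, y, x) in µm.
    """

    coupling_frame: int
    interface_center: tuple[float, float, float]
    cell_rear: tuple[float, float, float]
    cell_id: str = ""

    def __post_init__(self):
        if np.allclose(self.interface_center, self.cell_rear):
            raise ValueError("annotation points must be distinct")


def detect_tight_coupling(contact_widths, contact_lag_frames: int = 2,
                          full_width_fraction: float = 0.9) -> int:
    """Frame index of tight cell-couple formation (time zero of the course).

    Tight coupling is the earlier of (a) the first frame where the interface
    has reached its full width — operationalized as ≥ ``full_width_fraction``
    of the steady-state width, the median over the final 25% of frames — and
    (b) ``contact_lag_frames`` frames (40 s at the 20-s frame interval) after
    first contact.
    """
    w = np.asarray(contact_widths, dtype=float)
    nonzero = np.flatnonzero(w > 0)
    if nonzero.size == 0:
        raise NoCellCoupleError("no cell couple: zero contact width in every frame")
    first_contact = int(nonzero[0])
    tail = w[-max(1, round(0.25 * w.size)):]
    steady = float(np.median(tail))
    full = np.flatnonzero(w >= full_width_fraction * steady)
    full_frame = int(full[0]) if full.size else w.size - 1
    return min(full_frame, first_contact + contact_lag_frames)


def segment_t_cell(volume: np.ndarray, seed_voxel, spacing=DEFAULT_SPACING,
                   cell_radius_um: float = 5.0) -> np.ndarray:
    """Segment the T cell containing ``seed_voxel`` from a 3D intensity volume.

    The threshold is chosen by Otsu's method on the volume restricted to a
    box of half-width 2 × ``cell_radius_um`` around the seed; the mask is the
    connected component (full 26-connectivity) of supra-threshold voxels that
    contains the seed. If the mask touches the volume border over more than
    25% of its surface a :class:`TruncatedCellWarning` is emitted.
    """
    seed = tuple(int(round(s)) for s in seed_voxel)
    if any(not 0 <= s < n for s, n in zip(seed, volume.shape)):
        raise ValueError("seed voxel outside the volume")
    sl = tuple(
        slice(max(0, s - int(np.ceil(2 * cell_radius_um / sp))),
              min(n, s + int(np.ceil(2 * cell_radius_um / sp)) + 1))
        for s, sp, n in zip(seed, spacing, volume.shape)
    )
    thr = threshold_otsu(volume[sl])
    fg = volume > thr
    if not fg[seed]:
        raise ValueError("seed lies in background (below the Otsu threshold)")
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    mask = labels == labels[seed]

    surface = mask & ~ndimage.binary_erosion(mask)
    border = np.zeros_like(mask)
    for ax in range(3):
        idx_lo = [slice(None)] * 3
        idx_hi = [slice(None)] * 3
        idx_lo[ax] = 0
        idx_hi[ax] = -1
        border[tuple(idx_lo)] = True
        border[tuple(idx_hi)] = True
    n_surface = int(surface.sum())
    if n_surface and (surface & border).sum() / n_surface > 0.25:
        warnings.warn("segmented cell is truncated by the volume border",
                      TruncatedCellWarning, stacklevel=2)
    return mask


@dataclass
class ReorientedCell:
    """A cell volume rotated so the interface faces up (toward z index 0)."""

    volume: np.ndarray
    mask: np.ndarray
    interface_center_um: np.ndarray  # (z, y, x) µm in the rotated frame
    rotation_deg: float


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180°: rotate about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def reorient_interface_up(volume: np.ndarray, mask: np.ndarray,
                          annotation: SynapseAnnotation,
                          spacing=DEFAULT_SPACING) -> ReorientedCell:
    """Rigidly rotate volume and mask so the rear→interface axis points up.

    The rotation is about the physical center of the volume, computed in
    physical (µm) coordinates so the anisotropic voxel grid is handled
    correctly; intensities are resampled trilinearly (total masked intensity
    is conserved to within interpolation error, ~1%). The caller must ensure
    the cell has enough margin to stay inside the field of view.
    """
    axis = np.asarray(annotation.interface_center, float) - np.asarray(annotation.cell_rear, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate synapse axis: annotation points coincide")
    axis /= norm
    up = np.array([-1.0, 0.0, 0.0])  # decreasing z index
    R = _rotation_between(axis, up)

    S = np.diag(spacing)
    S_inv = np.diag(1.0 / np.asarray(spacing))
    center_phys = S @ ((np.asarray(volume.shape) - 1) / 2.0)
    M = S_inv @ R.T @ S
    offset = S_inv @ (np.eye(3) - R.T) @ center_phys

    # fill outside-mask voxels with the nearest masked intensity first, so
    # trilinear interpolation at the cell edge does not dilute the cell with
    # background and masked intensity is conserved
    fill_idx = ndimage.distance_transform_edt(~mask, sampling=spacing, return_indices=True)[1]
    filled = volume[tuple(fill_idx)].astype(float)
    vol_rot = ndimage.affine_transform(filled, M, offset=offset, order=3)
    mask_rot = ndimage.affine_transform(mask.astype(np.float32), M, offset=offset, order=1) > 0.5
    iface = R @ (np.asarray(annotation.interface_center, float) - center_phys) + center_phys
    angle = float(np.degrees(np.arccos(np.clip(np.dot(axis, up), -1.0, 1.0))))
    return ReorientedCell(vol_rot, mask_rot, iface, angle)


@dataclass(frozen=True)
class HalfSpheroidTemplate:
    """The standardized half-spheroid shape and its fixed voxel order.

    The template is the set of grid voxels whose centers lie inside a half
    spheroid with lateral semi-axis ``a`` and axial semi-axis ``c``, cut by
    its flat (interface) face. Voxel centers sit at depth (k + 1/2)·dz below
    the face for layer k and on a lateral lattice centered on the symmetry
    axis. The voxel order is the C-order scan of the (layer, y, x) grid,
    interface-adjacent layer first; this order is the tie-break everywhere a
    fixed order is needed.
    """

    mask: np.ndarray          # (layers, ny, nx) bool
    spacing: tuple            # (z, y, x) µm
    lateral_semi_axis: float  # a, µm
    axial_semi_axis: float    # c, µm
    indices: np.ndarray       # (n, 3) int voxel coordinates, fixed order
    centers_um: np.ndarray    # (n, 3) float (depth, y, x) µm

    @property
    def n_voxels(self) -> int:
        return len(self.indices)

    @property
    def axial_layer(self) -> np.ndarray:
        """Layer index (0 = interface-adjacent) of each template voxel."""
        return self.indices[:, 0]


def _count_interior(a_values, c, spacing, r2_sorted):
    """Interior voxel count for each lateral semi-axis in ``a_values`` at axial ``c``."""
    dz = spacing[0]
    depths = (np.arange(int(np.ceil(c / dz))) + 0.5) * dz
    depths = depths[depths < c]
    if depths.size == 0:
        return np.zeros(len(a_values), dtype=int)
    scale = 1.0 - (depths / c) ** 2           # (K,)
    thr = (np.asarray(a_values)[:, None] ** 2) * scale[None, :]
    counts = np.searchsorted(r2_sorted, thr.ravel(), side="right")
    return counts.reshape(len(a_values), -1).sum(axis=1)


@lru_cache(maxsize=8)
def _calibrate_semi_axes(spacing: tuple, target: int, aspect_target: float,
                         lo: float, hi: float, step: float):
    dz, dy, dx = spacing
    imax = int(np.ceil(hi / dx)) + 1
    jmax = int(np.ceil(hi / dy)) + 1
    ii = np.arange(-imax, imax + 1) * dx
    jj = np.arange(-jmax, jmax + 1) * dy
    r2 = np.sort((ii[:, None] ** 2 + jj[None, :] ** 2).ravel())

    a_values = np.round(np.arange(lo, hi + step / 2, step), 6)
    best = None
    nearest = (np.inf, None)
    for c in a_values:  # same grid for the axial semi-axis
        counts = _count_interior(a_values, float(c), spacing, r2)
        hits = np.flatnonzero(counts == target)
        for h in hits:
            a = float(a_values[h])
            cand = (abs(a / c - aspect_target), a, float(c))
            if best is None or cand < best:
                best = cand
        gap = np.min(np.abs(counts - target))
        if gap < nearest[0]:
            k = int(np.argmin(np.abs(counts - target)))
            nearest = (gap, int(counts[k]))
    if best is None:
        raise ValueError(
            f"no semi-axis pair gives exactly {target} interior voxels in "
            f"[{lo}, {hi}] µm at spacing {spacing}; nearest achievable count "
            f"was {nearest[1]}"
        )
    return best[1], best[2]


def build_template(spacing=DEFAULT_SPACING, target_voxels: int = TEMPLATE_VOXELS,
                   aspect_target: float = 1.5,
                   search_bounds=(2.0, 8.0), search_step: float = 0.01) -> HalfSpheroidTemplate:
    """Build the half-spheroid template with a calibrated interior count.

    The semi-axes are not specified by the count alone, so they are found by
    a 2-parameter grid search over (lateral, axial) semi-axes for pairs whose
    interior voxel count equals ``target_voxels`` exactly; among solutions
    the pair with lateral/axial aspect ratio closest to ``aspect_target``
    (a moderately flattened cell) is kept.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    a, c = _calibrate_semi_axes(spacing, int(target_voxels), float(aspect_target),
                                float(search_bounds[0]), float(search_bounds[1]),
                                float(search_step))
    dz, dy, dx = spacing
    n_layers = int(np.ceil(c / dz))
    depths = (np.arange(n_layers) + 0.5) * dz
    jmax = int(np.ceil(a / dy))
    imax = int(np.ceil(a / dx))
    ys = np.arange(-jmax, jmax + 1) * dy
    xs = np.arange(-imax, imax + 1) * dx
    D, Y, X = np.meshgrid(depths, ys, xs, indexing="ij")
    mask = (X ** 2 + Y ** 2) / a ** 2 + D ** 2 / c ** 2 <= 1.0
    indices = np.argwhere(mask)  # C-order: layer, then y, then x
    centers = np.column_stack([D[mask], Y[mask], X[mask]])
    if len(indices) != target_voxels:
        raise AssertionError("template construction disagrees with calibration")
    return HalfSpheroidTemplate(mask=mask, spacing=spacing,
                                lateral_semi_axis=a, axial_semi_axis=c,
                                indices=indices, centers_um=centers)


@dataclass
class StandardizedCell:
    """A cell's fluorescence distribution on the template, as probabilities."""

    vector: np.ndarray
    cell_id: str = ""
    frame: int = 0

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if np.any(self.vector < 0):
            raise ValueError("probability vector entries must be non-negative")
        if abs(self.vector.sum() - 1.0) > 1e-9:
            raise ValueError("probability vector must sum to 1")


def _infer_interface_center(mask: np.ndarray, spacing) -> np.ndarray:
    """Interface center from a reoriented mask: centroid of the top layer,
    placed on the face just above it."""
    z0 = int(np.flatnonzero(mask.any(axis=(1, 2)))[0])
    ys, xs = np.nonzero(mask[z0])
    return np.array([(z0 - 0.5) * spacing[0], ys.mean() * spacing[1], xs.mean() * spacing[2]])


def standardize_shape(volume: np.ndarray, mask: np.ndarray,
                      template: HalfSpheroidTemplate, spacing=DEFAULT_SPACING,
                      interface_center_um=None, cell_id: str = "", frame: int = 0,
                      ray_step_um: float | None = None) -> StandardizedCell:
    """Resample a reoriented cell onto the template by radial shape mapping.

    For each template voxel a ray is cast from the interface center in the
    voxel's direction; the cell's radial extent along that ray (first exit
    from the mask) is linearly rescaled to the template's radial extent, and
    intensity is sampled at the corresponding cell point by trilinear
    interpolation. Outside-mask intensities are first replaced by the nearest
    masked value so the cell boundary does not bleed background into the
    resampling. The resulting vector is normalized to sum to 1.
    """
    if not mask.any():
        raise ValueError("empty cell mask")
    spacing_arr = np.asarray(spacing, dtype=float)
    origin = (np.asarray(interface_center_um, dtype=float)
              if interface_center_um is not None
              else _infer_interface_center(mask, spacing_arr))

    # fill outside-mask voxels with the nearest inside intensity
    idx = ndimage.distance_transform_edt(~mask, sampling=spacing_arr, return_indices=True)[1]
    filled = volume[tuple(idx)].astype(float)

    q = template.centers_um  # (n, 3) = (depth, y, x); depth along +z of the volume
    qnorm = np.linalg.norm(q, axis=1)
    u = q / qnorm[:, None]
    a, c = template.lateral_semi_axis, template.axial_semi_axis
    r_template = 1.0 / np.sqrt((u[:, 1] ** 2 + u[:, 2] ** 2) / a ** 2 + u[:, 0] ** 2 / c ** 2)

    # march along each ray to find the cell's radial extent (first mask exit)
    h = ray_step_um if ray_step_um is not None else 0.5 * float(spacing_arr.min())
    max_dist = float(np.linalg.norm(spacing_arr * np.asarray(volume.shape)))
    steps = np.arange(1, int(np.ceil(max_dist / h)) + 1) * h
    pts = origin[None, None, :] + u[:, None, :] * steps[None, :, None]
    coords = (pts / spacing_arr).reshape(-1, 3).T
    inside = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0).reshape(
        len(u), -1).astype(bool)
    # the origin sits on the cell face, so shallow rays may start a fraction of
    # a voxel outside the voxelized mask: look for the exit only after the
    # first inside sample
    n_steps = inside.shape[1]
    first_in = np.argmax(inside, axis=1)
    run = inside | (np.arange(n_steps)[None, :] < first_in[:, None])
    first_out = np.argmin(run, axis=1)
    all_in = run.all(axis=1)
    r_cell = np.where(all_in, steps[-1], first_out * h)
    r_cell = np.where(inside.any(axis=1), r_cell, h)
    r_cell = np.maximum(r_cell, h)

    sample = origin[None, :] + u * (qnorm * r_cell / r_template)[:, None]
    values = ndimage.map_coordinates(filled, (sample / spacing_arr).T, order=1)
    values = np.clip(values, 0.0, None)
    total = values.sum()
    if total <= 0:
        raise ValueError("no intensity inside the cell mask")
    return StandardizedCell(values / total, cell_id=cell_id, frame=frame)


@dataclass(frozen=True)
class EnrichmentRegion:
    """The fixed top-decile region of the average probability distribution."""

    mask: np.ndarray     # bool, one entry per template voxel
    indices: np.ndarray  # the region's voxel indices in template order

    @property
    def cardinality(self) -> int:
        return len(self.indices)


def compute_enrichment_region(cells, fraction: float = 0.10) -> EnrichmentRegion:
    """Top-``fraction`` most fluorescent voxels of the average distribution.

    The average is taken over all supplied standardized cells (intended to be
    all cells, all time points and all sensors of a dataset); the region is
    the ``round(fraction × n)`` voxels with the highest average probability.
    Ties at the cutoff are broken by the template's fixed voxel order.
    """
    vectors = [c.vector if isinstance(c, StandardizedCell) else np.asarray(c, float) for c in cells]
    if not vectors:
        raise ValueError("need at least one standardized cell")
    avg = np.mean(vectors, axis=0)
    k = int(round(fraction * avg.size))
    order = np.argsort(-avg, kind="stable")   # stable: ties keep voxel order
    chosen = np.sort(order[:k])
    mask = np.zeros(avg.size, dtype=bool)
    mask[chosen] = True
    return EnrichmentRegion(mask=mask, indices=chosen)


def enrichment(cell: StandardizedCell, region: EnrichmentRegion) -> float:
    """Mean probability inside the enrichment region over the mean in the cell."""
    vec = cell.vector
    if vec.size != region.mask.size:
        raise ValueError("cell and region are on different templates")
    return float(vec[region.mask].mean() / vec.mean())
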