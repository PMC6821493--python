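"""Ground-truthed synthetic imaging data for the analysis pipeline.

This module generates the three kinds of input the analysis consumes, each
with a :class:`GroundTruth` record of what was rendered:

* 4D (T, Z, Y, X) spinning-disk-like movies of a T cell coupled to an APC,
  with a scripted µm-scale accumulation pattern at the interface each frame,
  Poisson shot noise and Gaussian read noise. The T cell is modeled as a
  sphere truncated by a planar contact disc; the APC contributes no
  fluorescence and is simply the dark half-space beyond the interface.
* 3D STED-like deconvolved volumes of puncta: hard ellipsoids of known
  volume, blurred by a Gaussian PSF, over a dim cellular background. The
  high punctum-to-background contrast emulates deconvolved super-resolution
  data.
* 2D sinusoidal membrane traces with an arc length known from adaptive
  quadrature.

Acquisition defaults mirror the imaging setup the analysis targets:
0.34 µm lateral / 1 µm axial voxels and one 3D stack every 20 s for 46
frames. All randomness flows from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, ndimage

from .membrane import MembraneTrace

__all__ = [
    "LABELS",
    "SimConfig",
    "PatternGeometry",
    "PatternScript",
    "GroundTruth",
    "VolumeSeries",
    "make_cell_couple",
    "make_cohort",
    "make_sted_field",
    "make_membrane_trace",
]

#: the six mutually exclusive interface patterns, plus "none"; fixed order
LABELS = ("none", "central", "invagination", "diffuse", "lamellal",
          "peripheral", "asymmetric")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and cell-geometry parameters of the simulated imaging.

    ``voxel_spacing`` is (axial, lateral, lateral) µm matching the package's
    (z, y, x) array convention. ``accumulation_contrast`` is the intensity of
    the accumulation region as a multiple of the cellular background (> 1).
    ``poisson_scale`` is the expected photon count of a background voxel
    (shot noise); ``gaussian_sd`` is additive read noise in intensity units.
    Setting both to 0 yields noise-free volumes.
    """

    voxel_spacing: tuple = (1.0, 0.34, 0.34)
    frame_interval_s: float = 20.0
    n_frames: int = 46
    t_cell_radius_um: float = 5.0
    apc_radius_um: float = 5.0
    interface_radius_um: float = 3.0
    background_intensity: float = 100.0
    accumulation_contrast: float = 2.0
    poisson_scale: float = 50.0
    gaussian_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.accumulation_contrast <= 1.0 and self.accumulation_contrast != 1.0:
            raise ValueError("accumulation contrast must be > 1 (or exactly 1 for no signal)")
        if self.interface_radius_um >= self.t_cell_radius_um:
            raise ValueError("interface radius must be smaller than the cell radius")


@dataclass(frozen=True)
class PatternGeometry:
    """Geometry of the scripted accumulation region, per pattern class."""

    patch_radius_frac: float = 0.4        # central patch radius / interface radius
    invagination_radius_frac: float = 0.25
    invagination_depth_um: float = 2.0
    patch_depth_um: float = 1.0           # thickness of interface-shell patterns
    lamella_depth_um: float = 0.9
    peripheral_inner_frac: float = 0.7    # inner radius of the rim annulus
    wedge_half_angle_deg: float = 45.0    # angular half-width of the asymmetric arc
    cortex_shell_um: float = 0.8          # thickness of the diffuse cortical shell
    cortex_depth_um: float = 3.0          # how far the diffuse shell reaches down


@dataclass
class PatternScript:
    """Per-frame intended pattern labels plus their geometry parameters."""

    labels: list[str]
    geometry: PatternGeometry = field(default_factory=PatternGeometry)

    def __post_init__(self):
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown pattern labels: {sorted(bad)}")
        if "invagination" in self.labels and self.geometry.invagination_depth_um < 1.0:
            raise ValueError("an invagination must be at least 1 µm deep")

    @classmethod
    def uniform(cls, label: str, n_frames: int, geometry: PatternGeometry | None = None):
        return cls([label] * n_frames, geometry or PatternGeometry())


@dataclass
class GroundTruth:
    """What was actually rendered; never consumed by analysis operations."""

    labels: list[str] | None = None
    coupling_frame: int | None = None
    times_s: np.ndarray | None = None
    cell_mask: np.ndarray | None = None
    accumulation_masks: list | None = None
    interface_center_um: np.ndarray | None = None
    interface_radius_um: float | None = None
    axis_into_cell: np.ndarray | None = None
    punctum_volumes_um3: np.ndarray | None = None
    punctum_centers_um: np.ndarray | None = None
    puncta_labels: np.ndarray | None = None
    arc_length_um: float | None = None


@dataclass
class VolumeSeries:
    """4D intensity data with physical voxel and time spacing."""

    data: np.ndarray          # (T, Z, Y, X)
    spacing: tuple            # (z, y, x) µm
    frame_interval_s: float
    channel: str = "GFP"

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _orthonormal_basis(u: np.ndarray):
    """Two unit vectors spanning the plane perpendicular to unit vector u."""
    trial = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(u, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _couple_grid(config: SimConfig, margin_um: float = 1.8):
    """Grid shape and voxel-center coordinates large enough for any orientation."""
    r = config.t_cell_radius_um
    h = np.sqrt(r ** 2 - config.interface_radius_um ** 2)
    half_extent = np.sqrt(((h + r) / 2.0) ** 2 + r ** 2) + margin_um
    spacing = np.asarray(config.voxel_spacing)
    shape = tuple(int(np.ceil(2 * half_extent / s)) | 1 for s in spacing)  # odd
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([Z, Y, X], axis=-1)
    center = spacing * (np.asarray(shape) - 1) / 2.0
    return shape, pts, center, h


def _accumulation_mask(label: str, depth, r, angle, dist_to_center,
                       config: SimConfig, geom: PatternGeometry, cell_mask):
    """Boolean mask of the scripted accumulation region for one frame."""
    R = config.interface_radius_um
    rc = config.t_cell_radius_um
    if label == "none":
        return np.zeros_like(cell_mask)
    if label == "central":
        m = (depth <= geom.patch_depth_um) & (r <= geom.patch_radius_frac * R)
    elif label == "invagination":
        m = (depth <= geom.invagination_depth_um) & (r <= geom.invagination_radius_frac * R)
    elif label == "lamellal":
        m = (depth <= geom.lamella_depth_um) & (r <= R)
    elif label == "diffuse":
        slab = depth <= geom.patch_depth_um
        shell = (np.abs(dist_to_center - rc) <= geom.cortex_shell_um) & (
            depth <= geom.cortex_depth_um)
        m = slab | shell
    elif label == "peripheral":
        m = (depth <= geom.patch_depth_um) & (r >= geom.peripheral_inner_frac * R) & (r <= R)
    elif label == "asymmetric":
        half = np.radians(geom.wedge_half_angle_deg)
        m = ((depth <= geom.patch_depth_um) & (r >= geom.peripheral_inner_frac * R)
             & (r <= R) & (np.abs(angle) <= half))
    else:  # pragma: no cover - guarded by PatternScript validation
        raise ValueError(label)
    return m & cell_mask


def make_cell_couple(config: SimConfig, script: PatternScript,
                     interface_normal=None) -> tuple[VolumeSeries, GroundTruth]:
    """Render a 4D movie of a T cell:APC couple with scripted patterns.

    The T cell is a sphere of radius ``t_cell_radius_um`` truncated by the
    planar contact disc of radius ``interface_radius_um``; cell voxels carry
    ``background_intensity``, the scripted accumulation region carries
    ``accumulation_contrast`` times that, the APC side is dark. Frames beyond
    the script length carry no accumulation. ``interface_normal`` (a (z,y,x)
    vector pointing from the cell toward the APC, default "up") lets the
    couple be rendered in an arbitrary orientation for reorientation tests.
    """
    if len(script.labels) > config.n_frames:
        raise ValueError("script is longer than the movie")
    geom = script.geometry
    r = config.t_cell_radius_um
    if geom.invagination_depth_um > 2 * r:
        raise ValueError(
            f"invagination depth {geom.invagination_depth_um} µm exceeds the "
            f"cell diameter {2 * r} µm")

    normal = np.array([-1.0, 0.0, 0.0]) if interface_normal is None else np.asarray(
        interface_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    u = -normal  # unit axis pointing from the interface into the T cell

    shape, pts, vol_center, h = _couple_grid(config)
    iface_center = vol_center - u * (h + r) / 2.0
    # for grid-aligned couples, snap the contact plane onto a voxel boundary so
    # the first cell layer always sits half a voxel beneath the interface and
    # µm-thin interface-shell patterns cannot fall between voxel centers
    aligned = np.flatnonzero(np.abs(u) > 1 - 1e-9)
    if aligned.size == 1:
        ax = int(aligned[0])
        sp_ax = config.voxel_spacing[ax]
        iface_center[ax] = (np.floor(iface_center[ax] / sp_ax) + 0.5) * sp_ax
    cell_center = iface_center + u * h

    rel = pts - iface_center
    depth = rel @ u
    in_plane = rel - depth[..., None] * u[None, None, None, :]
    e1, e2 = _orthonormal_basis(u)
    py = in_plane @ e1
    px = in_plane @ e2
    r_inplane = np.hypot(py, px)
    angle = np.arctan2(py, px)
    dist_to_center = np.linalg.norm(pts - cell_center, axis=-1)
    cell_mask = (dist_to_center <= r) & (depth >= 0)

    labels = list(script.labels) + ["none"] * (config.n_frames - len(script.labels))
    if config.accumulation_contrast == 1.0:
        # no contrast over background: nothing accumulates, whatever was scripted
        labels = ["none"] * config.n_frames
    rng = np.random.default_rng(config.seed)
    frames = np.empty((config.n_frames, *shape), dtype=np.float32)
    acc_masks = []
    bg = config.background_intensity
    for t, label in enumerate(labels):
        acc = _accumulation_mask(label, depth, r_inplane, angle, dist_to_center,
                                 config, geom, cell_mask)
        if label != "none" and not acc.any():
            raise ValueError(f"scripted geometry for {label!r} renders no voxels "
                             "inside the cell")
        expected = np.where(cell_mask, bg, 0.0)
        expected[acc] = config.accumulation_contrast * bg
        img = expected
        if config.poisson_scale > 0:
            img = rng.poisson(expected / bg * config.poisson_scale) * (bg / config.poisson_scale)
        if config.gaussian_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_sd, size=shape)
        frames[t] = img
        acc_masks.append(acc)

    series = VolumeSeries(frames, tuple(config.voxel_spacing), config.frame_interval_s)
    truth = GroundTruth(labels=labels, cell_mask=cell_mask, accumulation_masks=acc_masks,
                        interface_center_um=iface_center,
                        interface_radius_um=config.interface_radius_um,
                        axis_into_cell=u)
    return series, truth


def _validate_schedule(schedule: pd.DataFrame) -> pd.DataFrame:
    if not set(schedule.columns) <= set(LABELS):
        raise ValueError(f"schedule columns must be a subset of {LABELS}")
    probs = schedule.reindex(columns=LABELS, fill_value=0.0).astype(float)
    vals = probs.to_numpy()
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("schedule probabilities must lie in [0, 1]")
    sums = vals.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError("schedule probabilities must sum to 1 at every time point")
    return probs


def make_cohort(n_cells: int, frequency_schedule: pd.DataFrame,
                config: SimConfig) -> list[tuple[VolumeSeries, GroundTruth]]:
    """Simulate a cohort of cell couples following a pattern-frequency schedule.

    ``frequency_schedule`` is a DataFrame indexed by time (s, relative to
    tight coupling, multiples of the frame interval) whose columns are
    pattern labels and whose rows are probabilities summing to 1. Each cell's
    label at each time point is an independent categorical draw from that
    row, so realized per-time label counts are multinomial. Each movie has
    one frame per schedule time point; the coupling frame is where time is 0.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    probs = _validate_schedule(frequency_schedule)
    times = np.asarray(probs.index, dtype=float)
    if n_cells == 0:
        return []
    rng = np.random.default_rng(config.seed)
    coupling = int(np.argmin(np.abs(times))) if 0.0 in times else 0
    p = probs.to_numpy()
    out = []
    for i in range(n_cells):
        labels = [LABELS[rng.choice(len(LABELS), p=row)] for row in p]
        cell_cfg = replace(config, n_frames=len(times),
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        series, truth = make_cell_couple(cell_cfg, PatternScript(labels))
        truth.coupling_frame = coupling
        truth.times_s = times
        out.append((series, truth))
    return out


def make_sted_field(true_volumes_um3, psf_sigma_um=(0.0, 0.0, 0.0),
                    config: SimConfig | None = None,
                    spacing=(0.05, 0.05, 0.05), centers_um=None,
                    box_um: float = 3.2, amplitude: float = 200.0,
                    amplitude_jitter=(0.7, 1.0), speckle_sd: float = 4.0,
                    min_center_separation_um: float | None = None,
                    ) -> tuple[np.ndarray, GroundTruth]:
    """Render a deconvolved-STED-like 3D puncta field of known volumes.

    Each punctum is a hard sphere of the requested volume, optionally
    blurred by a residual Gaussian PSF of ``psf_sigma_um`` (default 0: fully
    deconvolved, sharp edges); its noise-free above-half-maximum volume
    equals the requested volume up to voxelization error. The image emulates
    deconvolved super-resolution data: a near-black background carrying only
    a half-normal residual speckle of ``speckle_sd``, and punctum peak
    intensities spread over ``amplitude_jitter × amplitude`` (set
    ``speckle_sd=0`` for a noise-free field). Centers are drawn uniformly with a minimum pairwise separation
    (default: non-overlapping and never below 0.1 µm) unless given
    explicitly; explicit centers closer than 0.1 µm are rejected.
    """
    config = config or SimConfig()
    vols = np.asarray(true_volumes_um3, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    if np.any(vols <= 0):
        raise ValueError("punctum volumes must be positive")
    if np.any(vols < voxel_vol):
        raise ValueError("requested punctum smaller than one voxel")
    radii = (3.0 * vols / (4.0 * np.pi)) ** (1.0 / 3.0)
    shape = tuple(int(np.ceil(box_um / s)) for s in spacing)
    rng = np.random.default_rng(config.seed)

    if centers_um is not None:
        centers = np.asarray(centers_um, dtype=float).reshape(len(vols), 3)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < 0.1 - 1e-12:
                    raise ValueError("punctum centers must be at least 0.1 µm apart")
    elif len(vols) == 0:
        centers = np.empty((0, 3))
    else:
        centers = np.empty((len(vols), 3))
        lo = radii.max() + 3 * max(psf_sigma_um)
        for i in range(len(vols)):
            for _ in range(10_000):
                cand = rng.uniform(lo, box_um - lo, size=3)
                sep = (min_center_separation_um if min_center_separation_um is not None
                       else np.maximum(0.1, radii[i] + radii[:i] + 0.15))
                if i == 0 or np.all(np.linalg.norm(centers[:i] - cand, axis=1) >= sep):
                    centers[i] = cand
                    break
            else:
                raise ValueError("could not place puncta with the required separation; "
                                 "enlarge box_um or reduce their number")

    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    img = np.zeros(shape, dtype=np.float64)
    label_img = np.zeros(shape, dtype=np.int32)
    amps = amplitude * rng.uniform(amplitude_jitter[0], amplitude_jitter[1], size=len(vols))
    for k, (c, r, a) in enumerate(zip(centers, radii, amps), start=1):
        inside = (Z - c[0]) ** 2 + (Y - c[1]) ** 2 + (X - c[2]) ** 2 <= r ** 2
        img[inside] = a
        label_img[inside] = k
    sigma_vox = np.asarray(psf_sigma_um, dtype=float) / spacing
    if np.any(sigma_vox > 0):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if speckle_sd > 0:
        img = img + np.abs(rng.normal(0.0, speckle_sd, size=shape))
    truth = GroundTruth(punctum_volumes_um3=vols, punctum_centers_um=centers,
                        puncta_labels=label_img)
    return img.astype(np.float32), truth


def make_membrane_trace(amplitude_um: float, wavelength_um: float, span_um: float,
                        sampling: int = 1000) -> tuple[MembraneTrace, GroundTruth]:
    """A sinusoidal membrane trace y = A·sin(2πx/λ) over [0, span].

    The ground-truth arc length is computed by adaptive quadrature of
    √(1 + A²k²cos²(kx)), independent of the polyline discretization.
    """
    if span_um <= 0:
        raise ValueError("span must be positive")
    if sampling < 2:
        raise ValueError("need at least 2 sample points")
    x = np.linspace(0.0, span_um, sampling)
    k = 2.0 * np.pi / wavelength_um
    y = amplitude_um * np.sin(k * x)
    trace = MembraneTrace(points=np.column_stack([x, y]),
                          endpoints=np.array([[0.0, 0.0], [span_um, 0.0]]))
    if amplitude_um == 0:
        true_len = span_um
    else:
        true_len, _ = integrate.quad(
            lambda t: np.sqrt(1.0 + (amplitude_um * k * np.cos(k * t)) ** 2),
            0.0, span_um, limit=500)
    return trace, GroundTruth(arc_length_um=float(true_len))
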