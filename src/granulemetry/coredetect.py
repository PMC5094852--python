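"""Dense-core identification and segmentation in 3D grey-value volumes.

Secretory-granule dense cores appear in density-coded FIB/SEM stacks as
compact bright blobs (higher grey = more electron dense) surrounded by a
clear halo.  Detection proceeds in five steps:

1. local background and noise estimation by grey-scale morphological opening,
2. background subtraction followed by Gaussian smoothing,
3. core-centre candidate detection (prominence-thresholded components),
4. per-core segmentation at a normalized fraction of the local peak,
5. plausibility filters (size, border margin, contrast).

All length parameters are physical (nm) and converted to voxel units through
:class:`~granulemetry.geometry.VoxelGeometry`, so anisotropic stacks are
handled transparently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from ._util import require
from .geometry import REFERENCE_GEOMETRY, VoxelGeometry

__all__ = [
    "EmVolume",
    "DetectionParams",
    "Candidate",
    "CoreDetection",
    "estimate_background",
    "subtract_and_smooth",
    "find_core_centers",
    "segment_core",
    "filter_candidates",
    "measure_core_grey",
    "detect_cores",
]


@dataclass
class EmVolume:
    """A 3D grey-value image with physical voxel geometry.

    ``data`` is indexed ``(z, y, x)``; values carry 0-255 semantics.  The
    density-coded convention is assumed (denser core = higher grey); use
    ``DetectionParams.invert`` for detector-coded input where cores are dark.
    """

    data: np.ndarray
    geometry: VoxelGeometry = REFERENCE_GEOMETRY
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        require(self.data.ndim == 3, "EmVolume.data must be 3D (z, y, x)")
        require(all(s >= 1 for s in self.data.shape), "each axis needs >= 1 voxel")
        require(np.isfinite(self.data).all(), "grey values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Grey values as float32, linearly rescaled to 0-255 for 16-bit input."""
        data = self.data
        if data.dtype == np.uint16:
            return (data.astype(np.float32) / 257.0)
        return data.astype(np.float32, copy=False)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the dense-core detector (lengths in nm).

    ``background_radius_nm`` must exceed the largest expected core radius so
    the opening removes cores entirely from the background estimate.  The
    segmentation fraction ``k`` sets the core boundary at ``k`` times the
    background-subtracted peak (a *normalized* threshold, so cores of
    different absolute grey are segmented consistently).  ``border_margin_nm``
    of ``None`` rejects cores closer to a volume face than their own
    equivalent radius; ``min_contrast_grey`` of ``None`` means 3x the
    estimated noise level.
    """

    background_radius_nm: float = 400.0
    smoothing_nm: float = 12.0
    min_separation_nm: float = 120.0
    prominence_threshold: float = 6.0
    k: float = 0.5
    min_diameter_nm: float = 100.0
    max_diameter_nm: float = 800.0
    border_margin_nm: Optional[float] = None
    min_contrast_grey: Optional[float] = None
    min_solidity: float = 0.4
    max_solidity: float = 2.0
    background_element: str = "box"
    min_residual_grey: float = 1.0
    invert: bool = False

    def __post_init__(self) -> None:
        require(self.background_radius_nm > 0, "background radius must be positive")
        require(self.smoothing_nm >= 0, "smoothing scale must be non-negative")
        require(self.min_separation_nm > 0, "minimum separation must be positive")
        require(0 < self.k < 1, "segmentation fraction k must lie strictly in (0, 1)")
        require(
            0 < self.min_diameter_nm < self.max_diameter_nm,
            "diameter bounds must be positive and ordered",
        )
        require(self.background_element in ("box", "ellipsoid"), "unknown element")


@dataclass
class Candidate:
    """A putative core centre before segmentation."""

    center_nm: np.ndarray  # (z, y, x)
    peak_voxel: tuple[int, int, int]
    peak_value: float


@dataclass
class CoreDetection:
    """One segmented dense core.

    ``voxels`` is an ``(n, 3)`` integer array of ``(z, y, x)`` indices forming
    a 26-connected set.  ``mean_grey`` is measured on the original
    (pre-subtraction) image, matching how granule condensation is scored.
    """

    center_nm: np.ndarray
    voxels: np.ndarray
    mean_grey: float
    peak_grey: float
    local_background: float


# ---------------------------------------------------------------------------
# step 1: background / noise


def _structuring_element(
    geometry: VoxelGeometry, radius_nm: float, kind: str
) -> tuple[tuple[int, int, int], Optional[np.ndarray]]:
    radii = geometry.radius_voxels(radius_nm)
    if any(r < 1 for r in radii) or radius_nm < geometry.spacing_zyx.max():
        raise ValueError(
            f"background radius {radius_nm} nm is smaller than one voxel along "
            f"some axis for spacing {tuple(geometry.spacing_zyx)}"
        )
    if kind == "box":
        return radii, None
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    dist2 = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return radii, dist2 <= 1.0


def estimate_background(
    data: np.ndarray,
    geometry: VoxelGeometry,
    radius_nm: float,
    element: str = "box",
) -> tuple[np.ndarray, float]:
    """Estimate the local background field and the noise level.

    The background is the grey-scale morphological opening (erosion then
    dilation) with a flat structuring element of the given physical radius —
    an anisotropic box by default (separable, O(N)) or an ellipsoid.  Opening
    never exceeds the image, and with a radius larger than the core radius it
    erases the bright cores, leaving the slowly varying background.

    The noise level is a robust scale estimate, ``1.4826 x MAD`` of the
    residual ``data - background`` restricted to voxels at or below the
    residual's median, which excludes the bright cores from the estimate.

    Returns ``(background, noise)`` with ``background`` the same shape as
    ``data`` (float32).
    """
    data = np.asarray(data, dtype=np.float32)
    radii, footprint = _structuring_element(geometry, radius_nm, element)
    if footprint is None:
        size = tuple(2 * r + 1 for r in radii)
        eroded = ndi.minimum_filter(data, size=size, mode="nearest")
        background = ndi.maximum_filter(eroded, size=size, mode="nearest")
    else:
        eroded = ndi.grey_erosion(data, footprint=footprint, mode="nearest")
        background = ndi.grey_dilation(eroded, footprint=footprint, mode="nearest")

    residual = data - background
    median = float(np.median(residual))
    low = residual[residual <= median]
    noise = 1.4826 * float(np.median(np.abs(low - np.median(low))))
    return background, noise


# ---------------------------------------------------------------------------
# step 2: subtract + smooth


def subtract_and_smooth(
    data: np.ndarray,
    background: np.ndarray,
    geometry: VoxelGeometry,
    smoothing_nm: float,
) -> np.ndarray:
    """Positive part of ``data - background``, Gaussian-smoothed.

    The smoothing scale is physical; per-axis sigmas are
    ``smoothing_nm / pitch`` so anisotropic voxels smooth isotropically in
    real space.  A scale of zero returns the raw residual.
    """
    data = np.asarray(data, dtype=np.float32)
    background = np.asarray(background, dtype=np.float32)
    if data.shape != background.shape:
        raise ValueError(
            f"background shape {background.shape} does not match volume {data.shape}"
        )
    residual = np.clip(data - background, 0.0, None)
    if smoothing_nm > 0:
        sigmas = smoothing_nm / geometry.spacing_zyx[: data.ndim]
        residual = ndi.gaussian_filter(residual, sigma=sigmas, mode="nearest")
    return residual


# ---------------------------------------------------------------------------
# step 3: centre candidates

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def find_core_centers(
    residual: np.ndarray,
    geometry: VoxelGeometry,
    params: DetectionParams,
    noise: float,
) -> list[Candidate]:
    """Locate candidate core centres in the background-free residual.

    Candidates are the 26-connected components of voxels whose residual
    exceeds ``prominence_threshold x noise`` (with a small absolute floor for
    noise-free input).  Rendered cores are plateaus rather than sharp peaks,
    so each supra-threshold component is treated as one maximum of that
    prominence; its centre is the residual-weighted centroid and its peak the
    component maximum (exact ties broken by lexicographic voxel order).
    Candidates closer together than ``min_separation_nm`` are reduced to the
    higher-peaked one.
    """
    require((residual >= 0).all(), "residual must be non-negative")
    threshold = max(params.prominence_threshold * noise, params.min_residual_grey)
    mask = residual > threshold
    if not mask.any():
        return []
    labels, n = ndi.label(mask, structure=_CONN26)
    spacing = geometry.spacing_zyx
    candidates: list[Candidate] = []
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        vals = np.where(comp, residual[sl], 0.0)
        peak_value = float(vals.max())
        peak_local = np.argwhere(vals == peak_value)[0]  # lexicographic first
        peak_voxel = tuple(int(p + s.start) for p, s in zip(peak_local, sl))
        coords = np.argwhere(comp).astype(float)
        coords += [s.start for s in sl]
        weights = residual[sl][comp]
        center = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        candidates.append(Candidate(center * spacing, peak_voxel, peak_value))

    # non-maximum suppression: higher peak wins, ties by voxel order
    candidates.sort(key=lambda c: (-c.peak_value, c.peak_voxel))
    kept: list[Candidate] = []
    for cand in candidates:
        if all(
            np.linalg.norm(cand.center_nm - k.center_nm) >= params.min_separation_nm
            for k in kept
        ):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# step 4: segmentation


def segment_core(
    residual: np.ndarray,
    geometry: VoxelGeometry,
    candidate: Candidate,
    params: DetectionParams,
) -> Optional[np.ndarray]:
    """Segment one core as a connected supra-threshold component.

    The threshold is ``k`` times the candidate's peak residual.  The core is
    the 26-connected component (within a working box sized by the maximum
    plausible core diameter) of voxels at or above threshold that contains
    the candidate's centre voxel.  Returns an ``(n, 3)`` index array, or
    ``None`` when the centre voxel itself falls below threshold (degenerate
    candidate, dropped by the pipeline).
    """
    spacing = geometry.spacing_zyx
    center_voxel = np.round(candidate.center_nm / spacing).astype(int)
    center_voxel = np.clip(center_voxel, 0, np.array(residual.shape) - 1)
    threshold = params.k * candidate.peak_value
    if residual[tuple(center_voxel)] < threshold:
        return None

    half = np.ceil((params.max_diameter_nm / 2) / spacing).astype(int) + 2
    lo = np.maximum(center_voxel - half, 0)
    hi = np.minimum(center_voxel + half + 1, residual.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    local_mask = residual[box] >= threshold
    labels, _ = ndi.label(local_mask, structure=_CONN26)
    seed = tuple(center_voxel - lo)
    lab = labels[seed]
    if lab == 0:  # pragma: no cover - guarded by the threshold check above
        return None
    voxels = np.argwhere(labels == lab)
    voxels += lo
    return voxels


# ---------------------------------------------------------------------------
# step 5: filters


def filter_candidates(
    detections: Sequence[CoreDetection],
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
    params: DetectionParams,
    noise: float = 0.0,
) -> list[CoreDetection]:
    """Reject implausible cores; survivors keep their order.

    A core is rejected when its equivalent diameter falls outside
    ``[min_diameter_nm, max_diameter_nm]``, when its centre lies within the
    border margin of a volume face (incomplete cores at the milled faces bias
    size and grey), when its mean grey exceeds the local background by less
    than the minimum contrast, or when its solidity — measured volume over
    the volume of a sphere with its equivalent diameter — falls outside
    ``[min_solidity, max_solidity]``.  Dense cores are filled, compact
    condensates with solidity near 1; thin membrane arcs are hollow
    (solidity well below 1) and shell bands spanning many planes carry far
    more volume than their small cross-section admits (solidity well above
    1), so both tails mark non-core structures.
    """
    from .morphometry import equivalent_diameter  # local import, avoids cycle

    min_contrast = (
        params.min_contrast_grey if params.min_contrast_grey is not None else 3.0 * noise
    )
    extent = (np.array(shape) - 1) * geometry.spacing_zyx
    accepted: list[CoreDetection] = []
    for det in detections:
        diameter = equivalent_diameter(det.voxels, geometry)
        if not (params.min_diameter_nm <= diameter <= params.max_diameter_nm):
            continue
        margin = params.border_margin_nm
        if margin is None:
            margin = diameter / 2
        if (det.center_nm < margin).any() or (det.center_nm > extent - margin).any():
            continue
        if det.mean_grey - det.local_background < min_contrast:
            continue
        sphere_volume = math.pi / 6.0 * diameter**3
        solidity = len(det.voxels) * geometry.voxel_volume_nm3 / sphere_volume
        if not (params.min_solidity <= solidity <= params.max_solidity):
            continue
        accepted.append(det)
    return accepted


def measure_core_grey(data: np.ndarray, voxels: np.ndarray) -> float:
    """Mean original grey over a core voxel set (the condensation readout)."""
    voxels = np.asarray(voxels)
    require(voxels.size > 0, "core voxel set must be non-empty")
    return float(np.asarray(data)[tuple(voxels.T)].mean())


# ---------------------------------------------------------------------------
# composition


def detect_cores(volume: EmVolume, params: DetectionParams | None = None) -> list[CoreDetection]:
    """Run the full dense-core pipeline on a volume.

    Deterministic for fixed input and parameters.  Returns accepted
    :class:`CoreDetection` records in suppression order (descending peak).
    """
    if params is None:
        params = DetectionParams()
    data = volume.as_float()
    if params.invert:
        data = 255.0 - data
    geometry = volume.geometry
    background, noise = estimate_background(
        data, geometry, params.background_radius_nm, params.background_element
    )
    residual = subtract_and_smooth(data, background, geometry, params.smoothing_nm)
    # Baseline rectification: grey opening under noise sits a few noise sd
    # below the true background (a min-filter property), which lifts the whole
    # residual by a uniform floor.  Re-zero at the residual median so relative
    # thresholds (prominence, k x peak) refer to true prominence above
    # background, not to the opening's offset.
    residual = np.clip(residual - np.median(residual), 0.0, None)
    candidates = find_core_centers(residual, geometry, params, noise)
    detections: list[CoreDetection] = []
    claimed = np.zeros(data.shape, dtype=bool)
    for cand in candidates:
        voxels = segment_core(residual, geometry, cand, params)
        if voxels is None:
            continue
        idx = tuple(voxels.T)
        # candidates come in descending peak order: a weaker candidate whose
        # segment overlaps an already-claimed core is a duplicate, not a core
        if claimed[idx].any():
            continue
        claimed[idx] = True
        detections.append(
            CoreDetection(
                center_nm=cand.center_nm,
                voxels=voxels,
                mean_grey=float(data[idx].mean()),
                peak_grey=float(data[idx].max()),
                local_background=float(background[cand.peak_voxel]),
            )
        )
    return filter_candidates(detections, data.shape, geometry, params, noise)
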