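"""Two-channel fluorescence phantoms for the in vitro fusion assay.

Green spots stand for purified immature granules, red spots for the partner
organelle fraction.  A planted fraction of green spots receives a coincident
red partner at a small sub-pixel offset with an intensity ratio well inside
the crosstalk gate; the remaining red spots are placed away from every green
spot so that chance coincidences are excluded by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .._util import require

__all__ = ["FluorPhantomSpec", "GroundTruthSpot", "generate_fluor_pair"]


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluorPhantomSpec:
    """Specification of one synthetic two-channel field.

    Coincident pairs draw their centre offset from a truncated 2D normal
    (per-axis sigma ``offset_sigma_px``, radius capped at ``offset_max_px``)
    and their red/green peak ratio log-uniformly from
    ``[1/ratio_max_fold, ratio_max_fold]``.
    """

    shape: tuple[int, int] = (512, 512)  # (height, width)
    pixel_nm: float = 100.0
    n_green: int = 300
    n_red: int = 300
    peak_mean: float = 1000.0
    peak_sd: float = 150.0
    peak_min: float = 300.0
    psf_sigma_px: float = 0.8
    background: float = 100.0
    noise_sd: float = 5.0
    coincident_fraction: float = 0.077
    offset_sigma_px: float = 0.2
    offset_max_px: float = 0.5
    ratio_max_fold: float = 2.0
    min_separation_px: float = 6.0
    border_px: float = 8.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        require(self.n_green >= 0 and self.n_red >= 0, "spot counts must be >= 0")
        require(
            0 <= self.coincident_fraction <= 1,
            "coincident fraction must lie in [0, 1]",
        )
        require(self.psf_sigma_px > 0, "point-spread sigma must be positive")
        require(self.ratio_max_fold >= 1, "ratio fold must be >= 1")


@dataclass
class GroundTruthSpot:
    id: str
    channel: str
    x_px: float
    y_px: float
    peak: float
    partner_id: Optional[str] = None


def _place(
    rng: np.random.Generator,
    n: int,
    spec: FluorPhantomSpec,
    avoid: np.ndarray,
    min_avoid: float,
) -> np.ndarray:
    """Place n points with mutual and cross-channel minimum separations."""
    h, w = spec.shape
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(spec.max_attempts):
            p = rng.uniform(
                [spec.border_px, spec.border_px],
                [w - spec.border_px, h - spec.border_px],
            )
            ok = True
            if placed and (
                np.linalg.norm(np.array(placed) - p, axis=1) < spec.min_separation_px
            ).any():
                ok = False
            if ok and len(avoid) and (
                np.linalg.norm(avoid - p, axis=1) < min_avoid
            ).any():
                ok = False
            if ok:
                placed.append(p)
                break
        else:
            raise PlacementError("spot count exceeds what fits at the separation")
    return np.array(placed).reshape(-1, 2)


def _render(image: np.ndarray, spots: list[tuple[np.ndarray, float]], sigma: float):
    h, w = image.shape
    half = int(math.ceil(4 * sigma + 2))
    for center, peak in spots:
        cx, cy = center
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        image[y0:y1, x0:x1] += peak * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2)
        )


def generate_fluor_pair(
    spec: FluorPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthSpot]]:
    """Generate (green, red) images and the ground-truth spot table.

    The number of planted pairs is the realized binomial draw over the green
    spots; pairing flags are recorded in the ground truth.  Deterministic for
    a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    green_xy = _place(rng, spec.n_green, spec, np.empty((0, 2)), 0.0)
    n_pairs = int(rng.binomial(spec.n_green, spec.coincident_fraction))
    require(
        spec.n_red >= n_pairs,
        "red channel has fewer spots than the realized coincident pairs",
    )

    def peak() -> float:
        return float(max(rng.normal(spec.peak_mean, spec.peak_sd), spec.peak_min))

    truths: list[GroundTruthSpot] = []
    green_spots: list[tuple[np.ndarray, float]] = []
    red_spots: list[tuple[np.ndarray, float]] = []

    for i in range(spec.n_green):
        truths.append(
            GroundTruthSpot(
                id=f"green{i:04d}",
                channel="green",
                x_px=float(green_xy[i, 0]),
                y_px=float(green_xy[i, 1]),
                peak=peak(),
            )
        )
        green_spots.append((green_xy[i], truths[-1].peak))

    # coincident partners on the first n_pairs green spots (order is random)
    for j in range(n_pairs):
        g = truths[j]
        while True:
            off = rng.normal(0.0, spec.offset_sigma_px, size=2)
            if np.linalg.norm(off) <= spec.offset_max_px:
                break
        ratio = math.exp(
            rng.uniform(-math.log(spec.ratio_max_fold), math.log(spec.ratio_max_fold))
        )
        rid = f"red{j:04d}"
        truths.append(
            GroundTruthSpot(
                id=rid,
                channel="red",
                x_px=g.x_px + float(off[0]),
                y_px=g.y_px + float(off[1]),
                peak=g.peak * ratio,
                partner_id=g.id,
            )
        )
        g.partner_id = rid
        red_spots.append((np.array([truths[-1].x_px, truths[-1].y_px]), truths[-1].peak))

    # unpaired red spots, kept away from all green spots
    n_free = spec.n_red - n_pairs
    if n_free:
        free_xy = _place(rng, n_free, spec, green_xy, spec.min_separation_px)
        for j in range(n_free):
            truths.append(
                GroundTruthSpot(
                    id=f"red{n_pairs + j:04d}",
                    channel="red",
                    x_px=float(free_xy[j, 0]),
                    y_px=float(free_xy[j, 1]),
                    peak=peak(),
                )
            )
            red_spots.append((free_xy[j], truths[-1].peak))

    green = np.full(spec.shape, spec.background, dtype=np.float32)
    red = np.full(spec.shape, spec.background, dtype=np.float32)
    _render(green, green_spots, spec.psf_sigma_px)
    _render(red, red_spots, spec.psf_sigma_px)
    if spec.noise_sd > 0:
        green += spec.noise_sd * rng.standard_normal(spec.shape, dtype=np.float32)
        red += spec.noise_sd * rng.standard_normal(spec.shape, dtype=np.float32)
    return green, red, truths
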