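"""Synthetic FIB/SEM phantom volumes with known granule ground truth.

A phantom is a uniform-background 8-bit volume into which secretory granules
are rendered with the density-coded convention (denser = higher grey): a
spherical dense core at its sampled grey, a clear halo ring at background
level, and a delimiting membrane shell at intermediate grey.  Fused doublets
are two disjoint cores separated by a clear gap (default 60 nm) inside a
single continuous membrane envelope.  Granules are placed by rejection sampling so
that non-partner membrane envelopes never overlap.

The cell is a box inset from the volume faces (its boundary stands in for
the plasma membrane) and the Golgi region is an ellipsoidal basket at the
cell centre, mirroring the annotation geometry of the real reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .._util import require
from ..coredetect import EmVolume
from ..geometry import REFERENCE_GEOMETRY, VoxelGeometry
from ..morphometry import RegionAnnotation

__all__ = [
    "GreyComponent",
    "GranulePopulationSpec",
    "EmPhantomSpec",
    "GroundTruthGranule",
    "PlacementError",
    "generate_em_volume",
    "wt_like_em_spec",
    "detection_benchmark_spec",
]


class PlacementError(RuntimeError):
    """Granule placement failed: the requested density is infeasible."""


@dataclass(frozen=True)
class GreyComponent:
    """One component of the core-grey mixture (weight, mean, sd on 0-255)."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        require(self.weight >= 0, "component weight must be non-negative")
        require(0 <= self.mean <= 255, "grey mean must lie in [0, 255]")
        require(self.sd >= 0, "grey sd must be non-negative")


@dataclass(frozen=True)
class GranulePopulationSpec:
    """Granule population of one region.

    Diameters are *granule* (membrane-to-membrane) diameters in nm, drawn
    from a truncated normal; the rendered core diameter is the granule
    diameter minus twice (halo + membrane).  Core grey is a mixture so that
    lighter (immature-like) and denser (mature-like) populations straddling
    the 190 boundary can coexist in one region.  ``fused_fraction`` is the
    expected number of fused-doublet events per granule.
    """

    count: int
    diameter_mean_nm: float = 344.0
    diameter_sd_nm: float = 72.0
    diameter_bounds_nm: tuple[float, float] = (210.0, 600.0)
    grey: tuple[GreyComponent, ...] = (GreyComponent(1.0, 215.0, 8.0),)
    halo_nm: float = 40.0
    membrane_nm: float = 10.0
    fused_fraction: float = 0.0

    def __post_init__(self) -> None:
        require(self.count >= 0, "count must be non-negative")
        lo, hi = self.diameter_bounds_nm
        require(0 < lo < hi, "diameter bounds must be positive and ordered")
        require(
            lo > 2 * (self.halo_nm + self.membrane_nm),
            "lower diameter bound must leave a positive core diameter",
        )
        require(0 <= self.fused_fraction <= 1, "fused fraction must lie in [0, 1]")
        require(len(self.grey) >= 1 and sum(c.weight for c in self.grey) > 0,
                "grey mixture needs at least one weighted component")

    @property
    def shell_nm(self) -> float:
        """Halo plus membrane: offset between core and granule radius."""
        return self.halo_nm + self.membrane_nm


@dataclass(frozen=True)
class EmPhantomSpec:
    """Full specification of one EM phantom volume.

    ``populations`` maps region names to population specs; supported regions
    are ``"golgi"`` (inside the Golgi basket, more than the periphery
    threshold away from the membrane), ``"periphery"`` (within the periphery
    band of the cell boundary) and ``"cell"`` (anywhere inside the cell,
    for detection benchmarks that ignore regions).
    """

    shape_zyx: tuple[int, int, int]
    geometry: VoxelGeometry = REFERENCE_GEOMETRY
    populations: dict = field(default_factory=dict)
    background_grey: float = 100.0
    membrane_grey: float = 140.0
    noise_sd: float = 5.0
    cell_margin_nm: float = 60.0
    golgi_semiaxes_nm: Optional[tuple[float, float, float]] = None  # (z, y, x)
    periphery_nm: float = 1000.0
    core_gap_nm: float = 60.0
    clearance_nm: float = 30.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        require(len(self.shape_zyx) == 3, "shape must be (z, y, x)")
        require(all(s >= 1 for s in self.shape_zyx), "dimensions must be >= 1")
        require(self.noise_sd >= 0, "noise sd must be non-negative")
        require(0 <= self.background_grey <= 255, "background grey out of range")
        for region in self.populations:
            require(region in ("golgi", "periphery", "cell"),
                    f"unsupported region {region!r}")
        if "golgi" in self.populations:
            require(self.golgi_semiaxes_nm is not None,
                    "a golgi population requires golgi_semiaxes_nm")

    # geometry helpers -----------------------------------------------------

    def _cell_bounds_nm(self) -> tuple[np.ndarray, np.ndarray]:
        spacing = self.geometry.spacing_zyx
        margins = np.maximum(np.ceil(self.cell_margin_nm / spacing), 1).astype(int)
        lo = margins * spacing
        hi = (np.array(self.shape_zyx) - 1 - margins) * spacing
        require(bool((hi > lo).all()), "cell margin leaves no interior")
        return lo, hi

    def _center_nm(self) -> np.ndarray:
        return (np.array(self.shape_zyx) - 1) * self.geometry.spacing_zyx / 2.0


@dataclass
class GroundTruthGranule:
    """A planted granule with its true parameters."""

    id: str
    center_nm: np.ndarray  # (z, y, x)
    core_diameter_nm: float
    granule_diameter_nm: float
    core_grey: float
    region: str
    partner_id: Optional[str] = None


# ---------------------------------------------------------------------------
# sampling helpers


def _sample_diameter(rng: np.random.Generator, pop: GranulePopulationSpec) -> float:
    lo, hi = pop.diameter_bounds_nm
    if pop.diameter_sd_nm == 0:
        require(lo <= pop.diameter_mean_nm <= hi, "mean outside truncation bounds")
        return pop.diameter_mean_nm
    for _ in range(100_000):
        d = rng.normal(pop.diameter_mean_nm, pop.diameter_sd_nm)
        if lo <= d <= hi:
            return float(d)
    raise RuntimeError("diameter truncation bounds reject everything")


def _sample_grey(rng: np.random.Generator, pop: GranulePopulationSpec) -> float:
    weights = np.array([c.weight for c in pop.grey], dtype=float)
    comp = pop.grey[rng.choice(len(weights), p=weights / weights.sum())]
    grey = rng.normal(comp.mean, comp.sd)
    # integral grey: 8-bit quantization then preserves planted values exactly
    return float(np.clip(round(grey), 1, 254))


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n


# ---------------------------------------------------------------------------
# generation


class _Placer:
    """Sequential rejection-sampling placement with overlap bookkeeping."""

    def __init__(self, spec: EmPhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.lo, self.hi = spec._cell_bounds_nm()
        self.center = spec._center_nm()
        self.centers: list[np.ndarray] = []
        self.outer: list[float] = []

    def depth(self, c: np.ndarray) -> float:
        """Distance (nm) to the nearest cell-box face."""
        return float(min(np.min(c - self.lo), np.min(self.hi - c)))

    def _in_golgi_core(self, c: np.ndarray, scale: float = 0.85) -> bool:
        semi = np.array(self.spec.golgi_semiaxes_nm) * scale
        return float(np.sum(((c - self.center) / semi) ** 2)) <= 1.0

    def admissible(self, c: np.ndarray, region: str, outer_r: float) -> bool:
        d = self.depth(c)
        if d < outer_r + 10.0:  # granule must fit inside the cell
            return False
        if region == "periphery":
            return d <= self.spec.periphery_nm - 50.0
        if region == "golgi":
            return d >= self.spec.periphery_nm + 50.0 and self._in_golgi_core(c)
        return True  # "cell"

    def overlaps(self, c: np.ndarray, outer_r: float) -> bool:
        if not self.centers:
            return False
        centers = np.array(self.centers)
        dist = np.linalg.norm(centers - c, axis=1)
        return bool(
            (dist < np.array(self.outer) + outer_r + self.spec.clearance_nm).any()
        )

    def random_point(self) -> np.ndarray:
        return self.rng.uniform(self.lo, self.hi)

    def place_single(self, region: str, outer_r: float) -> np.ndarray:
        for _ in range(self.spec.max_attempts):
            c = self.random_point()
            if self.admissible(c, region, outer_r) and not self.overlaps(c, outer_r):
                self.centers.append(c)
                self.outer.append(outer_r)
                return c
        raise PlacementError(f"could not place a granule in region {region!r}")

    def place_pair(
        self, region: str, outer: tuple[float, float], separation: float
    ) -> tuple[np.ndarray, np.ndarray]:
        for _ in range(self.spec.max_attempts):
            c1 = self.random_point()
            if not self.admissible(c1, region, outer[0]) or self.overlaps(c1, outer[0]):
                continue
            c2 = c1 + separation * _unit_vector(self.rng)
            if not self.admissible(c2, region, outer[1]) or self.overlaps(c2, outer[1]):
                continue
            self.centers.extend([c1, c2])
            self.outer.extend(outer)
            return c1, c2
        raise PlacementError(f"could not place a fused doublet in region {region!r}")


def _render(
    volume: np.ndarray,
    spec: EmPhantomSpec,
    cores: Sequence[tuple[np.ndarray, float, float]],  # (center, r_core, grey)
    halo_nm: float,
    membrane_nm: float,
) -> None:
    """Render one granule (or one fused doublet) into the volume in place."""
    spacing = spec.geometry.spacing_zyx
    centers = np.array([c for c, _, _ in cores])
    r_out = np.array([r + halo_nm + membrane_nm for _, r, _ in cores])
    lo = np.floor((centers - r_out[:, None]).min(axis=0) / spacing).astype(int) - 1
    hi = np.ceil((centers + r_out[:, None]).max(axis=0) / spacing).astype(int) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, volume.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.ogrid[box]
    dists = []
    for (c, _, _) in cores:
        d2 = sum(((g * p - ci) ** 2) for g, p, ci in zip(grids, spacing, c))
        dists.append(np.sqrt(d2))
    phi = np.minimum.reduce([d - r for d, r in zip(dists, r_out)])
    sub = volume[box]
    sub[phi <= -membrane_nm] = spec.background_grey  # halo / inter-core clearing
    sub[(phi > -membrane_nm) & (phi <= 0)] = spec.membrane_grey
    for d, (_, r_core, grey) in zip(dists, cores):
        sub[d <= r_core] = grey


def generate_em_volume(
    spec: EmPhantomSpec,
) -> tuple[EmVolume, RegionAnnotation, list[GroundTruthGranule]]:
    """Generate a seeded phantom volume, its annotation and its ground truth.

    Bit-identical output for identical spec and seed.  Raises
    :class:`PlacementError` when the requested density is infeasible within
    the per-granule attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    placer = _Placer(spec, rng)
    volume = np.full(spec.shape_zyx, spec.background_grey, dtype=np.float32)
    truths: list[GroundTruthGranule] = []
    next_id = 0

    def new_id() -> str:
        nonlocal next_id
        gid = f"g{next_id:04d}"
        next_id += 1
        return gid

    for region in sorted(spec.populations):
        pop: GranulePopulationSpec = spec.populations[region]
        n = pop.count
        if n == 0:
            continue
        n_pairs = int(rng.binomial(n, pop.fused_fraction)) if pop.fused_fraction else 0
        n_pairs = min(n_pairs, n // 2)
        n_singles = n - 2 * n_pairs

        for _ in range(n_pairs):
            params = []
            for _ in range(2):
                d = _sample_diameter(rng, pop)
                params.append((d, (d - 2 * pop.shell_nm) / 2, _sample_grey(rng, pop)))
            separation = params[0][1] + params[1][1] + spec.core_gap_nm
            outer = tuple(p[1] + pop.shell_nm for p in params)
            c1, c2 = placer.place_pair(region, outer, separation)
            ids = (new_id(), new_id())
            for (c, (d, r_core, grey)), gid, pid in zip(
                ((c1, params[0]), (c2, params[1])), ids, ids[::-1]
            ):
                truths.append(
                    GroundTruthGranule(
                        id=gid,
                        center_nm=c,
                        core_diameter_nm=2 * r_core,
                        granule_diameter_nm=d,
                        core_grey=grey,
                        region=region,
                        partner_id=pid,
                    )
                )
            _render(
                volume,
                spec,
                [(c1, params[0][1], params[0][2]), (c2, params[1][1], params[1][2])],
                pop.halo_nm,
                pop.membrane_nm,
            )

        for _ in range(n_singles):
            d = _sample_diameter(rng, pop)
            r_core = (d - 2 * pop.shell_nm) / 2
            grey = _sample_grey(rng, pop)
            c = placer.place_single(region, r_core + pop.shell_nm)
            truths.append(
                GroundTruthGranule(
                    id=new_id(),
                    center_nm=c,
                    core_diameter_nm=2 * r_core,
                    granule_diameter_nm=d,
                    core_grey=grey,
                    region=region,
                )
            )
            _render(volume, spec, [(c, r_core, grey)], pop.halo_nm, pop.membrane_nm)

    if spec.noise_sd > 0:
        volume += spec.noise_sd * rng.standard_normal(
            spec.shape_zyx, dtype=np.float32
        )
    data = np.clip(np.rint(volume), 0, 255).astype(np.uint8)

    annotation = _build_annotation(spec)
    return EmVolume(data=data, geometry=spec.geometry), annotation, truths


def _build_annotation(spec: EmPhantomSpec) -> RegionAnnotation:
    spacing = spec.geometry.spacing_zyx
    margins = np.maximum(np.ceil(spec.cell_margin_nm / spacing), 1).astype(int)
    cell = np.zeros(spec.shape_zyx, dtype=bool)
    inner = tuple(slice(int(m), int(s - m)) for m, s in zip(margins, spec.shape_zyx))
    cell[inner] = True
    golgi = np.zeros(spec.shape_zyx, dtype=bool)
    if spec.golgi_semiaxes_nm is not None:
        center = spec._center_nm()
        grids = np.ogrid[tuple(slice(0, s) for s in spec.shape_zyx)]
        expr = sum(
            ((g * p - c) / a) ** 2
            for g, p, c, a in zip(grids, spacing, center, spec.golgi_semiaxes_nm)
        )
        golgi = (expr <= 1.0) & cell
    return RegionAnnotation(
        golgi_mask=golgi, cell_mask=cell, periphery_nm=spec.periphery_nm
    )


# ---------------------------------------------------------------------------
# presets


def wt_like_em_spec(
    seed: int,
    shape_zyx: tuple[int, int, int] = (160, 512, 512),
    golgi_count: int = 3,
    periphery_count: int = 35,
) -> EmPhantomSpec:
    """Resting wild-type-like phantom: the generator's reference conditions.

    Periphery granules are large (mean 344 nm) and almost all denser-core
    (planted lighter fraction 0.8 %); Golgi granules are smaller (mean
    280.7 nm) with an 11.7 % lighter fraction; grey populations sit at 170
    and 215, straddling the 190 boundary; fused doublets occur at 8 events
    per 1,000 granules in both regions.
    """
    golgi_pop = GranulePopulationSpec(
        count=golgi_count,
        diameter_mean_nm=280.7,
        diameter_sd_nm=59.0,
        diameter_bounds_nm=(190.0, 470.0),
        grey=(
            GreyComponent(0.117, 170.0, 8.0),
            GreyComponent(0.883, 215.0, 8.0),
        ),
        fused_fraction=0.008,
    )
    periphery_pop = GranulePopulationSpec(
        count=periphery_count,
        diameter_mean_nm=344.0,
        diameter_sd_nm=72.0,
        diameter_bounds_nm=(210.0, 600.0),
        grey=(
            GreyComponent(0.008, 170.0, 8.0),
            GreyComponent(0.992, 215.0, 8.0),
        ),
        fused_fraction=0.008,
    )
    return EmPhantomSpec(
        shape_zyx=shape_zyx,
        populations={"golgi": golgi_pop, "periphery": periphery_pop},
        golgi_semiaxes_nm=(480.0, 600.0, 600.0),
        seed=seed,
    )


def detection_benchmark_spec(
    seed: int,
    shape_zyx: tuple[int, int, int] = (128, 512, 512),
    count: int = 200,
    noise_sd: float = 5.0,
) -> EmPhantomSpec:
    """Detection benchmark: many well-contrasted granules, regions ignored."""
    pop = GranulePopulationSpec(
        count=count,
        diameter_mean_nm=280.0,
        diameter_sd_nm=35.0,
        diameter_bounds_nm=(220.0, 380.0),
        grey=(GreyComponent(1.0, 215.0, 8.0),),
    )
    return EmPhantomSpec(
        shape_zyx=shape_zyx,
        populations={"cell": pop},
        noise_sd=noise_sd,
        clearance_nm=20.0,
        seed=seed,
    )
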