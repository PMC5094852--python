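"""Thin-section sampling of spheres: the stereological size bias.

An ultrathin section through a sphere of diameter D shows a circular
cross-section whose diameter depends on where the section falls.  For a
section at height h from the equator the chord formula gives
``d(h) = D * sqrt(1 - (2h/D)^2)``; averaging over random sections the
apparent diameter is only ``pi/4`` of the true one.  A slab of finite
thickness reports the largest cross-section it contains, so thick sections
(or whole-volume imaging, the limiting case) remove the bias.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .._util import require

__all__ = ["simulate_thin_sections"]


def simulate_thin_sections(
    true_diameters_nm: Sequence[float],
    section_thickness_nm: float,
    n_sections: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apparent diameters of randomly sectioned spheres.

    For each section a sphere is drawn uniformly from ``true_diameters_nm``
    and a slab of the given thickness is placed through it, its centre
    uniform over the sphere's extent.  The apparent diameter is the diameter
    of the largest circular cross-section inside the slab: the full diameter
    when the slab contains the equator, the chord at the slab edge nearest
    the equator otherwise.  Thickness 0 reduces to the chord formula
    ``d(h) = D*sqrt(1-(2h/D)^2)``; a slab at least as thick as the sphere
    always contains the equator and reports the full diameter.
    """
    if section_thickness_nm < 0:
        raise ValueError("section thickness must be non-negative")
    diameters = np.asarray(true_diameters_nm, dtype=float)
    require(diameters.size > 0, "at least one sphere diameter is required")
    require(bool((diameters > 0).all()), "sphere diameters must be positive")
    require(n_sections >= 0, "section count must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    d = diameters[rng.integers(0, diameters.size, size=n_sections)]
    center = rng.uniform(-d / 2, d / 2)

    apparent = np.empty_like(d)
    contains_equator = np.abs(center) <= section_thickness_nm / 2
    apparent[contains_equator] = d[contains_equator]
    off = ~contains_equator
    h = np.abs(center[off]) - section_thickness_nm / 2
    apparent[off] = d[off] * np.sqrt(1.0 - (2.0 * h / d[off]) ** 2)
    return apparent
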