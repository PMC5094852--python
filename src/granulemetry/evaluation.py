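"""Ground-truth evaluation: detection scoring and parameter recovery.

These helpers benchmark the pipeline against the synthetic generators'
planted truth: centre matching with precision/recall, and end-to-end
recovery of per-region diameter means, lighter-core fractions, the fused
doublet rate and the fluorescence coincidence fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .coredetect import DetectionParams, detect_cores
from .fluorassay import ColocParams, quantify_fusion
from .fusion3d import detect_fusion_events
from .morphometry import (
    ClassificationParams,
    annotate_regions,
    classify_grey,
    group_cores_into_granules,
)
from .synth import (
    FluorPhantomSpec,
    generate_em_volume,
    generate_fluor_pair,
    wt_like_em_spec,
)

__all__ = [
    "MatchResult",
    "match_centers",
    "run_em_pipeline",
    "detection_benchmark",
    "em_recovery_experiment",
    "fluor_recovery_experiment",
]


@dataclass
class MatchResult:
    """One-to-one assignment of detections to planted objects."""

    pairs: list[tuple[int, int]]  # (truth index, detection index)
    precision: float
    recall: float
    mean_error_nm: float


def match_centers(
    true_centers_nm: np.ndarray,
    detected_centers_nm: np.ndarray,
    max_distance_nm: float,
) -> MatchResult:
    """Optimal one-to-one matching within a distance gate (Hungarian)."""
    t = np.asarray(true_centers_nm, dtype=float).reshape(-1, 3)
    d = np.asarray(detected_centers_nm, dtype=float).reshape(-1, 3)
    if len(t) == 0 or len(d) == 0:
        return MatchResult([], 0.0 if len(d) else 1.0, 0.0 if len(t) else 1.0, np.nan)
    cost = np.linalg.norm(t[:, None, :] - d[None, :, :], axis=2)
    big = 10 * max_distance_nm + cost.max()
    rows, cols = linear_sum_assignment(np.where(cost <= max_distance_nm, cost, big))
    pairs = [
        (int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= max_distance_nm
    ]
    errors = [cost[r, c] for r, c in pairs]
    return MatchResult(
        pairs=pairs,
        precision=len(pairs) / len(d),
        recall=len(pairs) / len(t),
        mean_error_nm=float(np.mean(errors)) if errors else np.nan,
    )


def run_em_pipeline(spec, det_params: Optional[DetectionParams] = None):
    """Generate a phantom and run detection + morphometry on it.

    Returns ``(records, truths, volume, annotation)`` with records carrying
    region labels.
    """
    volume, annotation, truths = generate_em_volume(spec)
    cores = detect_cores(volume, det_params or DetectionParams())
    records = group_cores_into_granules(cores, volume.geometry)
    records = annotate_regions(records, annotation, volume.geometry)
    return records, truths, volume, annotation, cores


def detection_benchmark(spec, det_params: Optional[DetectionParams] = None) -> dict:
    """Detection precision/recall/centre-error/grey-error on one phantom."""
    volume, _, truths = generate_em_volume(spec)
    cores = detect_cores(volume, det_params or DetectionParams())
    diag = float(np.linalg.norm(volume.geometry.spacing_zyx))
    match = match_centers(
        np.array([t.center_nm for t in truths]),
        np.array([c.center_nm for c in cores]).reshape(-1, 3),
        max_distance_nm=5 * diag,
    )
    grey_ok = 0
    for ti, di in match.pairs:
        n_vox = len(cores[di].voxels)
        tol = 3 * spec.noise_sd / np.sqrt(n_vox) if spec.noise_sd > 0 else 1e-9
        if abs(cores[di].mean_grey - truths[ti].core_grey) <= max(tol, 1e-9):
            grey_ok += 1
    errors = [
        float(np.linalg.norm(truths[ti].center_nm - cores[di].center_nm))
        for ti, di in match.pairs
    ]
    return {
        "n_true": len(truths),
        "n_detected": len(cores),
        "precision": match.precision,
        "recall": match.recall,
        "mean_center_error_nm": float(np.mean(errors)) if errors else np.nan,
        "voxel_diagonal_nm": diag,
        "grey_within_tolerance_fraction": grey_ok / max(len(match.pairs), 1),
    }


def em_recovery_experiment(
    seeds: Sequence[int],
    spec_factory=wt_like_em_spec,
    det_params: Optional[DetectionParams] = None,
) -> dict:
    """Pooled parameter recovery across seeded phantoms.

    Per region: planted (realized ground truth) and recovered mean diameter
    of single-core granules, with SEMs, and planted vs recovered lighter-core
    fractions.  Recovered granule diameters add twice the shell width (halo
    plus membrane, known phantom geometry) to the measured core equivalent
    diameter, since membranes are not segmented.  Also pools the planted and
    recovered fused-doublet rates per 1,000 granules.
    """
    class_params = ClassificationParams()
    planted: dict[str, dict[str, list]] = {}
    recovered: dict[str, dict[str, list]] = {}
    n_truth_total = 0
    n_truth_pairs = 0
    n_rec_total = 0
    n_rec_events = 0
    cell_volume_um3 = 0.0

    for seed in seeds:
        spec = spec_factory(seed)
        records, truths, volume, annotation, cores = run_em_pipeline(spec, det_params)
        cell_volume_um3 += float(annotation.cell_mask.sum()) * volume.geometry.voxel_volume_um3
        shell = {
            region: spec.populations[region].shell_nm for region in spec.populations
        }
        n_truth_total += len(truths)
        n_truth_pairs += sum(1 for t in truths if t.partner_id is not None) // 2
        n_rec_total += len(records)
        n_rec_events += len(detect_fusion_events(records))

        for t in truths:
            if t.partner_id is not None:
                continue
            bucket = planted.setdefault(t.region, {"diam": [], "lighter": []})
            bucket["diam"].append(t.granule_diameter_nm)
            bucket["lighter"].append(t.core_grey < class_params.grey_threshold)
        for r in records:
            if r.n_cores != 1 or r.region not in shell:
                continue
            bucket = recovered.setdefault(r.region, {"diam": [], "lighter": []})
            bucket["diam"].append(r.diameter_nm + 2 * shell[r.region])
            bucket["lighter"].append(classify_grey(r, class_params) == "lighter")

    out: dict = {"regions": {}}
    for region in sorted(planted):
        p, r = planted[region], recovered.get(region, {"diam": [], "lighter": []})
        pd, rd = np.array(p["diam"]), np.array(r["diam"])
        out["regions"][region] = {
            "n_planted": len(pd),
            "n_recovered": len(rd),
            "planted_diameter_mean_nm": float(pd.mean()),
            "recovered_diameter_mean_nm": float(rd.mean()) if len(rd) else np.nan,
            "recovered_diameter_sem_nm": (
                float(rd.std(ddof=1) / np.sqrt(len(rd))) if len(rd) > 1 else np.nan
            ),
            "planted_lighter_fraction": float(np.mean(p["lighter"])),
            "recovered_lighter_fraction": (
                float(np.mean(r["lighter"])) if r["lighter"] else np.nan
            ),
        }
    out["planted_fusion_per_1000"] = 1000.0 * n_truth_pairs / n_truth_total
    out["recovered_fusion_per_1000"] = (
        1000.0 * n_rec_events / n_rec_total if n_rec_total else np.nan
    )
    out["n_granules_planted"] = n_truth_total
    out["n_granules_recovered"] = n_rec_total
    from .morphometry import vesicle_density

    out["granule_density_per_um3"] = (
        vesicle_density(n_rec_total, cell_volume_um3) if cell_volume_um3 else np.nan
    )
    return out


def fluor_recovery_experiment(
    seeds: Sequence[int],
    spec_factory=None,
    coloc_params: Optional[ColocParams] = None,
) -> dict:
    """Pooled recovery of the coincident-pair fraction across seeded fields."""
    if spec_factory is None:
        spec_factory = lambda seed: FluorPhantomSpec(seed=seed)  # noqa: E731
    n_green = n_events = n_planted_pairs = n_planted_green = 0
    for seed in seeds:
        spec = spec_factory(seed)
        green, red, truths = generate_fluor_pair(spec)
        result = quantify_fusion(green, red, coloc_params)
        n_green += result.n_green
        n_events += result.n_events
        n_planted_green += sum(1 for t in truths if t.channel == "green")
        n_planted_pairs += sum(
            1 for t in truths if t.channel == "green" and t.partner_id is not None
        )
    return {
        "planted_fraction": n_planted_pairs / n_planted_green,
        "recovered_fraction": n_events / n_green if n_green else np.nan,
        "recovered_rate_pct": 100.0 * n_events / n_green if n_green else np.nan,
        "n_green_detected": n_green,
        "n_green_planted": n_planted_green,
        "n_events": n_events,
        "n_planted_pairs": n_planted_pairs,
    }
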