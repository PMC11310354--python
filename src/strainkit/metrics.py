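"""Strain-error metrics over shared overlap regions, and the permutation
test used to compare methods.

The spatial strain error at a pixel is the Frobenius norm of the
difference between predicted and true symmetric strain tensors (the
off-diagonal entry contributes twice under the tensor double sum).  The
per-frame error is its median over the overlap region; the overall
error pools all overlap pixels of all frames before taking the median
(not a median of medians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import StrainField

__all__ = [
    "ErrorSummary",
    "spatial_strain_error",
    "strain_error",
    "median_strain_error",
    "overlap_mask",
    "permutation_test",
    "summarize_errors",
]


def spatial_strain_error(pred: StrainField, truth: StrainField) -> np.ndarray:
    """Per-pixel tensor-difference norm, sqrt(sum_ij (dpred_ij)^2)."""
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    dxx = pred.exx - truth.exx
    dxy = pred.exy - truth.exy
    dyy = pred.eyy - truth.eyy
    return np.sqrt(dxx**2 + 2.0 * dxy**2 + dyy**2)


def strain_error(
    spatial_map: np.ndarray, mask: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Median (and first/third quartiles) of a spatial error map over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("overlap mask is empty")
    vals = np.asarray(spatial_map)[mask]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def median_strain_error(
    spatial_maps: Sequence[np.ndarray], mask: np.ndarray
) -> float:
    """Pooled median over all overlap pixels of all frames."""
    mask = np.asarray(mask, dtype=bool)
    if len(spatial_maps) == 0:
        raise ValueError("need at least one frame")
    pooled = np.concatenate([np.asarray(m)[mask] for m in spatial_maps])
    if pooled.size == 0:
        raise ValueError("empty pixel pool")
    return float(np.median(pooled))


def overlap_mask(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixels where every method produced a valid estimate."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], dtype=bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("mask shapes differ")
        out &= m
    if not out.any():
        counts = [int(np.asarray(m).sum()) for m in masks]
        raise ValueError(
            f"overlap region is empty (per-mask valid counts: {counts})"
        )
    return out


@dataclass
class ErrorSummary:
    """Per-frame and cycle-level error statistics of one method."""

    spatial_errors: list[np.ndarray]
    per_frame_error: np.ndarray
    per_frame_quartiles: np.ndarray
    overall_error: float
    overlap: np.ndarray


def summarize_errors(
    preds: Sequence[StrainField],
    truths: Sequence[StrainField],
    extra_masks: Sequence[np.ndarray] = (),
) -> ErrorSummary:
    """Full error summary of a predicted sequence against ground truth.

    The overlap region is the conjunction of every prediction's validity
    mask with any ``extra_masks`` (e.g. other methods' valid regions).
    """
    if len(preds) != len(truths):
        raise ValueError("one truth per prediction required")
    masks = [p.valid_mask for p in preds] + list(extra_masks)
    overlap = overlap_mask(masks)
    maps = [spatial_strain_error(p, t) for p, t in zip(preds, truths)]
    med_q = [strain_error(m, overlap) for m in maps]
    return ErrorSummary(
        spatial_errors=maps,
        per_frame_error=np.array([m for m, _ in med_q]),
        per_frame_quartiles=np.array([q for _, q in med_q]),
        overall_error=median_strain_error(maps, overlap),
        overlap=overlap,
    )


def permutation_test(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of sample medians.

    Pools both samples, redraws the group assignment ``n_perm`` times,
    and returns the add-one estimate
    p = (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 100:
        import logging

        logging.getLogger(__name__).warning(
            "permutation test with n_perm=%d (< 100) is imprecise", n_perm
        )
    observed = abs(np.median(a) - np.median(b))
    # canonicalize so the test is invariant to swapping the two samples:
    # the statistic is symmetric, and sorting the pool plus putting the
    # smaller group first makes the permutation draws identical
    if b.size < a.size:
        a, b = b, a
    pooled = np.sort(np.concatenate([a, b]))
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, int(2e7 // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        diffs = np.abs(
            np.median(perm[:, : a.size], axis=1)
            - np.median(perm[:, a.size:], axis=1)
        )
        count += int((diffs >= observed - 1e-15).sum())
        done += m
    return (1 + count) / (n_perm + 1)
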