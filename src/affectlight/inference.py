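"""Significance thresholds for decoding accuracy maps.

Two parallel multiple-comparison corrections are provided, mirroring common
searchlight practice:

1. a permutation null of sphere accuracies (condition labels shuffled within
   each subject x run block, preserving class balance) combined with a
   resel-wise Bonferroni alpha — the familywise alpha divided by the number of
   non-overlapping searchlight spheres that fit in the mask;
2. an exact binomial threshold with voxel-wise Bonferroni correction: the
   smallest accuracy k*/n whose upper-tail probability under
   Binomial(n, chance) is at or below the per-test alpha.

When both are available the operating threshold is the more conservative
(larger) of the two.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .datasets import PatternDataset
from .neighborhood import SphereNeighborhood, sphere_offsets
from .searchlight import (
    AccuracyMap,
    _cv_accuracy,
    leave_one_run_out,
    leave_one_subject_out,
)

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Sorted accuracies from label-permuted classifications."""

    values: np.ndarray
    n_permutations: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size != self.n_permutations:
            raise ValueError("length of values must equal n_permutations")


@dataclass
class SignificanceDecision:
    """A threshold, how it was obtained, and the resulting binary map."""

    threshold: float
    method: str  # "permutation-resel" | "binomial-bonferroni"
    alpha: float
    significance_map: np.ndarray = field(repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.significance_map.sum())


# ---------------------------------------------------------------------------
# permutation null


def _shuffle_labels_within_blocks(attrs, rng) -> np.ndarray:
    """Permute condition labels independently within each (subject, run) block."""
    y = attrs["condition"].to_numpy().copy()
    for _, block in attrs.groupby(["subject_id", "run_id"], sort=False):
        idx = block.index.to_numpy()
        y[idx] = y[rng.permutation(idx)]
    return y


def permutation_null_sphere(
    sphere_dataset: PatternDataset,
    cv_scheme: str,
    n_perms: int,
    seed: int,
    C: float | None = None,
) -> NullDistribution:
    """Null accuracies for one sphere under label exchange.

    Every permutation shuffles condition labels within each (subject, run)
    block — preserving run structure and exact class balance — re-runs the
    full cross-validation on the sphere's features and records the mean fold
    accuracy.

    Parameters
    ----------
    sphere_dataset : PatternDataset
        Dataset restricted to one sphere's voxels (``samples`` columns are the
        sphere members).
    cv_scheme : {"loso", "loro"}
        Leave-one-subject-out or leave-one-run-out folds.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    attrs = sphere_dataset.attrs
    if cv_scheme == "loso":
        folds = leave_one_subject_out(attrs)
    elif cv_scheme == "loro":
        folds = leave_one_run_out(attrs)
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")

    X = sphere_dataset.samples
    gram = X @ X.T  # labels change, features do not: reuse across permutations
    norms = np.sqrt(np.clip(np.diag(gram), 0, None))
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perms)
    for p in range(n_perms):
        y = _shuffle_labels_within_blocks(attrs, rng)
        vals[p] = _cv_accuracy(gram, y, norms, folds, C)
    chance = 1.0 / len(sphere_dataset.conditions)
    return NullDistribution(
        values=vals,
        n_permutations=n_perms,
        metadata={"cv_scheme": cv_scheme, "chance": chance, "seed": seed},
    )


# ---------------------------------------------------------------------------
# resel accounting


def count_resels(mask: np.ndarray, radius: float) -> int:
    """Greedy non-overlapping sphere packing of the mask.

    Scans in-mask voxels in lexicographic (C) order and accepts a centre
    whenever its sphere shares no voxel with any previously accepted sphere;
    the accepted count approximates the number of independent resolution
    elements at this searchlight radius.  Deterministic by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    offs = sphere_offsets(radius)
    shape = np.asarray(mask.shape)
    covered = np.zeros(mask.shape, dtype=bool)
    count = 0
    for c in np.argwhere(mask):
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        ix, iy, iz = pts[:, 0], pts[:, 1], pts[:, 2]
        inmask = mask[ix, iy, iz]
        ix, iy, iz = ix[inmask], iy[inmask], iz[inmask]
        if covered[ix, iy, iz].any():
            continue
        covered[ix, iy, iz] = True
        count += 1
    return count


def resel_alpha(total_alpha: float, n_resels: int) -> float:
    """Bonferroni alpha per resel: total_alpha / n_resels."""
    if not (0 < total_alpha <= 1):
        raise ValueError("total_alpha must be in (0, 1]")
    if n_resels < 1:
        raise ValueError("n_resels must be >= 1")
    return total_alpha / n_resels


# ---------------------------------------------------------------------------
# thresholds


def _resolution_step(values: np.ndarray) -> float:
    gaps = np.diff(np.unique(values))
    gaps = gaps[gaps > 0]
    return float(gaps.min()) if gaps.size else float(np.finfo(float).eps)


def null_threshold(
    null: NullDistribution, alpha: float, method: str = "exceedance"
) -> float:
    """Accuracy threshold from a permutation null.

    ``method="exceedance"`` (default) returns the smallest observed accuracy t
    whose exceedance count ``#{null >= t}`` is strictly below
    ``floor(alpha * n_permutations)`` — e.g. with alpha*n ~= 10.5 a value must
    be matched or exceeded fewer than 10 times to pass.  ``method="quantile"``
    returns the empirical (1 - alpha) upper quantile instead.

    When ``alpha * n_permutations < 1`` the null is too short to resolve the
    requested level; a warning is issued and the null maximum plus one
    resolution step is returned (nothing observed can pass).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    vals = null.values
    n = null.n_permutations
    if method == "quantile":
        return float(np.quantile(vals, 1.0 - alpha, method="higher"))
    if method != "exceedance":
        raise ValueError(f"unknown method {method!r}")
    m = int(np.floor(alpha * n))
    if m < 1:
        warnings.warn(
            f"alpha * n_permutations = {alpha * n:.3g} < 1: null resolution "
            "insufficient; returning null maximum + one resolution step"
        )
        return float(vals[-1] + _resolution_step(vals))
    for t in np.unique(vals):
        if n - np.searchsorted(vals, t, side="left") < m:
            return float(t)
    warnings.warn("no observed value passes the exceedance rule; returning max + step")
    return float(vals[-1] + _resolution_step(vals))


def binomial_threshold(n_trials: int, chance_p: float, per_test_alpha: float) -> float:
    """Smallest accuracy k*/n with exact binomial tail P(X >= k*) <= alpha.

    Uses exact tail sums under X ~ Binomial(n_trials, chance_p); no normal
    approximation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < chance_p < 1):
        raise ValueError("chance_p must be in (0, 1)")
    if not (0 < per_test_alpha <= 1):
        raise ValueError("per_test_alpha must be in (0, 1]")
    k = np.arange(n_trials + 1)
    upper_tail = binom.sf(k - 1, n_trials, chance_p)  # P(X >= k)
    ok = np.flatnonzero(upper_tail <= per_test_alpha)
    if ok.size == 0:
        raise ValueError(f"alpha {per_test_alpha} unattainable at n_trials={n_trials}")
    return float(k[ok[0]] / n_trials)


def threshold_map(accuracy_map: AccuracyMap, threshold: float) -> np.ndarray:
    """Binary significance map: in-mask voxels with accuracy > threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    if accuracy_map.data.shape != accuracy_map.mask.shape:
        raise ValueError("accuracy map grid does not match its mask")
    with np.errstate(invalid="ignore"):
        sig = accuracy_map.mask & (np.nan_to_num(accuracy_map.data, nan=-1.0) > threshold)
    logger.info("threshold %.4f: %d significant voxels", threshold, int(sig.sum()))
    return sig


def operating_threshold(permutation_thr: float, binomial_thr: float) -> float:
    """The more conservative (larger) of the two corrected thresholds."""
    return max(permutation_thr, binomial_thr)


def decide_significance(
    accuracy_map: AccuracyMap,
    threshold: float,
    method: str,
    alpha: float,
) -> SignificanceDecision:
    """Package a thresholding choice with its binary map."""
    return SignificanceDecision(
        threshold=threshold,
        method=method,
        alpha=alpha,
        significance_map=threshold_map(accuracy_map, threshold),
    )
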