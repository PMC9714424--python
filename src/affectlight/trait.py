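"""Brain-behavior correlation of decoding accuracy with trait scores.

Per-subject searchlight accuracy maps are regressed voxel-wise on a demeaned
trait score (one Interpersonal Reactivity Index sub-scale at a time).  The
slope t statistic is enhanced with threshold-free cluster enhancement (TFCE)
and familywise error is controlled by the permutation distribution of the
maximum TFCE statistic over the mask: the regressor is randomly re-associated
with subjects in each permutation.  The output is a map of 1 - p, significant
at 1 - p >= 0.95, optionally intersected with the group-level decoding mask
(the conjunction: voxels where classification is above chance for everyone
AND varies with the trait).

The test is one-sided (positive association) by default, with a two-sided
option that enhances |t| instead.  Each sub-scale is tested in its own model;
no correction across sub-scales is applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Sentinel replacing infinite t statistics at zero-residual voxels.
T_SENTINEL = 1e6

#: 6-connectivity structuring element (faces only).
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class TfceParams:
    """Threshold-free cluster enhancement settings.

    ``E`` and ``H`` are the extent and height exponents (0.5 and 2 are the
    published convention); integration uses ``n_steps`` equal height steps up
    to the map maximum unless a fixed step ``dh`` is given.  Clusters are
    6-connected.
    """

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    dh: float | None = None

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def demean(scores) -> np.ndarray:
    """Centre trait scores to mean zero (the regressor convention)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need >= 3 subjects")
    if np.ptp(scores) == 0:
        raise ValueError("constant scores make a degenerate regressor")
    return scores - scores.mean()


def voxelwise_statistic(accuracy_stack: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Per-voxel t statistic of the OLS slope of accuracy on the regressor.

    ``accuracy_stack`` is (n_subjects, n_voxels); the regressor is demeaned
    internally, so with a single regressor plus intercept the t statistic is a
    monotone transform of the Pearson correlation.  Voxels with zero accuracy
    variance get t = 0; zero-residual (perfect-fit) voxels are capped at
    ``T_SENTINEL`` with the slope's sign.
    """
    Y = np.asarray(accuracy_stack, dtype=float)
    x = demean(regressor)
    if Y.ndim != 2 or Y.shape[0] != x.size:
        raise ValueError(
            f"accuracy stack rows ({Y.shape[0] if Y.ndim == 2 else '?'}) must "
            f"match regressor length ({x.size})"
        )
    n = x.size
    sxx = float(x @ x)
    beta = (x @ Y) / sxx
    fitted = Y.mean(axis=0)[None, :] + np.outer(x, beta)
    sse = ((Y - fitted) ** 2).sum(axis=0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        t = beta / se
    t[np.var(Y, axis=0) == 0] = 0.0
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=T_SENTINEL, neginf=-T_SENTINEL),
                -T_SENTINEL, T_SENTINEL)
    return t


def tfce(stat_map: np.ndarray, mask: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a 3-D map.

    Discrete integration: for each height step h the 6-connected
    supra-threshold clusters are labelled and every member voxel accumulates
    ``extent(h)**E * h**H * dh``.  Negative values contribute nothing (apply
    to ``-map`` or ``|map|`` for the other tail / two-sided use).
    """
    if params is None:
        params = TfceParams()
    stat = np.where(np.asarray(mask, dtype=bool), np.asarray(stat_map, dtype=float), 0.0)
    if not np.isfinite(stat).all():
        raise ValueError("stat map must be finite")
    hmax = stat.max()
    out = np.zeros_like(stat)
    if hmax <= 0:
        return out
    if params.dh is not None:
        dh = params.dh
        heights = np.arange(dh, hmax + 1e-12, dh)
    else:
        dh = hmax / params.n_steps
        heights = dh * np.arange(1, params.n_steps + 1)
    for h in heights:
        supra = stat >= h
        labels, n_lab = ndimage.label(supra, structure=CONNECTIVITY_6)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += np.where(supra, sizes[labels] ** params.E * h**params.H * dh, 0.0)
    return out


@dataclass
class CorrectedPMap:
    """Voxel-wise 1 - p from the max-statistic permutation null."""

    one_minus_p: np.ndarray
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)
    null_max: np.ndarray = field(repr=False)
    significance_level: float = 0.95

    @property
    def significance_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.mask & (
                np.nan_to_num(self.one_minus_p, nan=-1.0) >= self.significance_level
            )


def permutation_fwe(
    accuracy_stack: np.ndarray,
    regressor: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    params: TfceParams | None = None,
    n_perms: int = 5000,
    seed: int = 0,
    alternative: str = "greater",
) -> CorrectedPMap:
    """Max-TFCE permutation test of the trait-accuracy association.

    The observed TFCE map is compared with the null distribution of the
    mask-wide maximum TFCE statistic under random re-association of the
    regressor with subjects.  p uses the small-sample convention
    ``(1 + #{null >= observed}) / (1 + n_perms)`` so p is never 0, and the
    returned map holds 1 - p at in-mask voxels (NaN outside).

    ``alternative="greater"`` enhances the positive t tail (the default);
    ``"two-sided"`` enhances ``|t|``.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    x = demean(regressor)  # raises on constant regressor
    Y = np.asarray(accuracy_stack, dtype=float)
    if Y.shape != (x.size, int(mask.sum())):
        raise ValueError(
            f"accuracy stack shape {Y.shape} must be "
            f"(n_subjects={x.size}, n_mask_voxels={int(mask.sum())})"
        )
    if params is None:
        params = TfceParams()

    def enhanced(xvec: np.ndarray) -> np.ndarray:
        t = voxelwise_statistic(Y, xvec)
        if alternative == "two-sided":
            t = np.abs(t)
        vol = np.zeros(mask.shape)
        vol[mask] = t
        return tfce(vol, mask, params)

    obs = enhanced(x)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perms)
    for p in range(n_perms):
        null_max[p] = enhanced(rng.permutation(x)).max()

    obs_in = obs[mask]
    # broadcast count of null maxima at or above each voxel's observed value
    ge = (null_max[None, :] >= obs_in[:, None]).sum(axis=1)
    pvals = (1.0 + ge) / (1.0 + n_perms)
    one_minus_p = np.full(mask.shape, np.nan)
    one_minus_p[mask] = 1.0 - pvals
    n_sig = int((1.0 - pvals >= 0.95).sum())
    logger.info("permutation FWE: %d voxels at 1-p >= 0.95 (%d permutations)", n_sig, n_perms)
    return CorrectedPMap(
        one_minus_p=one_minus_p, mask=mask, affine=affine, null_max=np.sort(null_max)
    )


def conjunction(group_mask: np.ndarray, trait_mask: np.ndarray) -> np.ndarray:
    """Voxel-wise AND of the group-decoding and trait-correlation masks."""
    group_mask = np.asarray(group_mask, dtype=bool)
    trait_mask = np.asarray(trait_mask, dtype=bool)
    if group_mask.shape != trait_mask.shape:
        raise ValueError(
            f"grid mismatch: {group_mask.shape} vs {trait_mask.shape}"
        )
    return group_mask & trait_mask


# ---------------------------------------------------------------------------
# modelling-object surface


class TraitCorrelation:
    """Voxel-wise trait-accuracy correlation model.

    Parameters
    ----------
    accuracy_maps : sequence of AccuracyMap
        One per subject, in trait-table row order, on a shared grid.
    traits : pandas.DataFrame
        Trait table with ``subject_id`` and sub-scale columns.
    subscale : str
        Which sub-scale to use as the regressor (default PT).
    params : TfceParams, optional
    alternative : {"greater", "two-sided"}
    """

    def __init__(
        self,
        accuracy_maps,
        traits: pd.DataFrame,
        subscale: str = "PT",
        params: TfceParams | None = None,
        alternative: str = "greater",
    ):
        maps = list(accuracy_maps)
        if len(maps) != len(traits):
            raise ValueError("one accuracy map per trait-table row required")
        if subscale not in traits.columns:
            raise ValueError(f"trait table has no column {subscale!r}")
        self.mask = maps[0].mask
        self.affine = maps[0].affine
        for m in maps:
            if m.mask.shape != self.mask.shape:
                raise ValueError("accuracy maps must share one grid")
        self.stack = np.vstack([m.values for m in maps])
        self.traits = traits
        self.subscale = subscale
        self.params = params or TfceParams()
        self.alternative = alternative

    def fit(self, n_perms: int = 5000, seed: int = 0) -> "TraitCorrelationResults":
        scores = self.traits[self.subscale].to_numpy(dtype=float)
        x = demean(scores)
        t_in = voxelwise_statistic(self.stack, x)
        stat_map = np.full(self.mask.shape, np.nan)
        stat_map[self.mask] = t_in
        enh_in = t_in if self.alternative == "greater" else np.abs(t_in)
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = enh_in
        tfce_map = tfce(vol, self.mask, self.params)
        pmap = permutation_fwe(
            self.stack,
            scores,
            self.mask,
            affine=self.affine,
            params=self.params,
            n_perms=n_perms,
            seed=seed,
            alternative=self.alternative,
        )
        return TraitCorrelationResults(
            model=self,
            stat_map=stat_map,
            tfce_map=tfce_map,
            corrected=pmap,
            n_perms=n_perms,
            seed=seed,
        )


@dataclass
class TraitCorrelationResults:
    """Fitted trait correlation: t map, TFCE map and corrected 1-p map."""

    model: TraitCorrelation
    stat_map: np.ndarray = field(repr=False)
    tfce_map: np.ndarray = field(repr=False)
    corrected: CorrectedPMap = field(repr=False)
    n_perms: int = 0
    seed: int = 0

    @property
    def significance_mask(self) -> np.ndarray:
        return self.corrected.significance_mask

    def conjunction_with(self, group_mask: np.ndarray) -> np.ndarray:
        """Intersect trait significance with a group-decoding significance mask."""
        return conjunction(group_mask, self.significance_mask)

    def cluster_table(self, significance_mask: np.ndarray | None = None) -> pd.DataFrame:
        """Clusters of significant voxels: size, peak voxel/world coords, peak 1-p."""
        sig = self.significance_mask if significance_mask is None else significance_mask
        labels, n_lab = ndimage.label(sig, structure=CONNECTIVITY_6)
        rows = []
        omp = np.nan_to_num(self.corrected.one_minus_p, nan=-1.0)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            vals = omp[tuple(vox.T)]
            peak = vox[np.argmax(vals)]
            world = (self.model.affine @ np.append(peak, 1.0))[:3]
            rows.append(
                {
                    "cluster": lab,
                    "size": len(vox),
                    "peak_i": int(peak[0]),
                    "peak_j": int(peak[1]),
                    "peak_k": int(peak[2]),
                    "peak_x": world[0],
                    "peak_y": world[1],
                    "peak_z": world[2],
                    "peak_one_minus_p": float(vals.max()),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster", "size", "peak_i", "peak_j", "peak_k",
                "peak_x", "peak_y", "peak_z", "peak_one_minus_p",
            ],
        )

    def summary(self) -> str:
        m = self.model
        sig = self.significance_mask
        in_t = self.stat_map[m.mask]
        lines = [
            "Trait-accuracy correlation results",
            "=" * 40,
            f"sub-scale regressor:   {m.subscale}",
            f"subjects:              {self.model.stack.shape[0]}",
            f"alternative:           {m.alternative}",
            f"TFCE (E, H, steps):    ({m.params.E:g}, {m.params.H:g}, {m.params.n_steps})",
            f"permutations:          {self.n_perms}",
            f"max |t|:               {np.nanmax(np.abs(in_t)):.4f}",
            f"significant voxels:    {int(sig.sum())} (1-p >= {self.corrected.significance_level})",
        ]
        table = self.cluster_table()
        if len(table):
            lines.append("clusters:")
            lines.append(table.to_string(index=False))
        return "\n".join(lines)
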