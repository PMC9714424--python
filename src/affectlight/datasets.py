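"""Core in-memory containers for masked statistic-map stacks and trait tables.

A :class:`PatternDataset` holds one row per (subject, run, condition)
z-statistic map, flattened to the in-mask voxels of a shared 3-D brain mask.
Trait tables are plain :class:`pandas.DataFrame` objects with one row per
subject and the four Interpersonal Reactivity Index sub-scale scores
(PT, FS, EC, PD); :func:`validate_traits` enforces their schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sub-scale columns of the Interpersonal Reactivity Index, in canonical order.
IRI_SUBSCALES = ("PT", "FS", "EC", "PD")

#: Each sub-scale is the sum of 7 items scored 0-4, hence the closed range.
IRI_SCORE_RANGE = (0, 28)


class SchemaError(ValueError):
    """Raised when a dataset or table violates its structural contract."""


@dataclass
class PatternDataset:
    """Stack of masked statistic maps tagged with subject, run and condition.

    Parameters
    ----------
    mask : numpy.ndarray
        Boolean 3-D array; True marks in-analysis voxels.
    affine : numpy.ndarray
        4x4 voxel-to-world transform shared by all maps.
    samples : numpy.ndarray
        ``(n_samples, n_mask_voxels)`` matrix of statistic values (z units).
        Row order matches ``attrs``.
    attrs : pandas.DataFrame
        One row per sample with columns ``subject_id``, ``run_id``,
        ``condition``.
    """

    mask: np.ndarray
    affine: np.ndarray
    samples: np.ndarray
    attrs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        self.attrs = self.attrs.reset_index(drop=True)

    # -- derived views -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (feature count)."""
        return self.samples.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(pd.unique(self.attrs["condition"]))

    @property
    def subjects(self) -> list:
        """Subject identifiers in first-appearance order."""
        return list(pd.unique(self.attrs["subject_id"]))

    def runs_of(self, subject_id) -> list:
        rows = self.attrs[self.attrs["subject_id"] == subject_id]
        return list(pd.unique(rows["run_id"]))

    def canonicalized(self) -> "PatternDataset":
        """Rows re-ordered to (subject, run, condition) canonical order.

        The SVM solver is entitled to break exact ties by sample order, so the
        searchlight engines canonicalize row order first; maps are then
        invariant to how the input stack happened to be arranged.
        """
        order = self.attrs.sort_values(
            ["subject_id", "run_id", "condition"], kind="mergesort"
        ).index.to_numpy()
        return self.subset(order)

    def subset(self, row_idx: np.ndarray) -> "PatternDataset":
        """Row-subset sharing the mask and affine."""
        row_idx = np.asarray(row_idx)
        return PatternDataset(
            mask=self.mask,
            affine=self.affine,
            samples=self.samples[row_idx],
            attrs=self.attrs.iloc[row_idx],
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> "PatternDataset":
        """Check the structural invariants; raise :class:`SchemaError` if broken."""
        if self.mask.ndim != 3 or not self.mask.any():
            raise SchemaError("mask must be 3-D with at least one True voxel")
        if self.affine.shape != (4, 4):
            raise SchemaError("affine must be a 4x4 matrix")
        if self.samples.shape != (len(self.attrs), int(self.mask.sum())):
            raise SchemaError(
                f"samples shape {self.samples.shape} inconsistent with "
                f"{len(self.attrs)} attribute rows x {int(self.mask.sum())} mask voxels"
            )
        if not np.isfinite(self.samples).all():
            raise SchemaError("samples contain non-finite values")
        missing = set(("subject_id", "run_id", "condition")) - set(self.attrs.columns)
        if missing:
            raise SchemaError(f"attrs missing columns: {sorted(missing)}")

        conditions = set(self.attrs["condition"])
        offenders = []
        for (subj, run), block in self.attrs.groupby(
            ["subject_id", "run_id"], sort=False
        ):
            counts = block["condition"].value_counts()
            if set(counts.index) != conditions or (counts != 1).any():
                offenders.append((subj, run))
        if offenders:
            raise SchemaError(
                "each (subject, run) block must contain every condition exactly "
                f"once; offending blocks: {offenders}"
            )
        return self


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait table: unique subjects, all four sub-scales in [0, 28]."""
    required = ("subject_id",) + IRI_SUBSCALES
    missing = set(required) - set(traits.columns)
    if missing:
        raise SchemaError(f"trait table missing columns: {sorted(missing)}")
    if traits["subject_id"].duplicated().any():
        dupes = traits.loc[traits["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"duplicate subject_ids in trait table: {dupes}")
    lo, hi = IRI_SCORE_RANGE
    for col in IRI_SUBSCALES:
        vals = traits[col]
        if ((vals < lo) | (vals > hi)).any():
            raise SchemaError(f"{col} scores outside [{lo}, {hi}]")
    return traits
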