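"""Searchlight decoding: cross-validated linear-SVM accuracy maps.

For every in-mask voxel a linear support vector machine is trained and tested
on the multivoxel patterns inside the sphere centred there, under one of two
cross-validation schemes:

* leave-one-subject-out (group analysis) — each fold trains on all other
  subjects' rows (all runs, all conditions) and tests on the held-out subject;
* leave-one-run-out (within-subject analysis) — folds are a single subject's
  scanning runs.

The mean fold accuracy is written to the sphere's centre voxel.  Multiclass
problems use the one-vs-one reduction with majority vote; vote ties are broken
by summed decision values.  The regularization constant defaults to
``C = 1 / mean ||x||`` over training rows, adapting to the scale of the data;
pass ``C`` explicitly to override.  Inputs are z-statistic maps and are used
as-is, with no per-sphere rescaling.

Internally each sphere precomputes the linear Gram matrix of its samples once
and refits the SVM per fold on kernel slices, which makes the per-voxel loop
cheap without changing the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import PatternDataset
from .neighborhood import SphereNeighborhood, build_neighborhood

logger = logging.getLogger(__name__)

GROUP_RADIUS_DEFAULT = 5.0
SUBJECT_RADIUS_DEFAULT = 3.0


@dataclass
class AccuracyMap:
    """Voxel-wise cross-validated accuracy on the mask grid.

    ``data`` is a 3-D array with accuracies in [0, 1] at evaluated in-mask
    voxels and NaN elsewhere; ``affine`` is copied from the source dataset.
    """

    data: np.ndarray
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)

    @property
    def values(self) -> np.ndarray:
        """In-mask accuracy vector (NaN where a voxel was not evaluated)."""
        return self.data[self.mask]

    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.values))


# ---------------------------------------------------------------------------
# cross-validation folds


def leave_one_subject_out(attrs: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per subject: test = that subject's rows, train = the rest."""
    subjects = pd.unique(attrs["subject_id"])
    folds = []
    for s in subjects:
        test = np.flatnonzero((attrs["subject_id"] == s).to_numpy())
        train = np.flatnonzero((attrs["subject_id"] != s).to_numpy())
        folds.append((train, test))
    return folds


def leave_one_run_out(attrs: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per run (single-subject data): test = that run's rows."""
    runs = pd.unique(attrs["run_id"])
    folds = []
    for r in runs:
        test = np.flatnonzero((attrs["run_id"] == r).to_numpy())
        train = np.flatnonzero((attrs["run_id"] != r).to_numpy())
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# single-sphere classification


def default_C(train_norms: np.ndarray) -> float:
    """Scale-adaptive regularization: reciprocal mean Euclidean row norm."""
    m = float(np.mean(train_norms))
    return 1.0 / m if m > 0 else 1.0


def _predict_from_decision(clf: SVC, kernel_test: np.ndarray) -> np.ndarray:
    df = clf.decision_function(kernel_test)
    if df.ndim == 1:  # binary: positive margin -> second class
        return clf.classes_[(df > 0).astype(int)]
    # one-vs-one votes folded into per-class scores; ties broken by the
    # (bounded) summed decision values baked into sklearn's ovr transform
    return clf.classes_[np.argmax(df, axis=1)]


def _cv_accuracy(
    gram: np.ndarray,
    y: np.ndarray,
    norms: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    C: float | None,
) -> float:
    accs = []
    for train, test in folds:
        y_train = y[train]
        if len(np.unique(y_train)) < len(np.unique(y)):
            logger.warning("fold skipped: a class is absent from training labels")
            continue
        c = C if C is not None else default_C(norms[train])
        clf = SVC(kernel="precomputed", C=c)
        clf.fit(gram[np.ix_(train, train)], y_train)
        pred = _predict_from_decision(clf, gram[np.ix_(test, train)])
        accs.append(float(np.mean(pred == y[test])))
    if not accs:
        raise ValueError("no valid cross-validation fold (classes missing)")
    return float(np.mean(accs))


def train_eval_sphere(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    C: float | None = None,
) -> float:
    """Fit a linear SVM on one sphere's training rows; return test accuracy.

    Raises ``ValueError`` if fewer than two classes are present in training.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("need >= 2 classes in training labels")
    if C is None:
        C = default_C(np.linalg.norm(X_train, axis=1))
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_train, y_train)
    df = clf.decision_function(X_test)
    if df.ndim == 1:
        pred = clf.classes_[(df > 0).astype(int)]
    else:
        pred = clf.classes_[np.argmax(df, axis=1)]
    return float(np.mean(pred == np.asarray(y_test)))


# ---------------------------------------------------------------------------
# searchlight engines


def _searchlight(
    dataset: PatternDataset,
    neighborhood: SphereNeighborhood,
    folds: list[tuple[np.ndarray, np.ndarray]],
    centers: np.ndarray | None = None,
    C: float | None = None,
) -> AccuracyMap:
    y = dataset.attrs["condition"].to_numpy()
    samples = dataset.samples
    out = np.full(dataset.mask.shape, np.nan)
    flat = out[dataset.mask]
    if centers is None:
        centers = np.arange(neighborhood.n_centers)
    for ci in np.asarray(centers):
        idx = neighborhood.members[ci]
        X = samples[:, idx]
        gram = X @ X.T
        norms = np.sqrt(np.clip(np.diag(gram), 0, None))
        flat[ci] = _cv_accuracy(gram, y, norms, folds, C)
    out[dataset.mask] = flat
    n_done = int(np.isfinite(flat).sum())
    logger.info("searchlight: %d centers evaluated over %d folds", n_done, len(folds))
    return AccuracyMap(data=out, mask=dataset.mask, affine=dataset.affine)


def run_group_searchlight(
    dataset: PatternDataset,
    neighborhood: SphereNeighborhood,
    centers: np.ndarray | None = None,
    C: float | None = None,
) -> AccuracyMap:
    """Leave-one-subject-out accuracy map over all subjects' stacked rows."""
    if len(dataset.subjects) < 2:
        raise ValueError("group searchlight needs >= 2 subjects")
    dataset = dataset.canonicalized()
    folds = leave_one_subject_out(dataset.attrs)
    return _searchlight(dataset, neighborhood, folds, centers, C)


def run_subject_searchlight(
    dataset: PatternDataset,
    subject_id,
    neighborhood: SphereNeighborhood,
    centers: np.ndarray | None = None,
    C: float | None = None,
) -> AccuracyMap:
    """Leave-one-run-out accuracy map within a single subject's data."""
    rows = np.flatnonzero((dataset.attrs["subject_id"] == subject_id).to_numpy())
    if rows.size == 0:
        raise ValueError(f"no rows for subject {subject_id!r}")
    sub = dataset.subset(rows).canonicalized()
    if len(pd.unique(sub.attrs["run_id"])) < 2:
        raise ValueError(f"subject {subject_id!r} has < 2 runs")
    folds = leave_one_run_out(sub.attrs)
    return _searchlight(sub, neighborhood, folds, centers, C)


def run_pairwise_searchlight(
    dataset: PatternDataset,
    condition_pair: tuple[str, str],
    neighborhood: SphereNeighborhood,
    centers: np.ndarray | None = None,
    C: float | None = None,
) -> AccuracyMap:
    """Two-way leave-one-subject-out searchlight restricted to a condition pair."""
    a, b = condition_pair
    if a == b:
        raise ValueError("condition pair must be two distinct labels")
    rows = np.flatnonzero(dataset.attrs["condition"].isin([a, b]).to_numpy())
    sub = dataset.subset(rows).canonicalized()
    folds = leave_one_subject_out(sub.attrs)
    return _searchlight(sub, neighborhood, folds, centers, C)


def condition_pairs(conditions) -> list[tuple[str, str]]:
    """All unordered condition pairs (C(k, 2) of them), in listed order."""
    conditions = list(conditions)
    return [
        (conditions[i], conditions[j])
        for i in range(len(conditions))
        for j in range(i + 1, len(conditions))
    ]


# ---------------------------------------------------------------------------
# modelling-object surface


class Searchlight:
    """Searchlight decoding model over a :class:`PatternDataset`.

    Parameters
    ----------
    dataset : PatternDataset
        Stacked statistic maps with subject/run/condition attributes.
    scheme : {"group", "subject", "pairwise"}
        Cross-validation design: leave-one-subject-out over all rows,
        leave-one-run-out within one subject, or a two-condition
        leave-one-subject-out analysis.
    radius : float, optional
        Sphere radius in voxels; defaults to 5 for group/pairwise and 3 for
        within-subject searchlights.
    subject_id : required when ``scheme="subject"``.
    condition_pair : required when ``scheme="pairwise"``.
    C : float, optional
        SVM regularization; default adapts to the training-row norms.
    """

    def __init__(
        self,
        dataset: PatternDataset,
        scheme: str = "group",
        radius: float | None = None,
        subject_id=None,
        condition_pair=None,
        C: float | None = None,
    ):
        if scheme not in ("group", "subject", "pairwise"):
            raise ValueError(f"unknown scheme {scheme!r}")
        if scheme == "subject" and subject_id is None:
            raise ValueError("scheme='subject' requires subject_id")
        if scheme == "pairwise" and condition_pair is None:
            raise ValueError("scheme='pairwise' requires condition_pair")
        if radius is None:
            radius = SUBJECT_RADIUS_DEFAULT if scheme == "subject" else GROUP_RADIUS_DEFAULT
        self.dataset = dataset
        self.scheme = scheme
        self.radius = float(radius)
        self.subject_id = subject_id
        self.condition_pair = condition_pair
        self.C = C

    @property
    def chance_level(self) -> float:
        k = 2 if self.scheme == "pairwise" else len(self.dataset.conditions)
        return 1.0 / k

    def fit(
        self,
        neighborhood: SphereNeighborhood | None = None,
        centers: np.ndarray | None = None,
    ) -> "SearchlightResults":
        """Run the searchlight; returns results carrying the accuracy map."""
        if neighborhood is None:
            neighborhood = build_neighborhood(self.dataset.mask, self.radius)
        if self.scheme == "group":
            amap = run_group_searchlight(self.dataset, neighborhood, centers, self.C)
            n_folds = len(self.dataset.subjects)
        elif self.scheme == "subject":
            amap = run_subject_searchlight(
                self.dataset, self.subject_id, neighborhood, centers, self.C
            )
            n_folds = len(self.dataset.runs_of(self.subject_id))
        else:
            amap = run_pairwise_searchlight(
                self.dataset, self.condition_pair, neighborhood, centers, self.C
            )
            n_folds = len(self.dataset.subjects)
        return SearchlightResults(model=self, accuracy_map=amap, n_folds=n_folds)


@dataclass
class SearchlightResults:
    """Fitted searchlight: the accuracy map plus fold bookkeeping."""

    model: Searchlight
    accuracy_map: AccuracyMap
    n_folds: int

    def mean_accuracy(self) -> float:
        return self.accuracy_map.mean_accuracy()

    def summary(self) -> str:
        m = self.model
        vals = self.accuracy_map.values
        done = np.isfinite(vals)
        lines = [
            "Searchlight decoding results",
            "=" * 40,
            f"scheme:           {m.scheme}",
            f"radius (voxels):  {m.radius:g}",
            f"conditions:       {', '.join(map(str, m.dataset.conditions))}",
            f"chance level:     {m.chance_level:.4f}",
            f"CV folds:         {self.n_folds}",
            f"centers run:      {int(done.sum())} / {vals.size}",
            f"mean accuracy:    {np.nanmean(vals):.4f}",
            f"max accuracy:     {np.nanmax(vals):.4f}",
        ]
        return "\n".join(lines)
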