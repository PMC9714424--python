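"""Synthetic multi-subject volumetric pattern datasets.

Emulates the statistical structure a searchlight decoding analysis assumes:
per-subject, per-run, per-condition z-statistic volumes on a shared mask, with
condition-specific multivoxel patterns embedded in designated ROIs, additive
Gaussian noise, optional spatial smoothing, and a monotone linkage between a
subject's Perspective-Taking score and the amplitude (hence separability) of
that subject's condition patterns.  The trait linkage acts through amplitude
only — pattern geometry is shared across subjects — which is the simplest
mechanism making trait scores predict decodability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datasets import IRI_SUBSCALES, PatternDataset, validate_traits

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian expressed in standard deviations.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_CONDITIONS = ("happy", "sad", "fear", "disgust")


@dataclass
class SignalROI:
    """Spherical region carrying condition-specific signal.

    ``center`` is a voxel-index triple, ``radius`` in voxel units, and
    ``amplitude`` the base signal strength in z units.
    """

    center: tuple[int, int, int]
    radius: float
    amplitude: float = 1.0


@dataclass
class GeneratorConfig:
    """Design of a synthetic decoding experiment.

    Defaults mirror the fixture scale used throughout the test suite: a
    20x20x20 grid of 2 mm isotropic voxels, 12 subjects x 3 runs x 4 affect
    conditions.  ``trait_beta`` is the change in signal amplitude per unit of
    centred PT score; 0 removes the individual-differences linkage.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 2.0
    n_subjects: int = 12
    runs_per_subject: int | dict = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    signal_rois: list[SignalROI] = field(default_factory=list)
    noise_sd: float = 1.0
    smoothing_fwhm: float = 0.0
    trait_beta: float = 0.0
    pattern_seed: int = 0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        self.grid_shape = shape
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.conditions)) < 2:
            raise ValueError("need at least 2 distinct condition labels")
        self.signal_rois = [
            roi if isinstance(roi, SignalROI) else SignalROI(*roi)
            for roi in self.signal_rois
        ]
        for roi in self.signal_rois:
            if any(not (0 <= c < s) for c, s in zip(roi.center, shape)):
                raise ValueError(f"ROI center {roi.center} outside grid {shape}")

    def runs_for(self, subject_index: int) -> int:
        if isinstance(self.runs_per_subject, dict):
            return int(self.runs_per_subject[subject_index])
        return int(self.runs_per_subject)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


def generate_trait_table(n_subjects: int, seed: int) -> pd.DataFrame:
    """Draw a synthetic Interpersonal Reactivity Index table.

    Each sub-scale (PT, FS, EC, PD) is the sum of 7 independent items scored
    uniformly on {0..4}; sub-scales are mutually independent.  Expected score
    is therefore 14 with variance 14 per sub-scale.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = np.random.default_rng(seed)
    table = {"subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)]}
    for scale in IRI_SUBSCALES:
        items = rng.integers(0, 5, size=(n_subjects, 7))
        table[scale] = items.sum(axis=1)
    return validate_traits(pd.DataFrame(table))


def _roi_voxel_indices(roi: SignalROI, mask: np.ndarray) -> np.ndarray:
    """Flat indices (into the in-mask vector) of a spherical ROI."""
    coords = np.argwhere(mask)
    d2 = ((coords - np.asarray(roi.center)) ** 2).sum(axis=1)
    return np.flatnonzero(d2 <= roi.radius**2)


def generate_dataset(
    config: GeneratorConfig,
    traits: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> PatternDataset:
    """Generate a :class:`PatternDataset` from the experimental design.

    Each ROI gets one unit-norm multivoxel template per condition, drawn once
    from ``pattern_seed`` and shared across subjects and runs.  Subject *i*'s
    sample for (run, condition c) is ``amplitude_i * template_c`` plus
    independent Gaussian noise of SD ``noise_sd`` at every in-mask voxel, with
    ``amplitude_i = roi.amplitude + trait_beta * (PT_i - mean(PT))``.  Negative
    amplitudes are clipped to 0 and logged.  Optional Gaussian smoothing is
    applied in-volume after signal and noise are combined.
    """
    validate_traits(traits)
    if mask is None:
        mask = np.ones(config.grid_shape, dtype=bool)
    n_vox = int(mask.sum())

    subject_ids = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    trait_lookup = traits.set_index("subject_id")
    for sid in subject_ids:
        if sid not in trait_lookup.index:
            raise KeyError(f"trait table has no row for subject {sid!r}")
    pt = trait_lookup.loc[subject_ids, "PT"].to_numpy(dtype=float)
    pt_centered = pt - pt.mean()

    # Condition templates: unit-norm over each ROI's voxels, one RNG stream so
    # geometry is reproducible independently of the noise stream.
    pattern_rng = np.random.default_rng(config.pattern_seed)
    templates: list[tuple[np.ndarray, dict[str, np.ndarray], float]] = []
    for roi in config.signal_rois:
        vox = _roi_voxel_indices(roi, mask)
        per_cond = {}
        for cond in config.conditions:
            t = pattern_rng.standard_normal(vox.size)
            t /= np.linalg.norm(t)
            per_cond[cond] = t
        templates.append((vox, per_cond, roi.amplitude))

    noise_rng = np.random.default_rng(config.noise_seed)
    sigma_vox = config.smoothing_fwhm * FWHM_TO_SIGMA / config.voxel_size

    rows = []
    attrs = {"subject_id": [], "run_id": [], "condition": []}
    n_clipped = 0
    for i, sid in enumerate(subject_ids):
        for run in range(1, config.runs_for(i) + 1):
            for cond in config.conditions:
                sample = np.zeros(n_vox)
                for vox, per_cond, base_amp in templates:
                    amp = base_amp + config.trait_beta * pt_centered[i]
                    if amp < 0:
                        n_clipped += 1
                        amp = 0.0
                    sample[vox] += amp * per_cond[cond]
                if config.noise_sd > 0:
                    sample = sample + noise_rng.normal(0.0, config.noise_sd, n_vox)
                if sigma_vox > 0:
                    vol = np.zeros(config.grid_shape)
                    vol[mask] = sample
                    vol = gaussian_filter(vol, sigma_vox)
                    sample = vol[mask]
                rows.append(sample)
                attrs["subject_id"].append(sid)
                attrs["run_id"].append(f"run-{run}")
                attrs["condition"].append(cond)
    if n_clipped:
        logger.warning("clipped %d negative signal amplitudes to 0", n_clipped)

    return PatternDataset(
        mask=mask,
        affine=config.affine,
        samples=np.asarray(rows),
        attrs=pd.DataFrame(attrs),
    ).validate()


def write_fixture(dataset: PatternDataset, traits: pd.DataFrame, out_dir) -> dict:
    """Write a dataset as one NIfTI per map + mask + trait TSV + JSON manifest.

    Returns the manifest dictionary.  The layout round-trips through
    :func:`affectlight.io.load_dataset`.
    """
    # local import: io depends on datasets, not on the generator
    from . import io as alio

    return alio.write_fixture(dataset, traits, out_dir)
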