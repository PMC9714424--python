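import numpy as np
import pytest

import affectlight as al

# Shared planted-linkage design: a single spherical ROI at the grid centre
# carrying condition-specific patterns whose amplitude increases with the
# subject's PT score.  Chosen once for the whole suite (see docs/methods.md).
PLANTED = dict(
    grid_shape=(6, 6, 6),
    roi_center=(3, 3, 3),
    roi_radius=2.0,
    base_amplitude=1.5,
    noise_sd=0.4,
    n_subjects=20,
    runs_per_subject=3,
)


def make_planted(beta: float, seed: int, n_subjects: int | None = None):
    """Generate a planted trait-linkage dataset; returns (traits, dataset, roi)."""
    n = n_subjects or PLANTED["n_subjects"]
    cfg = al.GeneratorConfig(
        grid_shape=PLANTED["grid_shape"],
        n_subjects=n,
        runs_per_subject=PLANTED["runs_per_subject"],
        signal_rois=[
            al.SignalROI(PLANTED["roi_center"], PLANTED["roi_radius"],
                         PLANTED["base_amplitude"])
        ],
        noise_sd=PLANTED["noise_sd"],
        trait_beta=beta,
        pattern_seed=seed,
        noise_seed=seed + 1,
    )
    traits = al.generate_trait_table(n, seed + 2)
    dataset = al.generate_dataset(cfg, traits)
    grid = np.indices(cfg.grid_shape).reshape(3, -1).T
    d2 = ((grid - np.asarray(PLANTED["roi_center"])) ** 2).sum(1)
    roi = (d2 <= PLANTED["roi_radius"] ** 2).reshape(cfg.grid_shape)
    return traits, dataset, roi


def roi_detection_count(beta: float, seed: int, n_perms: int = 300) -> int:
    """ROI voxels reaching FWE significance for the PT regressor."""
    traits, ds, roi = make_planted(beta, seed)
    nbh = al.build_neighborhood(ds.mask, 1)
    maps = [al.run_subject_searchlight(ds, s, nbh) for s in traits["subject_id"]]
    stack = np.vstack([m.values for m in maps])
    pm = al.permutation_fwe(
        stack,
        traits["PT"].to_numpy(float),
        ds.mask,
        params=al.TfceParams(n_steps=50),
        n_perms=n_perms,
        seed=seed + 7,
    )
    return int((pm.significance_mask & roi).sum())


@pytest.fixture(scope="session")
def noise_dataset():
    """12 subjects x 3 runs x 4 conditions of pure noise on an 8^3 grid."""
    cfg = al.GeneratorConfig(
        grid_shape=(8, 8, 8), n_subjects=12, runs_per_subject=3,
        noise_sd=1.0, pattern_seed=0, noise_seed=1,
    )
    traits = al.generate_trait_table(12, 2)
    return al.generate_dataset(cfg, traits)


@pytest.fixture(scope="session")
def tiny_signal_dataset():
    """Zero-noise single-ROI dataset: perfectly separable conditions."""
    cfg = al.GeneratorConfig(
        grid_shape=(5, 5, 5), n_subjects=4, runs_per_subject=2,
        signal_rois=[al.SignalROI((2, 2, 2), 1.5, 2.0)],
        noise_sd=0.0, pattern_seed=3, noise_seed=4,
    )
    traits = al.generate_trait_table(4, 5)
    return al.generate_dataset(cfg, traits)
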