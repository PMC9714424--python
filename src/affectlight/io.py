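"""NIfTI / TSV / JSON input-output and run configuration.

A dataset on disk is: one 3-D NIfTI per (subject, run, condition) statistic
map, one mask NIfTI, a tab-separated trait table, and a JSON manifest listing
``{file, subject_id, run_id, condition}`` per map.  Volumes use NaN as the
out-of-mask marker and are masked on read.  Voxel indices are 0-based
throughout; world coordinates appear only in reports, via the NIfTI affine.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datasets import PatternDataset, SchemaError, validate_traits

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"
MASK_NAME = "mask.nii.gz"
TRAITS_NAME = "traits.tsv"

AFFINE_ATOL = 1e-4


def save_map(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3-D volume as NIfTI-1 (float32, NaN marks out-of-mask)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI; returns (data as float64, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


def read_traits(path) -> pd.DataFrame:
    return validate_traits(pd.read_csv(path, sep="\t"))


def write_traits(traits: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_traits(traits).to_csv(path, sep="\t", index=False)
    return path


def write_fixture(dataset: PatternDataset, traits: pd.DataFrame, out_dir) -> dict:
    """Write a PatternDataset as NIfTI maps + mask + traits + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_map(dataset.mask.astype(np.float32), dataset.affine, out_dir / MASK_NAME)
    write_traits(traits, out_dir / TRAITS_NAME)
    entries = []
    for i, row in dataset.attrs.iterrows():
        vol = np.full(dataset.mask.shape, np.nan)
        vol[dataset.mask] = dataset.samples[i]
        fname = f"{row.subject_id}_{row.run_id}_{row.condition}.nii.gz"
        save_map(vol, dataset.affine, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "subject_id": row.subject_id,
                "run_id": row.run_id,
                "condition": row.condition,
            }
        )
    manifest = {"maps": entries, "mask": MASK_NAME, "traits": TRAITS_NAME}
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    logger.info("wrote fixture: %d maps to %s", len(entries), out_dir)
    return manifest


def load_dataset(manifest_path, mask_path=None) -> PatternDataset:
    """Load a PatternDataset from a JSON manifest and mask volume.

    Every referenced map must exist and share the mask's grid and affine
    (within ``AFFINE_ATOL``); a missing condition in any (subject, run) block
    raises a :class:`SchemaError` listing the offenders.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    if mask_path is None:
        mask_path = root / manifest["mask"]
    mask_data, affine = load_map(mask_path)
    mask = mask_data > 0

    samples, attrs = [], {"subject_id": [], "run_id": [], "condition": []}
    for entry in manifest["maps"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing file: {fpath}")
        data, aff = load_map(fpath)
        if data.shape != mask.shape:
            raise SchemaError(
                f"{fpath.name}: grid {data.shape} does not match mask {mask.shape}"
            )
        if not np.allclose(aff, affine, atol=AFFINE_ATOL):
            raise SchemaError(
                f"{fpath.name}: affine mismatch\nmap affine:\n{aff}\nmask affine:\n{affine}"
            )
        samples.append(np.nan_to_num(data[mask], nan=0.0))
        for key in attrs:
            attrs[key].append(entry[key])
    ds = PatternDataset(
        mask=mask,
        affine=affine,
        samples=np.asarray(samples),
        attrs=pd.DataFrame(attrs),
    )
    return ds.validate()


# ---------------------------------------------------------------------------
# run configuration and provenance


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file as a dictionary."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_provenance(out_path, command: str, parameters: dict, inputs: list) -> Path:
    """Write a JSON sidecar from which the run can be replayed."""
    from . import __version__

    sidecar = Path(str(out_path) + ".provenance.json")
    record = {
        "command": command,
        "parameters": parameters,
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()
        },
        "affectlight_version": __version__,
    }
    sidecar.write_text(json.dumps(record, indent=1, default=str))
    return sidecar
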