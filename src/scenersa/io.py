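"""Readers and writers for the pipeline's on-disk formats.

Corpora are PNG files plus a CSV manifest; voxel datasets are one NIfTI per
subject (conditions stacked on the 4th axis, 2 mm isotropic affine) with a
JSON parameter sidecar; card sorts are long-format CSV; label masks are
single-channel PNG with a JSON label-index map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .neural_patterns import BetaMaps
from .semantic_model import UNLABELLED, LabelMask
from .synthetic_data import SyntheticCardSortSet, SyntheticCorpus

#: MNI-like 2 mm isotropic affine (RAS, origin at volume center offset 0).
def default_affine(voxel_mm: float = 2.0) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    return affine


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(corpus.images, corpus.group_labels)):
        name = f"image_{i:05d}.png"
        PILImage.fromarray((img * 255).astype(np.uint8)).save(outdir / name)
        rows.append({"filename": name, "group_label": int(label)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(outdir / "params.json", "w") as fh:
        json.dump(corpus.params, fh, indent=2)
    return manifest


def read_corpus(outdir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    images = np.stack([
        np.asarray(PILImage.open(outdir / name), dtype=float) / 255.0
        for name in manifest["filename"]
    ])
    return images, manifest["group_label"].to_numpy()


def write_beta_maps(betas: BetaMaps, path: str | Path,
                    params: dict | None = None) -> Path:
    """One NIfTI per subject: conditions along the 4th axis."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(betas.data, 0, -1)  # (x, y, z, conditions)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), betas.affine), str(path))
    if params is not None:
        with open(path.with_suffix("").with_suffix(".json"), "w") as fh:
            json.dump(params, fh, indent=2)
    return path


def read_beta_maps(path: str | Path) -> BetaMaps:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    return BetaMaps(data, affine=img.affine)


def write_cardsorts(sorts: SyntheticCardSortSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject, assignment in enumerate(sorts.sorts):
        for card, stack in enumerate(assignment):
            rows.append({"subject": subject, "card_id": card,
                         "cluster": int(sorts.card_clusters[card]),
                         "stack": int(stack)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cardsorts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Single-channel PNG (index + 1; 0 = unlabelled) + JSON label map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    shifted = np.where(mask.labels == UNLABELLED, 0, mask.labels + 1).astype(np.uint8)
    PILImage.fromarray(shifted, mode="L").save(path)
    label_map = {str(i + 1): label for i, label in enumerate(mask.vocabulary)}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(label_map, fh, indent=2)
    return path


def read_label_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    shifted = np.asarray(PILImage.open(path), dtype=int)
    with open(path.with_suffix(".json")) as fh:
        label_map = json.load(fh)
    vocabulary = tuple(label_map[str(i + 1)] for i in range(len(label_map)))
    labels = np.where(shifted == 0, UNLABELLED, shifted - 1)
    return LabelMask(labels, vocabulary=vocabulary)


def write_pmap(volume: np.ndarray, affine: np.ndarray, path: str | Path,
               evaluated: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume.astype(np.float32), affine), str(path))
    if evaluated is not None:
        mask_path = path.with_name(path.stem.split(".")[0] + "_evaluated.nii")
        nib.save(nib.Nifti1Image(evaluated.astype(np.uint8), affine), str(mask_path))
    return path


def write_matrix_json(matrix: np.ndarray, path: str | Path,
                      meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"matrix": np.asarray(matrix).tolist()}
    if meta:
        payload.update(meta)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
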