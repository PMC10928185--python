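"""Synthetic inputs and dataset accounting.

Two generators exercise the full pipeline without any external data:

* :func:`make_feature_dataset` draws class-conditional Gaussian feature
  matrices with planted informative, redundant (noisy linear combinations
  of informative), and pure-noise columns — the structure a wrapper
  feature selector is supposed to disentangle.
* :func:`make_modality_images` draws four image classes on an elliptical
  brain-like mask, distinguished by band-limited texture frequency,
  orientation, and mean intensity, so a small CNN can exceed chance.

:func:`plan_slice_selection` encodes the axial-slice accounting rule used
when 2-D slices are taken from multi-modality MRI volumes (e.g. slices
40–114 of a 155-slice volume for every patient and modality).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "LabelVector",
    "ImageDataset",
    "SliceCounts",
    "make_feature_dataset",
    "make_modality_images",
    "plan_slice_selection",
    "save_features",
    "load_features",
    "save_image_dataset",
    "load_image_dataset",
    "convert_nifti_volumes",
]

MODALITY_NAMES = ("flair", "t1", "t1ce", "t2")


@dataclass
class FeatureMatrix:
    """n_samples x n_features matrix of deep-feature activations."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be non-empty")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVector:
    """Integer class codes 0..K-1 with class names."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        k = len(self.class_names)
        if self.labels.min(initial=0) < 0 or (k and self.labels.max(initial=0) >= k):
            raise ValueError("label codes out of range")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ImageDataset:
    """Stack of H x W x C images in [0, 1] plus labels and provenance."""

    images: np.ndarray
    labels: LabelVector
    metadata: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


@dataclass
class SliceCounts:
    per_class: int
    total: int
    slice_range: tuple[int, int]


def plan_slice_selection(n_patients: int, slice_lo: int, slice_hi: int,
                         n_modalities: int = 4) -> SliceCounts:
    """Per-class and total image counts for an axial slice-range selection.

    Each patient contributes slices ``slice_lo..slice_hi`` (inclusive,
    1-based) for every modality; each modality is one class.
    """
    if n_patients < 1 or n_modalities < 1:
        raise ValueError("n_patients and n_modalities must be positive")
    if not 1 <= slice_lo <= slice_hi:
        raise ValueError("need 1 <= slice_lo <= slice_hi")
    per_class = n_patients * (slice_hi - slice_lo + 1)
    return SliceCounts(per_class=per_class, total=per_class * n_modalities,
                       slice_range=(slice_lo, slice_hi))


# --------------------------------------------------------------------- #
# feature-matrix generator


def make_feature_dataset(n_samples: int = 200, n_classes: int = 4,
                         n_informative: int = 5, n_redundant: int = 5,
                         n_noise: int = 40, class_sep: float = 3.0,
                         seed: int = 0) -> tuple[FeatureMatrix, LabelVector]:
    """Class-conditional Gaussian features with planted column structure.

    Informative columns: unit-variance Gaussians around per-class means
    whose root-mean-square pairwise distance equals ``class_sep``.
    Redundant columns: random linear combinations of the informative
    block plus noise (sd 0.3), so they carry signal but strictly less
    than the originals. Noise columns: class-independent standard
    Gaussians. Column names are tagged ``inf_*`` / ``red_*`` / ``noise_*``.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative feature")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if n_redundant < 0 or n_noise < 0:
        raise ValueError("column counts must be non-negative")
    if n_samples < 2 * n_classes:
        raise ValueError("n_samples too small for stratified classes")

    rng = np.random.default_rng(seed)

    # balanced labels in a shuffled order
    base = np.arange(n_samples) % n_classes
    labels = rng.permutation(base)

    # class means on a regular simplex: every pair of classes is exactly
    # class_sep apart (falls back to a scaled random layout when the
    # informative dimension cannot hold a K-simplex)
    if class_sep > 0 and n_informative >= n_classes - 1:
        verts = np.eye(n_classes)
        verts -= verts.mean(axis=0)
        verts /= np.linalg.norm(verts[0] - verts[1])    # unit edge length
        basis = np.linalg.svd(verts, full_matrices=False)[2][:n_classes - 1]
        means = np.zeros((n_classes, n_informative))
        means[:, :n_classes - 1] = class_sep * (verts @ basis.T)
        # random rotation spreads the separation over all informative axes
        q, _ = np.linalg.qr(rng.normal(size=(n_informative, n_informative)))
        means = means @ q
    elif class_sep > 0:
        means = rng.normal(size=(n_classes, n_informative))
        means -= means.mean(axis=0)
        d2 = ((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=-1)
        rms = np.sqrt(d2[np.triu_indices(n_classes, 1)].mean())
        if rms > 0:
            means *= class_sep / rms
    else:
        means = np.zeros((n_classes, n_informative))

    informative = means[labels] + rng.normal(size=(n_samples, n_informative))
    blocks = [informative]
    names = [f"inf_{i}" for i in range(n_informative)]
    if n_redundant:
        mix = rng.normal(size=(n_informative, n_redundant))
        mix /= np.linalg.norm(mix, axis=0, keepdims=True)
        redundant = informative @ mix + rng.normal(
            size=(n_samples, n_redundant))
        blocks.append(redundant)
        names += [f"red_{i}" for i in range(n_redundant)]
    if n_noise:
        blocks.append(rng.normal(size=(n_samples, n_noise)))
        names += [f"noise_{i}" for i in range(n_noise)]

    values = np.concatenate(blocks, axis=1)
    fm = FeatureMatrix(values=values, feature_names=names)
    lv = LabelVector(labels=labels,
                     class_names=[f"class_{k}" for k in range(n_classes)])
    return fm, lv


# --------------------------------------------------------------------- #
# modality-image generator

# per-class texture signature: (cycles across image, orientation rad,
# base intensity, blob gain)
_CLASS_SIGNATURES = [
    (3.0, 0.0, 0.35, 0.9),
    (7.0, np.pi / 4, 0.55, 0.4),
    (12.0, np.pi / 2, 0.45, 0.7),
    (18.0, 3 * np.pi / 4, 0.65, 0.2),
]


def brain_mask(height: int, width: int) -> np.ndarray:
    """Elliptical "brain" support mask used by the image generator."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    ry, rx = 0.42 * height, 0.38 * width
    return (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0


def make_modality_images(n_per_class: int = 50, height: int = 64,
                         width: int = 64, seed: int = 0) -> ImageDataset:
    """Four image classes with distinct frequency/intensity signatures.

    Each image is an elliptical mask carrying a class-specific oriented
    grating and a random bright blob, plus pixel noise; background is
    near zero. Classes are interleaved so the stack is balanced.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    if height < 16 or width < 16:
        raise ValueError("images must be at least 16x16")
    rng = np.random.default_rng(seed)
    mask = brain_mask(height, width)
    yy, xx = np.mgrid[0:height, 0:width]
    images, labels, meta = [], [], []
    for idx in range(n_per_class):
        for cls, (freq, theta, level, blob_gain) in enumerate(_CLASS_SIGNATURES):
            phase = rng.uniform(0, 2 * np.pi)
            u = (xx * np.cos(theta) + yy * np.sin(theta)) / width
            tex = 0.5 + 0.5 * np.sin(2 * np.pi * freq * u + phase)
            by = rng.uniform(0.3, 0.7) * height
            bx = rng.uniform(0.3, 0.7) * width
            sig = 0.08 * min(height, width)
            blob = np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2)
                            / (2 * sig ** 2)))
            img = level * (0.6 + 0.4 * tex) + blob_gain * blob
            img += 0.03 * rng.normal(size=(height, width))
            img = np.where(mask, img, 0.02 * np.abs(
                rng.normal(size=(height, width))))
            images.append(np.clip(img, 0, 1)[..., None])
            labels.append(cls)
            meta.append({"class": MODALITY_NAMES[cls], "seed": int(seed),
                         "index": idx})
    lv = LabelVector(labels=np.array(labels), class_names=list(MODALITY_NAMES))
    return ImageDataset(images=np.stack(images), labels=lv, metadata=meta)


# --------------------------------------------------------------------- #
# serialisation


def save_features(fm: FeatureMatrix, lv: LabelVector, path) -> None:
    """Write features + labels as CSV (header row, final column 'label')."""
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df["label"] = lv.labels
    df.to_csv(path, index=False)


def load_features(path) -> tuple[FeatureMatrix, LabelVector]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature table must contain a 'label' column")
    labels = df.pop("label").to_numpy(dtype=int)
    k = int(labels.max()) + 1
    fm = FeatureMatrix(values=df.to_numpy(dtype=float),
                       feature_names=list(df.columns))
    lv = LabelVector(labels=labels,
                     class_names=[f"class_{i}" for i in range(k)])
    return fm, lv


def save_image_dataset(ds: ImageDataset, root) -> None:
    """Write per-class PNG directories plus a JSON manifest."""
    from PIL import Image

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"class_names": ds.labels.class_names, "files": []}
    counters = {}
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels.labels)):
        cname = ds.labels.class_names[lab]
        cdir = root / cname
        cdir.mkdir(exist_ok=True)
        j = counters.get(cname, 0)
        counters[cname] = j + 1
        fname = f"{cname}/{j:05d}.png"
        arr = (np.clip(img[..., 0], 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(root / fname)
        meta = ds.metadata[i] if i < len(ds.metadata) else {}
        manifest["files"].append({"path": fname, "label": int(lab), **meta})
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_image_dataset(root) -> ImageDataset:
    from PIL import Image

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    images, labels, meta = [], [], []
    for entry in manifest["files"]:
        arr = np.asarray(Image.open(root / entry["path"]), dtype=float) / 255.0
        images.append(arr[..., None])
        labels.append(entry["label"])
        meta.append({k: v for k, v in entry.items()
                     if k not in ("path", "label")})
    lv = LabelVector(labels=np.array(labels),
                     class_names=manifest["class_names"])
    return ImageDataset(images=np.stack(images), labels=lv, metadata=meta)


def convert_nifti_volumes(volumes: dict[str, list], out_root,
                          slice_lo: int = 40, slice_hi: int = 114) -> SliceCounts:
    """Adapter for real multi-modality NIfTI volumes.

    ``volumes`` maps a modality/class name to a list of NIfTI file paths.
    Axial slices ``slice_lo..slice_hi`` (1-based) are extracted from each
    volume, min–max scaled per slice, and written in the PNG layout of
    :func:`save_image_dataset`. Never exercised by the test suite; it
    exists for users with local data.
    """
    import nibabel as nib
    from PIL import Image

    out_root = Path(out_root)
    class_names = list(volumes)
    manifest = {"class_names": class_names, "files": []}
    n_patients = None
    for lab, cname in enumerate(class_names):
        paths = volumes[cname]
        n_patients = len(paths) if n_patients is None else n_patients
        cdir = out_root / cname
        cdir.mkdir(parents=True, exist_ok=True)
        j = 0
        for vol_path in paths:
            data = np.asanyarray(nib.load(str(vol_path)).dataobj)
            for s in range(slice_lo - 1, slice_hi):
                sl = data[:, :, s].astype(float)
                lo, hi = sl.min(), sl.max()
                sl = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
                fname = f"{cname}/{j:05d}.png"
                Image.fromarray((sl * 255).astype(np.uint8)).save(
                    out_root / fname)
                manifest["files"].append({"path": fname, "label": lab,
                                          "source": str(vol_path),
                                          "slice": s + 1})
                j += 1
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return plan_slice_selection(n_patients or 1, slice_lo, slice_hi,
                                len(class_names))
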