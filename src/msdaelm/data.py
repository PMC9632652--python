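"""In-memory containers for labeled multi-domain data and their on-disk formats.

A *domain* is one cohort of samples (one hospital's CT series, one slide
archive, one synthetic condition).  Feature-space domains are held in
:class:`LabeledFeatureSet`; image-space domains in :class:`LabeledImageSet`.

On disk, feature sets are delimited tables: a header row of feature names
plus a final ``label`` column.  Image sets are a directory of PNG files with
a manifest table carrying ``path``, ``label`` and ``domain`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "LabeledFeatureSet",
    "LabeledImageSet",
    "read_feature_table",
    "write_feature_table",
    "read_feature_npz",
    "write_feature_npz",
    "read_image_manifest",
    "write_image_domain",
]


@dataclass
class LabeledFeatureSet:
    """One domain's samples: feature matrix, optional binary labels, domain tag.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix; all entries must be finite.
    labels : ndarray of shape (n_samples,) or None
        Class indices in {0, 1}; may be absent for unlabeled use.
    domain_id : str
        Free-form tag naming the domain ("S1", "target", a filename stem...).
    feature_names : list of str, optional
        Column names; defaults to ``f0..f{p-1}``.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    domain_id: str = "domain"
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise InputError("features must be a 2-D matrix (n_samples, n_features)")
        if self.features.shape[0] < 1:
            raise InputError(f"domain {self.domain_id!r}: at least one sample required")
        if not np.all(np.isfinite(self.features)):
            raise InputError(f"domain {self.domain_id!r}: non-finite feature values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.features.shape[0],):
                raise InputError(
                    f"domain {self.domain_id!r}: labels length "
                    f"{self.labels.shape} does not match n_samples "
                    f"{self.features.shape[0]}"
                )
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise InputError("feature_names length does not match n_features")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct class indices (empty array when unlabeled)."""
        if self.labels is None:
            return np.array([], dtype=int)
        return np.unique(self.labels)

    def class_subset(self, label: int) -> "LabeledFeatureSet":
        """Samples of one class, as a new set tagged ``<domain>[l=<label>]``."""
        if self.labels is None:
            raise InputError(f"domain {self.domain_id!r} carries no labels")
        mask = self.labels == label
        if not mask.any():
            raise InputError(f"domain {self.domain_id!r} has no class-{label} samples")
        return LabeledFeatureSet(
            self.features[mask],
            self.labels[mask],
            domain_id=f"{self.domain_id}[l={label}]",
            feature_names=list(self.feature_names),
        )

    def with_labels(self, labels: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            self.features, labels, self.domain_id, list(self.feature_names)
        )


@dataclass
class LabeledImageSet:
    """One domain's images: stack of single-channel images plus labels.

    ``images`` has shape (n, channels, height, width) with values in [0, 1].
    """

    images: np.ndarray
    labels: np.ndarray
    domain_id: str = "domain"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise InputError("images must have shape (n, channels, height, width)")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.images.shape[0],):
            raise InputError("labels length does not match number of images")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# Feature-table I/O


def write_feature_table(fs: LabeledFeatureSet, path: str | Path, sep: str = ",") -> None:
    """Write a feature set as a delimited table (features + final label column)."""
    df = pd.DataFrame(fs.features, columns=fs.feature_names)
    if fs.labels is not None:
        df["label"] = fs.labels
    df.to_csv(path, sep=sep, index=False)


def read_feature_table(
    path: str | Path, domain_id: str | None = None, sep: str = ","
) -> LabeledFeatureSet:
    """Read a delimited feature table.

    The final ``label`` column, when present, becomes the label vector;
    ``domain_id`` defaults to the filename stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return LabeledFeatureSet(
        df.to_numpy(dtype=float),
        labels,
        domain_id=domain_id or path.stem,
        feature_names=list(df.columns),
    )


def write_feature_npz(fs: LabeledFeatureSet, path: str | Path) -> None:
    """Write a feature set as a dense-matrix + label-vector archive."""
    payload = {"features": fs.features,
               "feature_names": np.array(fs.feature_names)}
    if fs.labels is not None:
        payload["labels"] = fs.labels
    np.savez(path, **payload)


def read_feature_npz(path: str | Path, domain_id: str | None = None) -> LabeledFeatureSet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        return LabeledFeatureSet(
            z["features"],
            z["labels"] if "labels" in z else None,
            domain_id=domain_id or path.stem,
            feature_names=[str(n) for n in z["feature_names"]],
        )


# ---------------------------------------------------------------------------
# Image-domain I/O (PNG directory + manifest)


def write_image_domain(iset: LabeledImageSet, out_dir: str | Path) -> Path:
    """Write an image set as 8-bit grayscale PNGs plus a ``manifest.csv``.

    Returns the manifest path.  Requires pillow via imageio only when called;
    image domains used in tests are normally kept in memory.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(iset.n_samples):
        img = np.clip(iset.images[i, 0], 0.0, 1.0)
        arr = np.round(img * 255).astype(np.uint8)
        name = f"{iset.domain_id}_{i:05d}.png"
        Image.fromarray(arr, mode="L").save(out_dir / name)
        rows.append({"path": name, "label": int(iset.labels[i]), "domain": iset.domain_id})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_image_manifest(manifest_path: str | Path) -> LabeledImageSet:
    """Load an image domain from a manifest table (path, label, domain)."""
    from PIL import Image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    imgs = []
    for p in df["path"]:
        arr = np.asarray(Image.open(base / p).convert("L"), dtype=float) / 255.0
        imgs.append(arr[None, :, :])
    domain = str(df["domain"].iloc[0]) if len(df) else manifest_path.parent.name
    return LabeledImageSet(np.stack(imgs), df["label"].to_numpy(), domain_id=domain)
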