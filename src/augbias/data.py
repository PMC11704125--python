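"""In-memory image dataset container and on-disk formats.

Datasets persist either as a directory of PNG files plus a ``labels.csv``
sidecar (columns ``filename,label,aux_label``) or as a packed ``.npz`` archive
for fast programmatic round trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["ImageDataset"]


@dataclass
class ImageDataset:
    """Images (N, H, W, C) in [0, 1] with per-image labels.

    ``labels`` is the primary condition/class label; ``aux_labels`` an optional
    secondary factor (phenotype id, style id, superclass id). ``meta`` records
    provenance (generator name, config fields, seed).
    """

    images: np.ndarray
    labels: np.ndarray
    aux_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim == 3:
            self.images = self.images[..., None]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.images.size and (self.images.min() < -1e-9 or self.images.max() > 1 + 1e-9):
            raise ValueError("image intensities must lie in [0, 1]")
        if self.aux_labels is not None:
            self.aux_labels = np.asarray(self.aux_labels, dtype=int)
            if len(self.aux_labels) != len(self.labels):
                raise ValueError("aux_labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_channels(self) -> int:
        return self.images.shape[3]

    def subset(self, idx) -> "ImageDataset":
        aux = None if self.aux_labels is None else self.aux_labels[idx]
        return ImageDataset(self.images[idx], self.labels[idx], aux, dict(self.meta))

    def as_nchw(self, dtype=np.float32) -> np.ndarray:
        """(N, C, H, W) array for the encoders."""
        return np.ascontiguousarray(self.images.transpose(0, 3, 1, 2).astype(dtype))

    # -- persistence ---------------------------------------------------------
    def save_png_dir(self, path: str):
        os.makedirs(path, exist_ok=True)
        rows = []
        for i, img in enumerate(self.images):
            arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
            arr = arr[..., 0] if arr.shape[2] == 1 else arr
            fname = f"img_{i:06d}.png"
            Image.fromarray(arr).save(os.path.join(path, fname))
            rows.append({
                "filename": fname,
                "label": int(self.labels[i]),
                "aux_label": int(self.aux_labels[i]) if self.aux_labels is not None else -1,
            })
        pd.DataFrame(rows).to_csv(os.path.join(path, "labels.csv"), index=False)

    @classmethod
    def load_png_dir(cls, path: str) -> "ImageDataset":
        table = pd.read_csv(os.path.join(path, "labels.csv"))
        images = []
        for fname in table["filename"]:
            arr = np.asarray(Image.open(os.path.join(path, fname)), dtype=np.float64) / 255.0
            images.append(arr)
        images = np.stack(images)
        aux = table["aux_label"].to_numpy()
        aux_labels = None if (aux < 0).all() else aux
        return cls(images, table["label"].to_numpy(), aux_labels, {"source": path})

    def save_npz(self, path: str):
        aux = self.aux_labels if self.aux_labels is not None else np.full(len(self), -1)
        np.savez_compressed(path, images=self.images.astype(np.float32),
                            labels=self.labels, aux_labels=aux)

    @classmethod
    def load_npz(cls, path: str) -> "ImageDataset":
        with np.load(path) as z:
            aux = z["aux_labels"]
            aux_labels = None if (aux < 0).all() else aux
            return cls(z["images"].astype(np.float64), z["labels"], aux_labels,
                       {"source": path})
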