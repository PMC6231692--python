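"""Activation matrices: pixel features, imports, and the differential-unit filter.

An :class:`ActivationMatrix` is the common container for every response source
compared in this package — neural firing rates, surrogate layer activations,
raw pixel graylevels, or matrices imported from an external feature extractor
(e.g. the 256 C2 outputs of an HMAX implementation). Rows are units, columns
are stimuli, and the column order is tied to a shape-set manifest through
``stimulus_ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from skimage.transform import resize


@dataclass
class ActivationMatrix:
    """unit x stimulus response matrix with provenance tag."""

    values: np.ndarray
    stimulus_ids: list[str]
    source_tag: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D unit x stimulus matrix")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one unit")
        if self.values.shape[1] != len(self.stimulus_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.stimulus_ids)} stimulus ids"
            )
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at unit {bad[0]}, stimulus {bad[1]}")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


def pixel_features(images: Sequence, stimulus_ids: Sequence[str] | None = None) -> ActivationMatrix:
    """One unit per pixel: the graylevel feature matrix of a rendered shape set.

    Rows follow row-major pixel order, so distances between columns equal
    image-space graylevel distances.
    """
    arrays = [np.asarray(getattr(im, "pixels", im), dtype=float) for im in images]
    shape0 = arrays[0].shape
    for k, a in enumerate(arrays):
        if a.shape != shape0:
            raise ValueError(f"image {k} has shape {a.shape}, expected {shape0}")
    values = np.stack([a.ravel(order="C") for a in arrays], axis=1)
    if stimulus_ids is None:
        stimulus_ids = [f"s{k:02d}" for k in range(len(arrays))]
    return ActivationMatrix(values, list(stimulus_ids), source_tag="pixels")


def preprocess_for_adapter(image, input_size: int, mean_image=0.0) -> np.ndarray:
    """Resize to an external extractor's input size, then subtract its mean image.

    The resize is nearest-neighbour so a binary stimulus stays two-level except
    at foreground/background boundary pixels; the output may be negative after
    mean subtraction.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    out = resize(
        pixels, (input_size, input_size), order=0, preserve_range=True,
        anti_aliasing=False,
    )
    return out - np.asarray(mean_image, dtype=float)


def save_activation_matrix(matrix: ActivationMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("activations", data=matrix.values)
            ds.attrs["stimulus_ids"] = [s.encode() for s in matrix.stimulus_ids]
            ds.attrs["source_tag"] = matrix.source_tag
    elif fmt == "csv":
        df = pd.DataFrame(
            matrix.values,
            index=[f"u{k}" for k in range(matrix.n_units)],
            columns=matrix.stimulus_ids,
        )
        df.index.name = "unit"
        df.to_csv(path, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_activation_matrix(path, format: str | None = None) -> ActivationMatrix:
    """Read a unit x stimulus matrix written by :func:`save_activation_matrix`
    or by an external extractor following the same layout.

    HDF5 round-trips bit-exactly; CSV to 12 significant digits.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            ds = f["activations"]
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in ds.attrs["stimulus_ids"]]
            tag = ds.attrs.get("source_tag", "imported")
            tag = tag.decode() if isinstance(tag, bytes) else str(tag)
            return ActivationMatrix(ds[()], ids, source_tag=tag)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"NaN cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    return ActivationMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns],
                            source_tag="imported")


def filter_differential_units(matrix: ActivationMatrix) -> ActivationMatrix:
    """Keep units whose activation standard deviation across stimuli is > 0.

    Constant units carry no stimulus information and contribute nothing to a
    Euclidean distance (and break rank correlations), so they are removed
    before distance-based analyses. Exact comparison to zero, in double
    precision. Idempotent.
    """
    sd = matrix.values.std(axis=1)
    keep = sd > 0.0
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("no differential units: all rows constant across stimuli")
    if n_keep == matrix.n_units:
        return matrix
    return ActivationMatrix(matrix.values[keep], list(matrix.stimulus_ids),
                            source_tag=matrix.source_tag)
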