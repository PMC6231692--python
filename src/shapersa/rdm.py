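"""Representational dissimilarity matrices (RDMs) and the two dissimilarity metrics.

Two metrics are supported, matching standard practice in representational
similarity analysis of neural populations:

* ``normalized_euclidean`` — sqrt(sum_i (R_i1 - R_i2)^2 / n) over the n units of
  a source (neurons, model units, or pixels). Normalizing by the unit count
  makes distances comparable across sources of different size.
* ``one_minus_spearman`` — 1 minus the Spearman rank correlation between the
  two stimuli's response vectors across units (average ranks for ties), giving
  a dissimilarity in [0, 2].

An RDM is symmetric with a zero diagonal; second-order analyses operate on its
upper triangle in a fixed row-major order (i < j, sorted by i then j).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .features import ActivationMatrix

METRICS = ("normalized_euclidean", "one_minus_spearman")


@dataclass
class RDM:
    """Symmetric stimulus x stimulus dissimilarity matrix tagged by metric."""

    values: np.ndarray
    metric: str
    stimulus_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        s = self.values.shape
        if len(s) != 2 or s[0] != s[1]:
            raise ValueError("RDM must be square")
        if s[0] != len(self.stimulus_ids):
            raise ValueError("stimulus_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if self.metric == "normalized_euclidean" and np.any(self.values < -1e-12):
            raise ValueError("normalized Euclidean RDM must be non-negative")
        if self.metric == "one_minus_spearman" and (
            np.any(self.values < -1e-9) or np.any(self.values > 2 + 1e-9)
        ):
            raise ValueError("1 - Spearman RDM must lie in [0, 2]")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]


def normalized_euclidean(x, y) -> float:
    """sqrt of the mean squared response difference across units."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size == 0:
        raise ValueError("empty response vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def spearman_dissimilarity(x, y) -> float:
    """1 - Spearman rho between two response vectors (average ranks for ties).

    Raises on a constant vector, where rho is undefined; pre-filter with
    :func:`shapersa.features.filter_differential_units`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be 1-D vectors of equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman dissimilarity undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(1.0 - rho)


def compute_rdm(matrix: ActivationMatrix, metric: str = "normalized_euclidean") -> RDM:
    """All pairwise dissimilarities between stimulus columns of an activation matrix."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    v = matrix.values
    n_units, n_stim = v.shape
    if n_stim < 2:
        raise ValueError("need at least 2 stimuli")
    if metric == "normalized_euclidean":
        d = squareform(pdist(v.T, metric="euclidean") / np.sqrt(n_units))
    else:
        if n_units < 2:
            raise ValueError("1 - Spearman needs at least 2 units")
        const = np.ptp(v, axis=0) == 0
        if const.any():
            j = int(np.argmax(const))
            raise ValueError(
                f"stimulus {matrix.stimulus_ids[j]!r} has a constant response vector; "
                "1 - Spearman is undefined (filter differential units first)"
            )
        ranks = rankdata(v, axis=0)
        rho = np.corrcoef(ranks.T)
        d = 1.0 - rho
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    return RDM(d, metric, list(matrix.stimulus_ids))


def upper_triangle(rdm: RDM | np.ndarray) -> np.ndarray:
    """Vector of the s(s-1)/2 above-diagonal entries, row-major (i<j by i then j)."""
    v = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def from_upper_triangle(vec, metric: str, stimulus_ids) -> RDM:
    """Inverse of :func:`upper_triangle`: symmetrize a condensed vector into an RDM."""
    return RDM(squareform(np.asarray(vec, dtype=float)), metric, list(stimulus_ids))


def percentile_normalize(rdm: RDM) -> RDM:
    """Replace each off-diagonal entry by its percentile rank among all of them.

    Display convention for heat-mapped RDMs: average ranks x 100 / count so the
    scale is comparable across sources. Never used for statistics.
    """
    ut = upper_triangle(rdm)
    pct = rankdata(ut) * (100.0 / ut.size)
    out = from_upper_triangle(pct, rdm.metric, rdm.stimulus_ids)
    out.metric = rdm.metric
    return out


def save_rdm(rdm: RDM, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("rdm", data=rdm.values)
            ds.attrs["stimulus_ids"] = [s.encode() for s in rdm.stimulus_ids]
            ds.attrs["metric"] = rdm.metric
    else:
        df = pd.DataFrame(rdm.values, index=rdm.stimulus_ids, columns=rdm.stimulus_ids)
        df.index.name = rdm.metric
        df.to_csv(path, float_format="%.12g")


def load_rdm(path, format: str | None = None) -> RDM:
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            ds = f["rdm"]
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in ds.attrs["stimulus_ids"]]
            metric = ds.attrs["metric"]
            metric = metric.decode() if isinstance(metric, bytes) else str(metric)
            return RDM(ds[()], metric, ids)
    df = pd.read_csv(path, index_col=0)
    metric = df.index.name if df.index.name in METRICS else "normalized_euclidean"
    return RDM(df.to_numpy(dtype=float), metric, [str(c) for c in df.columns])
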