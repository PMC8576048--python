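"""ROI time series -> Pearson connectivity matrices -> network feature vectors.

Mirrors the resting-state preprocessing that is done at the ROI level:
discarding the initial volumes acquired before magnetization equilibrium,
band-pass filtering to the 0.01-0.1 Hz band where resting-state BOLD
fluctuations live (cardiac ~1.3 Hz and respiratory ~0.2 Hz signals fall
outside it), and Pearson correlation between every pair of ROI signals.
Voxel-level steps (slice timing, motion correction, normalization) are out
of scope: inputs are already ROI-level series or precomputed matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import Edge, Network, NetworkPartition

__all__ = [
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "FeatureMatrix",
    "discard_initial_volumes",
    "bandpass_filter",
    "compute_fc",
    "vectorize",
    "build_feature_matrix",
    "fisher_z",
    "read_fc",
    "write_fc",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class TimeSeriesPanel:
    """One subject's ROI time series: ``values`` is T x R (time x ROI)."""

    subject_id: str
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be a 2-D (time x ROI) array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson FC matrix with unit diagonal, entries in [-1, 1]."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("connectivity matrix diagonal must be 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("connectivity entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    """N subjects x d edges of one network, columns in canonical edge order."""

    network: Network
    subjects: tuple[str, ...]
    edge_index: tuple[Edge, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subjects), len(self.edge_index)):
            raise ValueError(
                f"feature matrix shape {v.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.edge_index)} edges"
            )
        object.__setattr__(self, "values", v)


def discard_initial_volumes(panel: TimeSeriesPanel, n: int = 10) -> TimeSeriesPanel:
    """Drop the first ``n`` volumes (magnetization-equilibrium scrub)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if panel.n_timepoints <= n:
        raise ValueError(
            f"cannot discard {n} volumes from a {panel.n_timepoints}-volume series"
        )
    return replace(panel, values=panel.values[n:])


def bandpass_filter(
    panel: TimeSeriesPanel,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
) -> TimeSeriesPanel:
    """Zero-phase Butterworth band-pass, applied identically to every column.

    Forward-backward filtering (``sosfiltfilt``) avoids phase lag that would
    distort inter-regional correlations; the default 4th-order design is
    applied twice, so the effective attenuation is squared.
    """
    nyquist = 0.5 / panel.tr_seconds
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz is not below the Nyquist frequency "
            f"{nyquist} Hz at TR={panel.tr_seconds}s"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / panel.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, panel.values, axis=0)
    return replace(panel, values=np.ascontiguousarray(filtered))


def compute_fc(panel: TimeSeriesPanel, roi_names: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation of every ROI pair; errors on zero-variance ROIs."""
    v = panel.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 time points to correlate")
    sd = v.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [roi_names[k] for k in dead] if roi_names is not None else list(dead + 1)
        )
        raise ValueError(f"zero-variance ROI column(s): {names}")
    fc = np.corrcoef(v, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(subject_id=panel.subject_id, values=fc)


def fisher_z(fc: ConnectivityMatrix) -> np.ndarray:
    """Fisher z-transform of the FC matrix (optional modeling extension)."""
    return np.arctanh(np.clip(fc.values, -0.999999, 0.999999))


def vectorize(
    fc: ConnectivityMatrix, partition: NetworkPartition, network: Network
) -> np.ndarray:
    """Extract one network's edge values in canonical (i, j) order."""
    edges = partition.edges(network)
    n = fc.n_rois
    for i, j in edges:
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(
                f"edge ({i}, {j}) out of range for a {n}-ROI connectivity matrix"
            )
    if not edges:
        return np.empty(0)
    idx = np.array(edges, dtype=int) - 1
    return fc.values[idx[:, 0], idx[:, 1]].copy()


def build_feature_matrix(
    fcs: Sequence[ConnectivityMatrix],
    partition: NetworkPartition,
    network: Network,
) -> FeatureMatrix:
    """Stack per-subject network vectors into an N x d feature matrix."""
    subjects = tuple(fc.subject_id for fc in fcs)
    rows = np.vstack([vectorize(fc, partition, network) for fc in fcs]) if fcs else np.empty((0, 0))
    return FeatureMatrix(
        network=network,
        subjects=subjects,
        edge_index=partition.edges(network),
        values=rows,
    )


def write_fc(fc: ConnectivityMatrix, path, roi_names: Sequence[str]) -> None:
    pd.DataFrame(fc.values, columns=list(roi_names)).to_csv(path, sep="\t", index=False)


def read_fc(path, subject_id: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(subject_id=subject_id, values=df.to_numpy(dtype=float))


def write_features(fm: FeatureMatrix, path) -> None:
    """Feature matrix as TSV; columns labelled ``i-j`` per edge."""
    cols = [f"{i}-{j}" for i, j in fm.edge_index]
    df = pd.DataFrame(fm.values, columns=cols)
    df.insert(0, "subject_id", list(fm.subjects))
    df.to_csv(path, sep="\t", index=False)


def read_features(path, network: Network) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    subjects = tuple(str(s) for s in df["subject_id"])
    edge_cols = [c for c in df.columns if c != "subject_id"]
    edges = tuple(tuple(int(x) for x in c.split("-")) for c in edge_cols)
    return FeatureMatrix(
        network=network,
        subjects=subjects,
        edge_index=edges,  # type: ignore[arg-type]
        values=df[edge_cols].to_numpy(dtype=float),
    )
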