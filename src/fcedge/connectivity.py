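"""Fisher-z network connectivity matrices and edge vectors.

Functional connectivity between two networks is the Pearson correlation of
their BOLD time series over the motion-retained volumes, Fisher
z-transformed (atanh).  Per-subject matrices from multiple runs are averaged
entrywise in z-space and flattened to the canonical upper-triangle edge
vector (136 edges for the 17-network parcellation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CLIP_DEFAULT = 1.0 - 1e-7
SYMMETRY_TOL = 1e-10

#: Default labels for the 17-network parcellation (subdivided visual,
#: somatomotor, attention, salience, limbic, central executive and default
#: mode systems).  Fully overridable; analyses only require that labels be
#: unique and ordered.
NETWORK_LABELS_17 = (
    "central_visual",
    "peripheral_visual",
    "somatomotor_A",
    "somatomotor_B",
    "dorsal_attention_A",
    "dorsal_attention_B",
    "anterior_ventral_attention_SN",
    "posterior_ventral_attention_SN",
    "orbitofrontal_limbic",
    "temporal_pole_limbic",
    "lateral_frontoparietal_CEN",
    "medial_superior_parietal_CEN",
    "medial_frontoparietal_CEN",
    "dorsal_DMN",
    "ventral_DMN",
    "anterior_DMN",
    "temporoparietal",
)


@dataclass
class ConnectivityMatrix:
    """Per-subject Fisher-z network x network connectivity."""

    subject_id: str
    z: np.ndarray
    labels: tuple
    n_volumes_used: tuple = ()


@dataclass
class EdgeVector:
    subject_id: str
    values: np.ndarray
    labels: tuple


def fisher_z(r):
    """Fisher transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def connectivity_from_run(
    data: np.ndarray,
    keep_mask: np.ndarray | None = None,
    clip: float = CLIP_DEFAULT,
    labels: tuple | None = None,
) -> np.ndarray:
    """Fisher-z correlation matrix of a volumes x networks run.

    Correlations are computed over the kept volumes only and clipped to
    ``+-clip`` before atanh so that degenerate perfect correlations yield a
    large finite z.  The diagonal is stored as 0 and never enters any edge
    vector.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("run data must be volumes x networks")
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape[0] != data.shape[0]:
            raise ValueError("keep_mask length must match volume count")
        data = data[keep_mask]
    if data.shape[0] < 3:
        raise ValueError(f"need at least 3 kept volumes, have {data.shape[0]}")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        name = labels[bad] if labels is not None else f"column {bad}"
        raise ValueError(f"zero-variance network over kept volumes: {name}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def average_runs(matrices, subject_id: str = "", labels: tuple | None = None,
                 n_volumes_used: tuple = ()) -> ConnectivityMatrix:
    """Entrywise mean of per-run Fisher-z matrices.

    A single run is returned unchanged with a warning: averaging across two
    resting-state scans is the intended design, but one usable run is still
    analyzable.
    """
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    if not matrices:
        raise ValueError("need at least one run matrix")
    shape = matrices[0].shape
    if any(m.shape != shape for m in matrices):
        raise ValueError("run matrices have mismatched shapes")
    if len(matrices) == 1:
        warnings.warn(
            f"subject {subject_id or '<unknown>'}: single run available; "
            "connectivity not averaged across runs",
            stacklevel=2,
        )
    z = np.mean(matrices, axis=0)
    if labels is None:
        labels = tuple(str(i) for i in range(shape[0]))
    return ConnectivityMatrix(
        subject_id=subject_id, z=z, labels=tuple(labels),
        n_volumes_used=tuple(n_volumes_used),
    )


def edge_labels(labels) -> tuple:
    """Canonical edge names: upper triangle, row-major, '<netA>__<netB>'."""
    labels = tuple(labels)
    if len(labels) != len(set(labels)):
        raise ValueError("network labels must be unique")
    return tuple(
        f"{labels[a]}__{labels[b]}"
        for a in range(len(labels))
        for b in range(a + 1, len(labels))
    )


def edge_vector(matrix: ConnectivityMatrix | np.ndarray,
                labels: tuple | None = None,
                subject_id: str = "") -> EdgeVector:
    """Flatten a symmetric z-matrix to the canonical N(N-1)/2 edge vector."""
    if isinstance(matrix, ConnectivityMatrix):
        z, labels, subject_id = matrix.z, matrix.labels, matrix.subject_id
    else:
        z = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(z.shape[0]))
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if np.max(np.abs(z - z.T)) > SYMMETRY_TOL:
        raise ValueError("connectivity matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(z.shape[0], k=1)
    return EdgeVector(
        subject_id=subject_id, values=z[iu].copy(), labels=edge_labels(labels)
    )


def matrix_from_edges(values: np.ndarray, n_networks: int) -> np.ndarray:
    """Inverse of :func:`edge_vector`: rebuild the symmetric matrix (diag 0)."""
    values = np.asarray(values, dtype=float)
    expected = n_networks * (n_networks - 1) // 2
    if values.size != expected:
        raise ValueError(f"expected {expected} edges for {n_networks} networks")
    z = np.zeros((n_networks, n_networks))
    iu = np.triu_indices(n_networks, k=1)
    z[iu] = values
    return z + z.T
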