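"""Separation-quality metrics and ambiguity resolution.

Perfect blind separation recovers each global matrix ``G^d = W^d A^d`` as
a permutation times a diagonal.  The metrics here score how far a result
is from that ideal:

* ``isi_com`` — joint (Amari-style) inter-symbol-interference index on the
  cross-data-set aggregate ``g_{m,n} = sum_d |g^d_{m,n}|``, normalised to
  [0, 1] with 0 at ideal separation and 1 at the all-ones worst case;
* ``u_wa`` — column-normalised off-diagonal leakage
  ``sum_n (sum_m g'_{m,n} - 1)``, zero at ideal separation;
* ``crmse`` — RMS of the ECG reconstruction error over the RMS of the
  true ECG (after scale alignment).

``align_sources`` resolves the scale/sign and the permutation (common to
all data sets) against reference sources, using an optimal assignment on
the absolute correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SourceSet

__all__ = ["GlobalMixMatrix", "AlignmentMap", "global_matrix", "isi_com", "u_wa",
           "align_sources", "crmse"]


@dataclass
class GlobalMixMatrix:
    """Per-data-set global matrices and their absolute-sum aggregate."""

    per_dataset: list[np.ndarray]
    aggregate: np.ndarray

    @property
    def K(self) -> int:
        return self.aggregate.shape[0]


@dataclass
class AlignmentMap:
    """Permutation (shared by all data sets) and signed per-component scales."""

    permutation: np.ndarray
    scales: np.ndarray


def global_matrix(W: list[np.ndarray], A: list[np.ndarray]) -> GlobalMixMatrix:
    """Form ``G^d = W^d A^d`` and the aggregate ``sum_d |G^d|``."""
    if len(W) != len(A):
        raise ValueError(f"got {len(W)} un-mixing and {len(A)} mixing matrices")
    per = []
    for d, (Wd, Ad) in enumerate(zip(W, A)):
        Wd = np.asarray(Wd, float)
        Ad = np.asarray(Ad, float)
        if Wd.shape != Ad.shape or Wd.shape[0] != Wd.shape[1]:
            raise ValueError(f"data set {d}: shapes {Wd.shape} and {Ad.shape} incompatible")
        per.append(Wd @ Ad)
    aggregate = np.sum([np.abs(G) for G in per], axis=0)
    return GlobalMixMatrix(per_dataset=per, aggregate=aggregate)


def _aggregate_of(G) -> np.ndarray:
    g = G.aggregate if isinstance(G, GlobalMixMatrix) else np.asarray(G, float)
    g = np.abs(np.asarray(g, float))
    K = g.shape[0]
    if g.ndim != 2 or g.shape[1] != K or K < 2:
        raise ValueError(f"aggregate must be square with K >= 2, got shape {g.shape}")
    if np.any(g.max(axis=1) == 0) or np.any(g.max(axis=0) == 0):
        raise ValueError("aggregate has an all-zero row or column; metric undefined")
    return g


def isi_com(G) -> float:
    """Joint inter-symbol-interference index of a global-matrix aggregate.

    Rows are normalised by their maximum and columns by theirs; the two
    off-diagonal mass sums are averaged and scaled by ``1/(2K(K-1))`` so
    the index is 0 exactly on permutation-times-positive-diagonal
    aggregates and 1 on the all-ones matrix.
    """
    g = _aggregate_of(G)
    K = g.shape[0]
    psi_row = float(np.sum(g / g.max(axis=1, keepdims=True)) - K)
    psi_col = float(np.sum(g / g.max(axis=0, keepdims=True)) - K)
    return (psi_row + psi_col) / (2.0 * K * (K - 1))


def u_wa(G) -> float:
    """Column-normalised leakage ``sum_n (sum_m g'_{m,n} - 1)``.

    Each column of the aggregate is divided by its maximum, so an ideal
    (permutation x diagonal) aggregate scores exactly zero and any
    off-diagonal leakage adds positively.
    """
    g = _aggregate_of(G)
    gp = g / g.max(axis=0, keepdims=True)
    return float(np.sum(gp.sum(axis=0) - 1.0))


def _stack_time(Y) -> tuple[list[np.ndarray], np.ndarray]:
    if isinstance(Y, np.ndarray) and Y.ndim == 2:
        return [Y], Y
    Ys = [np.asarray(y, float) for y in Y]
    return Ys, np.concatenate(Ys, axis=1)


def align_sources(Y, S_ref) -> tuple[AlignmentMap, list[np.ndarray] | np.ndarray]:
    """Resolve permutation and signed scale against reference sources.

    ``Y`` may be one ``K x L`` matrix or a list of them (one per data
    set); ``S_ref`` likewise (or a :class:`SourceSet`).  One permutation —
    chosen by maximising total absolute correlation with an optimal
    assignment — is applied to every data set; one signed least-squares
    scale per component is fitted on the concatenated data.  Aligned
    components correlate non-negatively with their reference.
    """
    if isinstance(S_ref, SourceSet):
        S_ref = S_ref.signals
    Ys, Ycat = _stack_time(Y)
    Ss, Scat = _stack_time(S_ref)
    if Ycat.shape != Scat.shape:
        raise ValueError(f"estimate {Ycat.shape} and reference {Scat.shape} differ")
    K = Ycat.shape[0]
    sy = Ycat.std(axis=1)
    ss = Scat.std(axis=1)
    for k in range(K):
        if sy[k] == 0:
            raise ValueError(f"estimated component {k} has zero variance")
        if ss[k] == 0:
            raise ValueError(f"reference component {k} has zero variance")
    Yc = Ycat - Ycat.mean(axis=1, keepdims=True)
    Sc = Scat - Scat.mean(axis=1, keepdims=True)
    corr = (Sc @ Yc.T) / (Ycat.shape[1] * np.outer(ss, sy))
    ref_idx, est_idx = linear_sum_assignment(-np.abs(corr))
    # ref_idx is sorted, so est_idx[k] is the estimate matched to reference k
    perm = est_idx
    scales = np.empty(K)
    for k in range(K):
        y = Yc[perm[k]]
        scales[k] = float(y @ Sc[k] / (y @ y))
    aligned = [scales[:, None] * Yd[perm] for Yd in Ys]
    out = aligned[0] if (isinstance(Y, np.ndarray) and np.ndim(Y) == 2) else aligned
    return AlignmentMap(permutation=perm, scales=scales), out


def crmse(s_ecg: np.ndarray, y_ecg: np.ndarray) -> float:
    """Relative RMS reconstruction error ``RMS(s - y) / RMS(s)``."""
    s = np.asarray(s_ecg, float).ravel()
    y = np.asarray(y_ecg, float).ravel()
    if s.shape != y.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {y.shape}")
    denom = np.sqrt(np.mean(s**2))
    if denom == 0:
        raise ValueError("reference ECG has zero RMS")
    return float(np.sqrt(np.mean((s - y) ** 2)) / denom)
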