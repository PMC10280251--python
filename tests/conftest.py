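"""Shared fixtures and controlled-source generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ecgiva import make_source_set, random_mixing_matrix
from ecgiva.core import DataSetCollection, MixedDataSet


def dependent_gaussian_scvs(K, D, L, rhos, seed):
    """Sources whose SCVs are compound-symmetric Gaussians with per-source
    cross-data-set correlation ``rhos[k]`` — the identifiable regime for
    second-order joint separation."""
    rng = np.random.default_rng(seed)
    S = np.zeros((K, D, L))
    for k, r in enumerate(rhos):
        C = np.full((D, D), r) + (1 - r) * np.eye(D)
        S[k] = np.linalg.cholesky(C) @ rng.standard_normal((D, L))
    return S


def dependent_laplacian_scvs(K, D, L, rhos, seed):
    """Multivariate-Laplacian SCVs: Gaussian vectors scaled by a shared
    sqrt-exponential radial factor (heavy tails + cross-data-set dependence)."""
    rng = np.random.default_rng(seed)
    S = np.zeros((K, D, L))
    for k, r in enumerate(rhos):
        C = np.full((D, D), r) + (1 - r) * np.eye(D)
        radial = np.sqrt(rng.exponential(1.0, size=L))
        S[k] = radial * (np.linalg.cholesky(C) @ rng.standard_normal((D, L)))
    return S


def dependent_ggd_scvs(K, D, L, beta, rhos, seed):
    """Multivariate generalized-Gaussian SCVs with shape ``beta``.

    Radius: with t = y' C^-1 y, the density exp(-t^beta) makes v = t^beta a
    Gamma(D/(2 beta), 1) variable; direction: normalised Gaussian.
    """
    rng = np.random.default_rng(seed)
    S = np.zeros((K, D, L))
    for k, r in enumerate(rhos):
        C = np.full((D, D), r) + (1 - r) * np.eye(D)
        Lc = np.linalg.cholesky(C)
        g = Lc @ rng.standard_normal((D, L))
        maha = np.sqrt(np.sum(np.linalg.solve(C, g) * g, axis=0))
        u = g / maha
        v = rng.gamma(D / (2.0 * beta), 1.0, size=L)
        t = v ** (1.0 / (2.0 * beta))
        S[k] = u * t
    return S


def collection_from_scvs(S, seed, mixing=None):
    """Mix (K, D, L) SCV sources into a clean DataSetCollection."""
    K, D, L = S.shape
    datasets = []
    for d in range(D):
        A = mixing[d] if mixing is not None else random_mixing_matrix(K, 1000 + 7 * seed + d)
        datasets.append(
            MixedDataSet(mixed=A @ S[:, d, :], delay=d, mixing=A, sources=S[:, d, :])
        )
    return DataSetCollection(datasets, snr_db="clean", seed=seed)


@pytest.fixture(scope="session")
def ecg_sources():
    """One 10 s four-source bank (ECG, BW, EM, MA) at 360 Hz."""
    return make_source_set(fs=360.0, duration=10.0, seed=42)
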