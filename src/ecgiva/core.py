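"""Core containers shared across the toolkit.

A recording session is modelled as ``D`` linearly mixed data sets

    X^d = A^d S^d,   1 <= d <= D,

where the rows of ``S^d`` are the zero-mean source signals (the ECG plus
the artifact channels) and ``A^d`` is an unknown square mixing matrix.
Joint blind source separation estimates per-data-set un-mixing matrices
``W^d`` so that ``Y^d = W^d X^d`` recovers the sources up to a scale and a
permutation that is common to all data sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SOURCE_LABELS = ("ECG", "BW", "EM", "MA", "OTHER")


@dataclass
class SourceSet:
    """A bank of K zero-mean source signals sampled at ``fs`` Hz.

    Parameters
    ----------
    signals
        ``(K, L)`` array; each row is one source, zero-mean.
    labels
        Length-K tags drawn from ``{"ECG", "BW", "EM", "MA", "OTHER"}``.
    fs
        Sampling rate in Hz.
    """

    signals: np.ndarray
    labels: Sequence[str]
    fs: float

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (K, L) array")
        K, L = self.signals.shape
        if K < 2 or L < 2:
            raise ValueError(f"need K >= 2 and L >= 2, got ({K}, {L})")
        if len(self.labels) != K:
            raise ValueError(f"{len(self.labels)} labels for {K} signals")
        bad = set(self.labels) - set(SOURCE_LABELS)
        if bad:
            raise ValueError(f"unknown source labels: {sorted(bad)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        rms = np.sqrt(np.mean(self.signals**2, axis=1))
        means = np.abs(self.signals.mean(axis=1))
        # all-zero rows (e.g. amplitude=0) are trivially zero-mean
        active = rms > 0
        if np.any(means[active] > 1e-8 * rms[active]):
            raise ValueError("source rows must be zero-mean (within 1e-8 of RMS)")

    @property
    def K(self) -> int:
        return self.signals.shape[0]

    @property
    def L(self) -> int:
        return self.signals.shape[1]

    def row(self, label: str) -> np.ndarray:
        """Return the first source row carrying ``label``."""
        idx = list(self.labels).index(label)
        return self.signals[idx]


@dataclass
class MixedDataSet:
    """One observed data set: ``mixed = A @ S_shifted (+ noise)``."""

    mixed: np.ndarray
    delay: int
    mixing: np.ndarray | None = None
    sources: np.ndarray | None = None  # the shifted/truncated truth, when simulated


@dataclass
class DataSetCollection:
    """Ordered list of D mixed data sets sharing one (K, L) geometry."""

    datasets: list[MixedDataSet]
    snr_db: float | str = "clean"
    seed: int | None = None
    fs: float | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.datasets) < 1:
            raise ValueError("need at least one data set")
        shapes = {ds.mixed.shape for ds in self.datasets}
        if len(shapes) != 1:
            raise ValueError(f"data sets disagree on shape: {sorted(shapes)}")
        delays = [ds.delay for ds in self.datasets]
        if delays[0] != 0:
            raise ValueError("first data set must have delay 0")
        if any(d < 0 for d in delays):
            raise ValueError("delays must be non-negative")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValueError("delays must be strictly increasing")
        for i, ds in enumerate(self.datasets):
            if ds.mixing is not None:
                A = np.asarray(ds.mixing, dtype=float)
                if A.shape != (self.K, self.K):
                    raise ValueError(f"mixing matrix {i} is not K x K")
                if not np.isfinite(np.linalg.cond(A)):
                    raise ValueError(f"mixing matrix {i} is singular")

    @property
    def D(self) -> int:
        return len(self.datasets)

    @property
    def K(self) -> int:
        return self.datasets[0].mixed.shape[0]

    @property
    def L(self) -> int:
        return self.datasets[0].mixed.shape[1]

    @property
    def mixed(self) -> list[np.ndarray]:
        return [ds.mixed for ds in self.datasets]

    @property
    def mixing(self) -> list[np.ndarray] | None:
        mats = [ds.mixing for ds in self.datasets]
        if any(m is None for m in mats):
            return None
        return mats


@dataclass
class AlgorithmOptions:
    """Tuning knobs shared by the separation algorithms.

    ``tolerance`` applies to the maximum absolute change of any un-mixing
    matrix entry between iterations; ``step_size`` is the initial natural
    gradient step (halved on cost increase).  ``ggd_shape`` is the shape
    of the generalized Gaussian source prior (``"estimate"`` fits it per
    source component vector from the marginal kurtosis each iteration).
    """

    max_iterations: int = 512
    tolerance: float = 1e-6
    step_size: float = 0.1
    ggd_shape: float | str = "estimate"
    seed: int = 0
    whiten: bool = True
    init: str = "identity"  # or "random" (seeded orthogonal)
    scv_ridge: float = 0.02  # diagonal loading of SCV covariances (x mean variance)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not (self.ggd_shape == "estimate" or
                (np.isscalar(self.ggd_shape) and self.ggd_shape > 0)):
            raise ValueError("ggd_shape must be positive or 'estimate'")
        if self.scv_ridge < 0:
            raise ValueError("scv_ridge must be non-negative")


@dataclass
class UnmixingResult:
    """Output of a separation algorithm.

    ``W[d] @ X[d]`` reproduces ``Y[d]`` exactly for the inputs the result
    was computed from.
    """

    W: list[np.ndarray]
    Y: list[np.ndarray]
    n_iterations: int
    converged: bool
    algorithm: str
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def D(self) -> int:
        return len(self.W)

    @property
    def K(self) -> int:
        return self.W[0].shape[0]


@dataclass
class RecordingBundle:
    """A multichannel recording plus its provenance."""

    channels: np.ndarray
    fs: float
    channel_names: Sequence[str]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("recording contains NaN or Inf samples")
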