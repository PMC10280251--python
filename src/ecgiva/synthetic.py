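"""Synthetic ECG recordings contaminated by the classic artifact trio.

The generators emulate the statistical and spectral structure of the three
contaminants that are hardest to remove from surface ECG:

* **baseline wander (BW)** — respiratory drift concentrated in the
  0.15-0.3 Hz band plus a slow, large-amplitude random walk from body
  movement;
* **muscle artifact (MA)** — intermittent bursts of broadband (>= 5 Hz)
  Gaussian noise from muscle contraction;
* **electrode movement (EM)** — sparse step-like transients with
  exponential recovery, from momentary changes of electrode-skin
  impedance.

The ECG itself is a sum-of-Gaussians PQRST template repeated at jittered
RR intervals.  ``mix`` and ``make_datasets`` implement the linear
instantaneous observation model ``X^d = A^d S^d`` with optional additive
white Gaussian sensor noise at a prescribed per-channel SNR; the delayed
data sets feed the joint (multi-data-set) separation algorithms.

Every generator is a pure function of its arguments, including ``seed``.
"""

from __future__ import annotations

import numbers

import numpy as np
from scipy import signal as sps

from .core import DataSetCollection, MixedDataSet, SourceSet

__all__ = [
    "gen_ecg",
    "gen_baseline_wander",
    "gen_muscle_artifact",
    "gen_electrode_movement",
    "make_source_set",
    "random_mixing_matrix",
    "mix",
    "make_datasets",
]

# PQRST template: (offset from R peak [s], Gaussian width [s], amplitude
# relative to R).  Timings are textbook adult values.
_PQRST = (
    (-0.170, 0.025, 0.12),   # P
    (-0.026, 0.010, -0.10),  # Q
    (0.000, 0.012, 1.00),    # R
    (0.030, 0.010, -0.25),   # S
    (0.250, 0.060, 0.30),    # T
)

#: default respiratory drift band in Hz
DEFAULT_DRIFT_BAND = (0.15, 0.3)


def _check_fs_duration(fs: float, duration: float, min_fs: float = 100.0) -> int:
    if fs <= 0 or duration <= 0:
        raise ValueError(f"fs and duration must be positive, got fs={fs}, duration={duration}")
    if fs < min_fs:
        raise ValueError(f"fs must be >= {min_fs} Hz, got {fs}")
    n = int(round(fs * duration))
    if n < 2:
        raise ValueError("duration too short for the given sampling rate")
    return n


def gen_ecg(
    fs: float = 360.0,
    duration: float = 10.0,
    heart_rate: float = 72.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a single-lead ECG as a jittered train of PQRST complexes.

    Each beat is a fixed sum of five Gaussians (P, Q, R, S, T waves);
    consecutive RR intervals get independent Gaussian jitter with a
    standard deviation of 3% of the mean RR interval.  The output is
    zero-mean with the R peak scaled to ``amplitude``.

    Parameters
    ----------
    fs : sampling rate, Hz (>= 100)
    duration : record length, s
    heart_rate : mean rate, beats per minute (30-220)
    amplitude : R-peak amplitude in output units
    seed : RNG seed; the output is a pure function of all arguments
    """
    n = _check_fs_duration(fs, duration)
    if not 30.0 <= heart_rate <= 220.0:
        raise ValueError(f"heart_rate must be in [30, 220] bpm, got {heart_rate}")
    rr = 60.0 / heart_rate
    if duration <= 2.0 * rr:
        raise ValueError(f"duration must exceed two RR intervals ({2 * rr:.2f} s)")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    wave = np.zeros(n)
    # first R a fraction into the record so the initial P wave fits
    beat = 0.35 * rr
    while beat < duration + 0.3:
        for off, width, amp in _PQRST:
            center = beat + off
            lo = max(0, int((center - 5 * width) * fs))
            hi = min(n, int((center + 5 * width) * fs) + 1)
            if hi > lo:
                wave[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / width) ** 2)
        beat += rr * (1.0 + 0.03 * rng.standard_normal())
    peak = wave.max()
    if peak > 0:
        wave *= amplitude / peak
    return wave - wave.mean()


def gen_baseline_wander(
    fs: float = 360.0,
    duration: float = 10.0,
    drift_band: tuple[float, float] = DEFAULT_DRIFT_BAND,
    amplitude: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate baseline wander: respiratory drift plus slow body movement.

    The respiratory component is a sum of six random-phase sinusoids with
    frequencies drawn uniformly from ``drift_band``; body movement is a
    low-pass-filtered random walk (cut-off 0.4 Hz) at 25% of the
    respiratory RMS.  The result is zero-mean and RMS-normalised to
    ``amplitude``; well over 90% of its power sits below 0.7 Hz.
    """
    n = _check_fs_duration(fs, duration)
    lo, hi = drift_band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"drift_band must satisfy 0 < lo < hi < fs/2, got {drift_band}")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    wave = np.zeros(n)
    freqs = rng.uniform(lo, hi, size=6)
    phases = rng.uniform(0, 2 * np.pi, size=6)
    amps = rng.rayleigh(1.0, size=6)
    # dominant respiratory line so the spectral peak stays inside the band
    amps[0] += 2.0
    for f, p, a in zip(freqs, phases, amps):
        wave += a * np.sin(2 * np.pi * f * t + p)
    resp_rms = np.sqrt(np.mean(wave**2))
    walk = np.cumsum(rng.standard_normal(n))
    b, a = sps.butter(4, 0.4 / (fs / 2), btype="low")
    walk = sps.filtfilt(b, a, walk)
    walk -= walk.mean()
    walk_rms = np.sqrt(np.mean(walk**2))
    if walk_rms > 0:
        walk *= 0.25 * resp_rms / walk_rms
    wave += walk
    wave -= wave.mean()
    rms = np.sqrt(np.mean(wave**2))
    return wave * (amplitude / rms) if rms > 0 else wave


def gen_muscle_artifact(
    fs: float = 360.0,
    duration: float = 10.0,
    amplitude: float = 1.0,
    burst_rate: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Simulate muscle (EMG) noise: burst-modulated broadband Gaussian noise.

    A white Gaussian carrier is high-pass filtered at 5 Hz (EMG occupies a
    wide band up to the Nyquist rate) and multiplied by an envelope that
    is a low resting tone plus ``burst_rate`` Hann-shaped bursts per
    second (Poisson counts, random width 0.3-1.5 s, random height).
    Sparse bursts make the marginal distribution super-Gaussian (positive
    excess kurtosis), which is what separates EMG from the sensor noise
    floor statistically.  Zero-mean, RMS = ``amplitude``.
    """
    n = _check_fs_duration(fs, duration)
    if burst_rate < 0:
        raise ValueError(f"burst_rate must be >= 0, got {burst_rate}")
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n)
    b, a = sps.butter(4, 5.0 / (fs / 2), btype="high")
    carrier = sps.filtfilt(b, a, carrier)
    envelope = np.full(n, 0.1)
    n_bursts = rng.poisson(burst_rate * duration)
    for _ in range(n_bursts):
        center = rng.uniform(0, duration)
        width = rng.uniform(0.3, 1.5)
        height = rng.uniform(0.5, 1.5)
        m = max(3, int(width * fs))
        win = height * sps.windows.hann(m)
        lo = int((center - width / 2) * fs)
        s0, s1 = max(0, lo), min(n, lo + m)
        if s1 > s0:
            envelope[s0:s1] += win[s0 - lo : s1 - lo]
    wave = carrier * envelope
    wave -= wave.mean()
    rms = np.sqrt(np.mean(wave**2))
    return wave * (amplitude / rms) if rms > 0 else wave


def gen_electrode_movement(
    fs: float = 360.0,
    duration: float = 10.0,
    amplitude: float = 1.0,
    event_rate: float = 0.5,
    seed: int = 0,
    roughness: float = 1.0,
) -> np.ndarray:
    """Simulate electrode-motion artifact.

    Electrode slippage briefly changes the electrode-skin impedance,
    producing an abrupt potential step that relaxes back exponentially as
    contact re-establishes (recovery time constant 0.1-0.5 s).  Events
    arrive as a Poisson process at ``event_rate`` per second with random
    sign and size.  On top of the transients rides continuous
    contact-roughness noise (band-limited 0.5-35 Hz, ``roughness`` times
    the transient RMS) — electrode-motion recordings are notoriously
    broadband and ECG-like between the large excursions, which is what
    makes this the hardest artifact to reject.  The trace is de-meaned
    and RMS-normalised to ``amplitude``; with ``event_rate=0`` the output
    is all zeros.
    """
    n = _check_fs_duration(fs, duration)
    if event_rate < 0:
        raise ValueError(f"event_rate must be >= 0, got {event_rate}")
    if roughness < 0:
        raise ValueError(f"roughness must be >= 0, got {roughness}")
    rng = np.random.default_rng(seed)
    wave = np.zeros(n)
    n_events = rng.poisson(event_rate * duration) if event_rate > 0 else 0
    t = np.arange(n) / fs
    for _ in range(n_events):
        t0 = rng.uniform(0, duration)
        sign = rng.choice([-1.0, 1.0])
        size = rng.uniform(0.5, 1.5)
        tau = rng.uniform(0.1, 0.5)
        i0 = int(t0 * fs)
        if i0 < n:
            wave[i0:] += sign * size * np.exp(-(t[i0:] - t0) / tau)
    if n_events > 0 and roughness > 0:
        b, a = sps.butter(2, [0.5 / (fs / 2), 35.0 / (fs / 2)], btype="band")
        rough = sps.filtfilt(b, a, rng.standard_normal(n))
        base = wave.std()
        if base > 0 and rough.std() > 0:
            wave += roughness * base / rough.std() * rough
    wave -= wave.mean()
    rms = np.sqrt(np.mean(wave**2))
    return wave * (amplitude / rms) if rms > 0 else wave


#: study-condition amplitudes for the four canonical sources.  The ECG value
#: is the R-peak height; 4.0 gives the ECG an RMS comparable to the artifact
#: channels (about 0 dB ECG-to-artifact power), the midrange of noise-stress
#: protocols.  Muscle noise rides lower, as on real torso leads.
DEFAULT_AMPLITUDES = {"ECG": 4.0, "BW": 1.0, "EM": 1.0, "MA": 0.5}


def make_source_set(
    fs: float = 360.0,
    duration: float = 10.0,
    heart_rate: float = 72.0,
    amplitudes: dict[str, float] | None = None,
    seed: int = 0,
) -> SourceSet:
    """Build the canonical K=4 source bank (ECG, BW, EM, MA) in one call.

    Child seeds for the four generators are spawned deterministically from
    ``seed``.
    """
    amps = dict(DEFAULT_AMPLITUDES)
    if amplitudes:
        amps.update(amplitudes)
    ss = np.random.SeedSequence(seed)
    s_ecg, s_bw, s_em, s_ma = (int(s.generate_state(1)[0]) for s in ss.spawn(4))
    rows = np.vstack(
        [
            gen_ecg(fs, duration, heart_rate, amps["ECG"], s_ecg),
            gen_baseline_wander(fs, duration, DEFAULT_DRIFT_BAND, amps["BW"], s_bw),
            gen_electrode_movement(fs, duration, amps["EM"], 0.5, s_em),
            gen_muscle_artifact(fs, duration, amps["MA"], 0.5, s_ma),
        ]
    )
    return SourceSet(rows, ["ECG", "BW", "EM", "MA"], fs)


def random_mixing_matrix(K: int, seed: int = 0, max_cond: float = 100.0) -> np.ndarray:
    """Draw a K x K mixing matrix with i.i.d. standard-normal entries.

    Draws are rejected (and redrawn from the same stream) while the
    condition number exceeds ``max_cond``; unbounded conditioning makes
    Monte-Carlo separation scores heavy-tailed.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        A = rng.standard_normal((K, K))
        if np.linalg.cond(A) <= max_cond:
            return A
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def _validate_snr(snr_db) -> None:
    if isinstance(snr_db, str):
        if snr_db != "clean":
            raise ValueError(f"snr_db must be a finite number or 'clean', got {snr_db!r}")
    elif not (isinstance(snr_db, numbers.Real) and np.isfinite(snr_db)):
        raise ValueError(f"snr_db must be a finite number or 'clean', got {snr_db!r}")


def mix(
    sources: SourceSet | np.ndarray,
    A: np.ndarray,
    snr_db: float | str = "clean",
    seed: int = 0,
) -> np.ndarray:
    """Mix sources linearly and add white Gaussian sensor noise.

    The noise is scaled per channel so that
    ``10*log10(P_signal / P_noise) == snr_db``, with signal power measured
    on the noiseless mixture ``A @ S``.  ``snr_db="clean"`` adds nothing.
    """
    S = sources.signals if isinstance(sources, SourceSet) else np.asarray(sources, float)
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"mixing matrix must be square, got shape {A.shape}")
    if A.shape[1] != S.shape[0]:
        raise ValueError(
            f"mixing matrix is {A.shape[0]}x{A.shape[1]} but there are {S.shape[0]} sources"
        )
    _validate_snr(snr_db)
    X = A @ S
    if snr_db == "clean":
        return X
    rng = np.random.default_rng(seed)
    p_sig = np.mean(X**2, axis=1, keepdims=True)
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    return X + sigma * rng.standard_normal(X.shape)


def make_datasets(
    sources: SourceSet,
    delays: tuple[int, ...] = (0, 1, 2, 3),
    snr_db: float | str = "clean",
    mixing_seed: int = 0,
    shared_mixing: bool = False,
    mixing_matrices: list[np.ndarray] | None = None,
) -> DataSetCollection:
    """Build the D delayed data sets that joint separation consumes.

    Data set ``d`` observes the sources advanced by ``delays[d]`` samples
    through its own random mixing matrix (independent draws by default;
    ``shared_mixing=True`` reuses the first draw everywhere).  All data
    sets are truncated to the common length ``L - max(delays)``.  Each
    data set receives an independent noise realisation at ``snr_db``.
    Pass ``mixing_matrices`` to pin the mixing (e.g. identity matrices in
    a controlled experiment).
    """
    delays = tuple(int(d) for d in delays)
    D = len(delays)
    if D < 1 or delays[0] != 0:
        raise ValueError("delays must start at 0")
    if any(b <= a for a, b in zip(delays, delays[1:])):
        raise ValueError(f"delays must be strictly increasing, got {delays}")
    K, L = sources.K, sources.L
    if max(delays) >= L / 10:
        raise ValueError(f"max delay {max(delays)} too large for L={L}")
    _validate_snr(snr_db)
    Lc = L - max(delays)

    ss = np.random.SeedSequence(mixing_seed)
    mix_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(D)]
    noise_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(D)]

    if mixing_matrices is not None:
        if len(mixing_matrices) != D:
            raise ValueError("need one mixing matrix per data set")
        mats = [np.asarray(m, dtype=float) for m in mixing_matrices]
    elif shared_mixing:
        mats = [random_mixing_matrix(K, mix_seeds[0])] * D
    else:
        mats = [random_mixing_matrix(K, s) for s in mix_seeds]

    datasets = []
    for d, (delay, A) in enumerate(zip(delays, mats)):
        shifted = sources.signals[:, delay : delay + Lc]
        X = mix(shifted, A, snr_db=snr_db, seed=noise_seeds[d])
        datasets.append(MixedDataSet(mixed=X, delay=delay, mixing=A, sources=shifted))
    return DataSetCollection(
        datasets, snr_db=snr_db, seed=mixing_seed, fs=sources.fs, labels=list(sources.labels)
    )
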