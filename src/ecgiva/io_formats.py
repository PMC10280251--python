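"""Readers and writers for the formats the toolkit touches.

Real recordings arrive in WFDB format (a plain-text ``.hea`` header next
to a binary ``.dat`` signal file); synthetic material and results travel
as CSV matrices (one column per channel) or as an ``.npz`` container with
a JSON metadata sidecar.  Only WFDB signal formats 16 (little-endian
int16) and 212 (packed 12-bit pairs) are supported — these cover the
MIT-BIH family of databases; anything else is rejected explicitly.
All readers refuse non-finite samples.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataSetCollection, MixedDataSet, RecordingBundle, UnmixingResult

__all__ = [
    "read_wfdb",
    "read_csv_matrix",
    "write_csv_matrix",
    "save_collection",
    "load_collection",
    "save_result",
    "load_result",
]

logger = logging.getLogger(__name__)


class WFDBParseError(ValueError):
    """Raised when a WFDB header or signal file cannot be parsed."""


# ---------------------------------------------------------------------------
# WFDB

def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WFDBParseError(f"{hea_path.name}: empty header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise WFDBParseError(f"{hea_path.name}: malformed record line {lines[0]!r}")
    try:
        nsig = int(rec[1])
        fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
        nsamp = int(rec[3]) if len(rec) > 3 else 0
    except ValueError as exc:
        raise WFDBParseError(f"{hea_path.name}: bad record line {lines[0]!r}") from exc
    if nsig < 1 or len(lines) < 1 + nsig:
        raise WFDBParseError(f"{hea_path.name}: expected {nsig} signal lines")
    signals = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise WFDBParseError(f"{hea_path.name}: malformed signal line {ln!r}")
        fname = f[0]
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(f) > 2:
            gspec = f[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                gain = float(gpart)
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gspec)
        if gain == 0:
            gain = 200.0
        adczero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adczero
        name = " ".join(f[8:]) if len(f) > 8 else f"ch{len(signals) + 1}"
        signals.append({"file": fname, "fmt": fmt, "gain": gain,
                        "baseline": baseline, "name": name})
    return fs, nsamp, signals


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    need = (n_values * 3 + 1) // 2
    if len(raw) < need:
        raise WFDBParseError(
            f"signal file truncated: {len(raw)} bytes, need {need} for {n_values} samples"
        )
    b = np.frombuffer(raw[: (n_values + 1) // 2 * 3], dtype=np.uint8).astype(np.int32)
    b = b.reshape(-1, 3)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(b.shape[0] * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # sign-extend 12-bit two's complement
    return out[:n_values]


def read_wfdb(record_path: str | Path) -> RecordingBundle:
    """Read a WFDB record (``.hea`` + ``.dat``) into physical units.

    ``record_path`` is the record name with or without the ``.hea``
    suffix.  Samples are converted as ``(adc - baseline) / gain``.  Only
    signal formats 16 and 212 with all channels in one signal file are
    supported.
    """
    p = Path(record_path)
    hea = p if p.suffix == ".hea" else p.with_suffix(".hea")
    if not hea.exists():
        raise WFDBParseError(f"header file not found: {hea}")
    fs, nsamp, signals = _parse_header(hea)
    nsig = len(signals)
    files = {s["file"] for s in signals}
    if len(files) != 1:
        raise WFDBParseError(f"{hea.name}: multi-file records are not supported")
    fmts = {s["fmt"] for s in signals}
    if len(fmts) != 1 or fmts.pop() not in (16, 212):
        raise WFDBParseError(
            f"{hea.name}: unsupported signal format {sorted(s['fmt'] for s in signals)}; "
            "only formats 16 and 212 are supported"
        )
    fmt = signals[0]["fmt"]
    dat = hea.parent / signals[0]["file"]
    if not dat.exists():
        raise WFDBParseError(f"signal file not found: {dat}")
    raw = dat.read_bytes()
    if fmt == 16:
        n_have = len(raw) // 2
        if nsamp and n_have < nsamp * nsig:
            raise WFDBParseError(
                f"{dat.name} truncated: {n_have} values, expected {nsamp * nsig}"
            )
        flat = np.frombuffer(raw[: (n_have // nsig) * nsig * 2], dtype="<i2").astype(np.int32)
    else:
        n_values = nsamp * nsig if nsamp else (len(raw) // 3) * 2
        flat = _decode_212(raw, n_values)
    n_frames = len(flat) // nsig
    if nsamp and n_frames < nsamp:
        raise WFDBParseError(f"{dat.name} truncated: {n_frames} frames, expected {nsamp}")
    adc = flat[: n_frames * nsig].reshape(n_frames, nsig).T
    channels = np.empty(adc.shape, dtype=float)
    for i, s in enumerate(signals):
        channels[i] = (adc[i] - s["baseline"]) / s["gain"]
    if not np.all(np.isfinite(channels)):
        raise WFDBParseError(f"{dat.name}: non-finite samples after conversion")
    return RecordingBundle(
        channels=channels,
        fs=fs,
        channel_names=[s["name"] for s in signals],
        provenance=f"wfdb:{hea.stem}",
    )


# ---------------------------------------------------------------------------
# CSV

def read_csv_matrix(path: str | Path, fs: float) -> RecordingBundle:
    """Read a channel-per-column CSV into a :class:`RecordingBundle`.

    The first row is taken as channel names unless every cell parses as a
    number, in which case channels are auto-named ``ch1..chK`` and a
    warning is logged.
    """
    path = Path(path)
    try:
        first = path.open().readline()
    except OSError as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    if not first.strip():
        raise ValueError(f"{path.name}: empty file")
    cells = [c.strip() for c in first.strip().split(",")]

    def _numeric(c: str) -> bool:
        try:
            float(c)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(c) for c in cells)
    try:
        df = pd.read_csv(path, header=0 if has_header else None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path.name}: {exc}") from exc
    if not has_header:
        df.columns = [f"ch{i + 1}" for i in range(df.shape[1])]
        logger.warning("%s: no header row; channels auto-named ch1..ch%d",
                       path.name, df.shape[1])
    values = df.to_numpy(dtype=float).T
    if values.size == 0:
        raise ValueError(f"{path.name}: no samples")
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0][1]) + 1
        raise ValueError(f"{path.name}: non-finite sample near line {bad}")
    return RecordingBundle(
        channels=values,
        fs=fs,
        channel_names=[str(c) for c in df.columns],
        provenance=f"csv:{path}",
    )


def write_csv_matrix(bundle: RecordingBundle, path: str | Path) -> None:
    """Write a bundle as CSV, one column per channel, header = names."""
    df = pd.DataFrame(bundle.channels.T, columns=list(bundle.channel_names))
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# npz container + JSON sidecar

def save_collection(coll: DataSetCollection, path: str | Path) -> None:
    """Store a :class:`DataSetCollection` as ``.npz`` plus a JSON sidecar."""
    path = Path(path)
    arrays = {}
    for d, ds in enumerate(coll.datasets):
        arrays[f"mixed_{d}"] = ds.mixed
        if ds.mixing is not None:
            arrays[f"mixing_{d}"] = ds.mixing
        if ds.sources is not None:
            arrays[f"sources_{d}"] = ds.sources
    np.savez(path, **arrays)
    meta = {
        "D": coll.D,
        "delays": [ds.delay for ds in coll.datasets],
        "snr_db": coll.snr_db,
        "seed": coll.seed,
        "fs": coll.fs,
        "labels": list(coll.labels) if coll.labels else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_collection(path: str | Path) -> DataSetCollection:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        datasets = []
        for d, delay in enumerate(meta["delays"]):
            datasets.append(
                MixedDataSet(
                    mixed=z[f"mixed_{d}"],
                    delay=int(delay),
                    mixing=z[f"mixing_{d}"] if f"mixing_{d}" in z else None,
                    sources=z[f"sources_{d}"] if f"sources_{d}" in z else None,
                )
            )
    return DataSetCollection(
        datasets,
        snr_db=meta["snr_db"],
        seed=meta["seed"],
        fs=meta["fs"],
        labels=meta["labels"],
    )


def save_result(res: UnmixingResult, path: str | Path, extra: dict | None = None) -> None:
    """Store an :class:`UnmixingResult` as ``.npz`` plus a JSON sidecar."""
    path = Path(path)
    arrays = {}
    for d in range(res.D):
        arrays[f"W_{d}"] = res.W[d]
        arrays[f"Y_{d}"] = res.Y[d]
    arrays["cost_trace"] = res.cost_trace
    np.savez(path, **arrays)
    meta = {
        "algorithm": res.algorithm,
        "n_iterations": res.n_iterations,
        "converged": bool(res.converged),
        "D": res.D,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_result(path: str | Path) -> UnmixingResult:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        W = [z[f"W_{d}"] for d in range(meta["D"])]
        Y = [z[f"Y_{d}"] for d in range(meta["D"])]
        trace = z["cost_trace"]
    return UnmixingResult(
        W=W,
        Y=Y,
        n_iterations=meta["n_iterations"],
        converged=meta["converged"],
        algorithm=meta["algorithm"],
        cost_trace=trace,
    )
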