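"""Cohort and results I/O: EDF, delimited text, JSON manifests, CSV tables.

EDF (European Data Format) support is a deliberately small, dependency-free
reader/writer pair: 16-bit samples, physical unit µV, one data record per
file.  Delimited epochs are one-column CSV files (header ``value_uv``), one
row per sample, with epoch metadata held in a JSON sidecar manifest.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .epoch import Epoch
from .errors import EdfFormatError, InvalidInputError, ManifestError

__all__ = [
    "write_edf",
    "read_edf",
    "read_edf_epoch",
    "write_cohort",
    "read_epochs",
    "write_results",
]

MANIFEST_NAME = "manifest.json"

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise InvalidInputError(f"EDF header field {text!r} exceeds {width} chars")
    return text.ljust(width).encode("ascii")


def _phys_range(signals: list[np.ndarray]) -> tuple[float, float]:
    peak = max((float(np.max(np.abs(s))) if s.size else 0.0) for s in signals)
    # round the bound up so every sample stays inside the written range
    pmax = max(math.ceil(max(peak, 1e-3) * 100.0) / 100.0, 0.01)
    return -pmax, pmax


def write_edf(
    path: str | Path,
    signals: list[np.ndarray],
    fs: float,
    labels: list[str] | None = None,
    record_id: str = "eegbands cohort",
) -> None:
    """Write one EDF file: one data record, 16-bit signals in µV."""
    if not signals:
        raise InvalidInputError("cannot write an EDF file with no signals")
    signals = [np.asarray(s, dtype=float) for s in signals]
    n_samples = signals[0].size
    if any(s.size != n_samples for s in signals):
        raise InvalidInputError("all EDF signals must share one length")
    if labels is None:
        labels = [f"ch{i}" for i in range(len(signals))]
    duration = n_samples / fs
    pmin, pmax = _phys_range(signals)
    # re-parse the formatted bounds so quantization uses the written values
    pmin_txt, pmax_txt = f"{pmin:.8g}"[:8], f"{pmax:.8g}"[:8]
    pmin_r, pmax_r = float(pmin_txt), float(pmax_txt)
    scale = (pmax_r - pmin_r) / (_DIG_MAX - _DIG_MIN)
    ns = len(signals)
    header = b"".join(
        [
            _field(0, 8),
            _field("synthetic", 80),
            _field(record_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (ns + 1), 8),
            _field("", 44),
            _field(1, 8),
            _field(f"{duration:.8g}"[:8], 8),
            _field(ns, 4),
        ]
    )
    per_signal = [
        b"".join(_field(lab, 16) for lab in labels),
        b"".join(_field("", 80) for _ in signals),
        b"".join(_field("uV", 8) for _ in signals),
        b"".join(_field(pmin_txt, 8) for _ in signals),
        b"".join(_field(pmax_txt, 8) for _ in signals),
        b"".join(_field(_DIG_MIN, 8) for _ in signals),
        b"".join(_field(_DIG_MAX, 8) for _ in signals),
        b"".join(_field("", 80) for _ in signals),
        b"".join(_field(n_samples, 8) for _ in signals),
        b"".join(_field("", 32) for _ in signals),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for s in signals:
            digital = np.round((s - pmin_r) / scale).astype(np.int64) + _DIG_MIN
            digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(digital.tobytes())


def read_edf(path: str | Path) -> tuple[list[np.ndarray], list[str], float]:
    """Read an EDF file -> (signals in µV, labels, fs).

    Raises :class:`EdfFormatError` on malformed headers, truncated payloads
    or sampling-rate disagreement between signals.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: file shorter than the 256-byte EDF header")

    def ascii_field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(ascii_field(236, 8))
        record_duration = float(ascii_field(244, 8))
        ns = int(ascii_field(252, 4))
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed EDF header numerics") from exc
    if ns < 1 or n_records < 1 or record_duration <= 0:
        raise EdfFormatError(f"{path}: implausible EDF header counts")
    header_bytes = 256 * (ns + 1)
    if len(raw) < header_bytes:
        raise EdfFormatError(f"{path}: truncated EDF signal header")

    def signal_fields(block: int, width: int) -> list[str]:
        # signal headers are stored field-major after the fixed header
        base = 256 + block
        return [
            raw[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    offset = 0
    labels = signal_fields(offset, 16); offset += 16 * ns
    offset += 80 * ns  # transducer
    offset += 8 * ns  # physical dimension
    try:
        pmin = [float(v) for v in signal_fields(offset, 8)]; offset += 8 * ns
        pmax = [float(v) for v in signal_fields(offset, 8)]; offset += 8 * ns
        dmin = [int(v) for v in signal_fields(offset, 8)]; offset += 8 * ns
        dmax = [int(v) for v in signal_fields(offset, 8)]; offset += 8 * ns
        offset += 80 * ns  # prefiltering
        spr = [int(v) for v in signal_fields(offset, 8)]
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed EDF signal header") from exc

    expected = header_bytes + n_records * sum(spr) * 2
    if len(raw) < expected:
        raise EdfFormatError(
            f"{path}: truncated EDF payload ({len(raw)} bytes, expected {expected})"
        )
    fs_values = {round(s / record_duration, 6) for s in spr}
    if len(fs_values) != 1:
        raise EdfFormatError(f"{path}: signals disagree on sampling rate: {fs_values}")
    fs = fs_values.pop()

    signals: list[np.ndarray] = []
    pos = header_bytes
    chunks: list[list[np.ndarray]] = [[] for _ in range(ns)]
    for _ in range(n_records):
        for i in range(ns):
            count = spr[i]
            data = np.frombuffer(raw, dtype="<i2", count=count, offset=pos)
            pos += 2 * count
            chunks[i].append(data.astype(float))
    for i in range(ns):
        digital = np.concatenate(chunks[i])
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        signals.append((digital - dmin[i]) * scale + pmin[i])
    return signals, labels, fs


def read_edf_epoch(
    path: str | Path,
    epoch_id: str = "",
    group: str = "unknown",
    channel_agg: str = "mean",
) -> Epoch:
    """Read an EDF file as a single epoch, aggregating channels if needed."""
    signals, labels, fs = read_edf(path)
    if len(signals) == 1:
        samples = signals[0]
    elif channel_agg == "mean":
        samples = np.mean(signals, axis=0)
    elif channel_agg.startswith("single:"):
        wanted = channel_agg.split(":", 1)[1]
        if wanted not in labels:
            raise InvalidInputError(f"{path}: no channel labelled {wanted!r}")
        samples = signals[labels.index(wanted)]
    else:
        raise InvalidInputError(f"unknown channel_agg {channel_agg!r}")
    return Epoch(samples=samples, fs=fs, epoch_id=epoch_id or Path(path).stem, group=group)


def write_cohort(
    cohort: list[Epoch],
    manifest: dict,
    out_dir: str | Path,
    fmt: str = "csv",
) -> Path:
    """Write a cohort directory: one file per epoch plus ``manifest.json``."""
    if fmt not in ("csv", "edf"):
        raise InvalidInputError(f"unknown cohort format {fmt!r}")
    if fmt == "edf" and not cohort:
        raise InvalidInputError("refusing to write an empty cohort as EDF")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    manifest["format"] = fmt
    by_id = {rec["epoch_id"]: rec for rec in manifest.get("epochs", [])}
    for epoch in cohort:
        name = f"{epoch.epoch_id}.{fmt}"
        target = out_dir / name
        if fmt == "csv":
            # %.17g guarantees exact float64 round-tripping
            pd.DataFrame({"value_uv": epoch.samples}).to_csv(
                target, index=False, float_format="%.17g"
            )
        else:
            write_edf(target, [epoch.samples], epoch.fs, labels=["eeg"])
        record = by_id.setdefault(epoch.epoch_id, {"epoch_id": epoch.epoch_id})
        record.update(
            {
                "file": name,
                "group": epoch.group,
                "fs": epoch.fs,
                "n_samples": epoch.n_samples,
            }
        )
    manifest["epochs"] = list(by_id.values())
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir


def read_epochs(path: str | Path, channel_agg: str = "mean") -> tuple[list[Epoch], dict]:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise ManifestError(f"no {MANIFEST_NAME} in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{manifest_path}: invalid JSON") from exc
    fmt = manifest.get("format")
    epochs: list[Epoch] = []
    seen: set[str] = set()
    for record in manifest.get("epochs", []):
        epoch_id = record["epoch_id"]
        if epoch_id in seen:
            raise ManifestError(f"duplicate epoch id {epoch_id!r} in manifest")
        seen.add(epoch_id)
        epoch_file = path / record["file"]
        if not epoch_file.exists():
            raise ManifestError(f"manifest references missing file {epoch_file}")
        if fmt == "csv":
            values = pd.read_csv(epoch_file, float_precision="round_trip")[
                "value_uv"
            ].to_numpy(dtype=float)
            epoch = Epoch(
                samples=values,
                fs=float(record["fs"]),
                epoch_id=epoch_id,
                group=record.get("group", "unknown"),
            )
        elif fmt == "edf":
            epoch = read_edf_epoch(
                epoch_file,
                epoch_id=epoch_id,
                group=record.get("group", "unknown"),
                channel_agg=channel_agg,
            )
        else:
            raise ManifestError(f"manifest declares unknown format {fmt!r}")
        if epoch.n_samples != int(record["n_samples"]):
            raise ManifestError(
                f"{epoch_file}: {epoch.n_samples} samples, manifest says {record['n_samples']}"
            )
        epochs.append(epoch)
    return epochs, manifest


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path, run_info: dict | None = None) -> Path:
    """Write named result tables as CSV plus a JSON run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        target = out_dir / f"{name}.csv"
        table.to_csv(target, index=False)
        written.append(target.name)
    log = {"files": written}
    log.update(run_info or {})
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out_dir
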