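"""Reading labeled phonocardiogram recordings.

Recordings arrive as mono WAV files (PCM16 or float) accompanied by a
manifest CSV with columns ``filename,label``.  Everything is resampled to a
common rate (2000 Hz by default, the rate used by the 2016 PhysioNet/CinC
heart-sound corpus) at ingestion so downstream stages can assume it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

TARGET_RATE = 2000

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
LABELS = (HEALTHY, UNHEALTHY)

#: Accepted spellings for each class, case-insensitive.  ``-1``/``1`` are the
#: codes used in PhysioNet header files.
DEFAULT_LABEL_ALIASES: dict[str, str] = {
    "healthy": HEALTHY,
    "normal": HEALTHY,
    "-1": HEALTHY,
    "unhealthy": UNHEALTHY,
    "1": UNHEALTHY,
}

MIN_DURATION_S = 0.2  # one STFT window (400 samples at 2000 Hz)
MAX_DURATION_S = 120.0


class DatasetError(ValueError):
    """Raised for malformed manifests or unreadable recordings."""


@dataclass
class PCGRecord:
    """One labeled heart-sound signal."""

    id: str
    samples: np.ndarray  # float64, dimensionless amplitude
    rate: int
    label: str

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def validate(self) -> "PCGRecord":
        if self.label not in LABELS:
            raise DatasetError(f"record {self.id!r}: unknown label {self.label!r}")
        if not np.all(np.isfinite(self.samples)):
            raise DatasetError(f"record {self.id!r}: non-finite samples")
        if not MIN_DURATION_S <= self.duration <= MAX_DURATION_S:
            raise DatasetError(
                f"record {self.id!r}: duration {self.duration:.3f}s outside "
                f"[{MIN_DURATION_S}, {MAX_DURATION_S}]s"
            )
        return self


@dataclass
class DatasetManifest:
    """Ordered list of (path, label) entries with per-class counts."""

    entries: list[tuple[Path, str]] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for _, lab in self.entries:
            counts[lab] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


def normalize_label(raw: str, aliases: dict[str, str] | None = None) -> str:
    aliases = DEFAULT_LABEL_ALIASES if aliases is None else aliases
    key = raw.strip().lower()
    if key not in aliases:
        raise DatasetError(f"unknown label {raw!r} (accepted: {sorted(aliases)})")
    return aliases[key]


def load_manifest(
    path: str | Path,
    aliases: dict[str, str] | None = None,
    check_exists: bool = True,
) -> DatasetManifest:
    """Load a ``filename,label`` CSV into a :class:`DatasetManifest`.

    Paths are resolved relative to the CSV's directory.  Duplicate record
    ids and unknown label strings are fatal; an empty manifest only logs a
    warning.
    """
    path = Path(path)
    if not path.is_file():
        raise DatasetError(f"manifest not found: {path}")
    entries: list[tuple[Path, str]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"filename", "label"} <= set(
            reader.fieldnames
        ):
            raise DatasetError(
                f"{path}: manifest must have header columns 'filename,label', "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            fname = row["filename"].strip()
            try:
                label = normalize_label(row["label"], aliases)
            except DatasetError as e:
                raise DatasetError(f"{path}:{i}: {e}") from None
            wav = path.parent / fname
            if check_exists and not wav.is_file():
                raise DatasetError(f"{path}:{i}: file not found: {wav}")
            rec_id = Path(fname).stem
            if rec_id in seen:
                raise DatasetError(f"{path}:{i}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            entries.append((wav, label))
    if not entries:
        logger.warning("manifest %s is empty (header only)", path)
    return DatasetManifest(entries=entries)


def _to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def read_record(
    path: str | Path,
    label: str = HEALTHY,
    target_rate: int = TARGET_RATE,
    record_id: str | None = None,
) -> PCGRecord:
    """Read a WAV file and return a validated record at ``target_rate``.

    Stereo input is reduced to mono by averaging channels.  Resampling uses
    a polyphase anti-aliased filter; a file already at ``target_rate``
    passes through untouched.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as e:  # corrupt / truncated / not a RIFF file
        raise DatasetError(f"cannot read WAV {path}: {e}") from e
    if data.size == 0:
        raise DatasetError(f"zero-length WAV: {path}")
    x = _to_float(data)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate))
        x = resample_poly(x, frac.numerator, frac.denominator)
    rec = PCGRecord(
        id=record_id or path.stem,
        samples=np.ascontiguousarray(x, dtype=np.float64),
        rate=target_rate,
        label=label,
    )
    return rec.validate()


def write_record(rec: PCGRecord, path: str | Path) -> Path:
    """Write a record as a 16-bit PCM WAV (values clipped to [-1, 1))."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    quantized = np.clip(np.round(rec.samples * 32767.0), -32768, 32767).astype(
        np.int16
    )
    wavfile.write(path, rec.rate, quantized)
    return path


def load_records(
    manifest: DatasetManifest, target_rate: int = TARGET_RATE
) -> list[PCGRecord]:
    """Read every manifest entry; per-record failures are fatal here
    (batch-tolerant reading lives in :func:`heartpcg.spectrogram.batch_convert`)."""
    return [read_record(p, label=lab, target_rate=target_rate) for p, lab in manifest.entries]


def write_manifest(
    entries: list[tuple[str, str]], path: str | Path
) -> Path:
    """Write a ``filename,label`` CSV (filenames relative to the CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(entries)
    return path
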