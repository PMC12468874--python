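"""Synthetic phonocardiogram generator.

Emulates the statistical structure the classification pipeline relies on:
2000 Hz mono recordings of periodic cardiac cycles, each cycle carrying an
S1 burst (valve closure at the start of systole, low-frequency) and an S2
burst (start of diastole, slightly higher-frequency), with the "unhealthy"
class additionally carrying a band-limited systolic murmur between S1 and
S2.  White background noise is added to every record and the default class
mix mirrors the ~77%/23% healthy/unhealthy imbalance of the 2016
PhysioNet/CinC corpus.

The murmur is stationary band-passed noise rather than a frequency-swept
tone: the simplest construct that separates the classes in the spectrogram
rows where real murmurs live (well above the S1/S2 bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataset_io import (
    HEALTHY,
    UNHEALTHY,
    DatasetManifest,
    PCGRecord,
    write_manifest,
    write_record,
)


@dataclass
class SynthConfig:
    """Generation parameters; defaults mirror the real corpus' conditions."""

    n_healthy: int = 124
    n_unhealthy: int = 36
    rate: int = 2000
    duration: float = 10.0  # seconds per record
    heart_rate: float = 70.0  # beats/minute
    heart_rate_jitter: float = 5.0  # s.d. of per-cycle bpm jitter
    s1_freq: tuple[float, float] = (30.0, 80.0)  # Hz band S1 tones drawn from
    s2_freq: tuple[float, float] = (50.0, 120.0)
    s1_duration: float = 0.10  # seconds (Gaussian envelope width ~ /6)
    s2_duration: float = 0.08
    systole: float = 0.30  # S1 onset -> S2 onset, seconds
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_amplitude: float = 0.35  # relative to S1 amplitude 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> "SynthConfig":
        nyq = self.rate / 2
        for lo, hi in (self.s1_freq, self.s2_freq, self.murmur_band):
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band ({lo}, {hi}) must sit inside (0, {nyq})")
        if self.n_healthy + self.n_unhealthy < 2:
            raise ValueError("need at least 2 records")
        cycle = 60.0 / self.heart_rate
        if self.systole + self.s2_duration >= cycle:
            raise ValueError(
                f"systole {self.systole}s + S2 does not fit in a "
                f"{cycle:.2f}s cardiac cycle at {self.heart_rate} bpm"
            )
        if self.murmur_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        return self


def _burst(t: np.ndarray, onset: float, dur: float, freq: float, amp: float) -> np.ndarray:
    """Gaussian-enveloped tone: a transient heart sound."""
    center = onset + dur / 2
    sigma = dur / 6
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return amp * env * np.sin(2 * np.pi * freq * (t - onset))


def generate_record(
    cfg: SynthConfig, rng: np.random.Generator, rec_id: str, label: str
) -> PCGRecord:
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    x = np.zeros(n)

    murmur_sos = None
    if label == UNHEALTHY and cfg.murmur_amplitude > 0:
        murmur_sos = butter(
            4, cfg.murmur_band, btype="bandpass", fs=cfg.rate, output="sos"
        )

    onset = rng.uniform(0.0, 0.2)
    while onset < cfg.duration:
        bpm = cfg.heart_rate + rng.normal(0.0, cfg.heart_rate_jitter)
        cycle = 60.0 / max(bpm, 30.0)
        f1 = rng.uniform(*cfg.s1_freq)
        f2 = rng.uniform(*cfg.s2_freq)
        x += _burst(t, onset, cfg.s1_duration, f1, amp=1.0)
        x += _burst(t, onset + cfg.systole, cfg.s2_duration, f2, amp=0.7)
        if murmur_sos is not None:
            # band-limited noise across the systolic interval S1 -> S2
            raw = rng.normal(0.0, 1.0, n)
            band = sosfiltfilt(murmur_sos, raw)
            band /= max(band.std(), 1e-12)
            sys_lo = onset + cfg.s1_duration
            sys_hi = onset + cfg.systole
            gate = np.exp(
                -0.5 * ((t - (sys_lo + sys_hi) / 2) / ((sys_hi - sys_lo) / 4)) ** 2
            )
            x += cfg.murmur_amplitude * gate * band
        onset += cycle
    x += rng.normal(0.0, cfg.noise_sd, n)
    # keep inside [-1, 1) so 16-bit WAV round-trips without clipping
    x *= 0.5 / max(np.abs(x).max(), 1e-12)
    return PCGRecord(id=rec_id, samples=x, rate=cfg.rate, label=label).validate()


def generate_dataset(cfg: SynthConfig) -> list[PCGRecord]:
    """Generate ``n_healthy + n_unhealthy`` labeled records, deterministically
    in ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_healthy):
        records.append(generate_record(cfg, rng, f"synth_h{i:04d}", HEALTHY))
    for i in range(cfg.n_unhealthy):
        records.append(generate_record(cfg, rng, f"synth_u{i:04d}", UNHEALTHY))
    return records


def write_dataset(cfg: SynthConfig, out_dir: str | Path) -> tuple[Path, list[PCGRecord]]:
    """Generate and write WAVs plus a manifest CSV readable by dataset_io.

    Returns (manifest path, records).  Byte-identical output for a fixed
    config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_dataset(cfg)
    entries = []
    for rec in records:
        fname = f"{rec.id}.wav"
        write_record(rec, out_dir / fname)
        entries.append((fname, rec.label))
    manifest_path = write_manifest(entries, out_dir / "manifest.csv")
    return manifest_path, records


def band_energy(x: np.ndarray, rate: int, band: tuple[float, float]) -> float:
    """Mean spectral energy of ``x`` inside a frequency band (periodogram)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].mean())
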