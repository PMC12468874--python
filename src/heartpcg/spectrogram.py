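"""PCG signal -> fixed-size time-frequency image.

A short-time Fourier transform with a Hamming window (length 400 samples =
0.2 s at 2000 Hz, overlap 50) turns each recording into a magnitude grid;
the grid is dB-transformed, min-max normalized and bilinearly resized to a
square image (200x200 by default) for the 2-D network.

Frame semantics match the common spectral-analysis convention: no padding,
``floor((L - window) / (window - overlap)) + 1`` frames, so a record must be
at least one window long.

The printed settings pair "FFT size 50" with a 400-sample window, which is
ill-defined for a standard STFT (fewer transform points than the window);
the default keeps ``fft_length = window_length``, and the ``matlab_truncate``
mode reproduces the literal setting by truncating each windowed frame to
``fft_length`` samples before the transform.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as sk_resize

from .dataset_io import DatasetManifest, PCGRecord, read_record

logger = logging.getLogger(__name__)

DB_EPS = 1e-10  # floor added to magnitudes before 20*log10


@dataclass
class STFTConfig:
    window_kind: str = "hamming"
    window_length: int = 400
    overlap: int = 50
    fft_length: int | None = None  # None -> window_length
    matlab_truncate: bool = False  # truncate windowed frames to fft_length
    out_size: int = 200
    scale: str = "db"  # or "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window_length:
            raise ValueError("require 0 <= overlap < window_length")
        if self.fft_length is None:
            self.fft_length = 50 if self.matlab_truncate else self.window_length
        if self.fft_length < 1:
            raise ValueError("fft_length must be >= 1")
        if self.window_kind != "hamming":
            raise ValueError(f"unsupported window: {self.window_kind}")
        if self.scale not in ("db", "linear"):
            raise ValueError(f"scale must be 'db' or 'linear', got {self.scale!r}")

    @property
    def hop(self) -> int:
        return self.window_length - self.overlap

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.window_length) // self.hop + 1


@dataclass
class SpectrogramImage:
    pixels: np.ndarray  # (H, W) in [0, 1]
    source_id: str
    label: str | None = None
    time_step: float | None = None  # seconds per pre-resize column
    freq_step: float | None = None  # per-row step, normalized rad/sample


def stft_magnitude(record: PCGRecord, cfg: STFTConfig) -> np.ndarray:
    """Raw STFT magnitude grid, shape (fft_length//2 + 1, n_frames).

    Magnitudes are the unscaled DFT of each Hamming-windowed frame, i.e.
    ``|sum_n w[n] x[n] e^{-2 pi i k n / Nfft}|``.
    """
    x = np.asarray(record.samples, dtype=np.float64)
    if len(x) < cfg.window_length:
        raise ValueError(
            f"record {record.id!r}: {len(x)} samples < one window "
            f"({cfg.window_length})"
        )
    win = sps.get_window("hamming", cfg.window_length, fftbins=True)
    if cfg.matlab_truncate and cfg.fft_length < cfg.window_length:
        # literal-setting compatibility: windowed frame cut to fft_length
        n_frames = cfg.n_frames(len(x))
        idx = np.arange(cfg.window_length) + cfg.hop * np.arange(n_frames)[:, None]
        frames = x[idx] * win
        mag = np.abs(np.fft.rfft(frames[:, : cfg.fft_length], axis=1)).T
        return mag
    _, _, spec = sps.spectrogram(
        x,
        fs=record.rate,
        window=win,
        nperseg=cfg.window_length,
        noverlap=cfg.overlap,
        nfft=cfg.fft_length,
        detrend=False,
        scaling="spectrum",
        mode="complex",
    )
    # scipy's spectrum scaling divides by the window sum; undo it to get the
    # raw DFT magnitude of each windowed frame
    return np.abs(spec) * win.sum()


def to_image(
    grid: np.ndarray,
    record: PCGRecord | None = None,
    cfg: STFTConfig | None = None,
    out_size: int | None = None,
) -> SpectrogramImage:
    """dB-transform (optional), min-max normalize and resize a magnitude grid.

    Under the dB + min-max pipeline the image is invariant to a constant
    signal gain: scaling the input by c > 0 shifts every dB value by the
    same additive constant, which the min-max rescale removes.
    """
    cfg = cfg or STFTConfig()
    size = out_size or cfg.out_size
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty spectrogram grid")
    if cfg.scale == "db":
        peak = grid.max()
        if peak > 0:
            # normalize by the peak before the dB transform: the epsilon
            # floor then caps dynamic range at -200 dB relative to the peak
            # and a constant signal gain cancels exactly
            grid = grid / peak
        vals = 20.0 * np.log10(grid + DB_EPS)
    else:
        vals = grid
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-12:
        logger.warning(
            "degenerate spectrogram (constant grid)%s -> uniform 0.5 image",
            f" for {record.id!r}" if record else "",
        )
        pixels = np.full((size, size), 0.5)
    else:
        vals = (vals - lo) / (hi - lo)
        pixels = sk_resize(
            vals, (size, size), order=1, mode="edge", anti_aliasing=False
        )
        pixels = np.clip(pixels, 0.0, 1.0)
    return SpectrogramImage(
        pixels=pixels,
        source_id=record.id if record else "",
        label=record.label if record else None,
        time_step=(cfg.hop / record.rate) if record else None,
        freq_step=np.pi / (grid.shape[0] - 1) if grid.shape[0] > 1 else None,
    )


def record_to_image(record: PCGRecord, cfg: STFTConfig | None = None) -> SpectrogramImage:
    cfg = cfg or STFTConfig()
    return to_image(stft_magnitude(record, cfg), record=record, cfg=cfg)


def save_png(img: SpectrogramImage, path: str | Path, colormap: str | None = None) -> Path:
    """Export for inspection: 8-bit grayscale, or colormapped RGB."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # flip so low frequencies sit at the bottom, as spectrograms are drawn
    arr = img.pixels[::-1]
    if colormap is None:
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)
    else:
        import matplotlib.cm as cm

        rgba = getattr(cm, colormap)(arr)
        Image.fromarray((rgba[..., :3] * 255).round().astype(np.uint8)).save(path)
    return path


def batch_convert(
    manifest: DatasetManifest,
    cfg: STFTConfig,
    out_dir: str | Path,
    target_rate: int = 2000,
) -> Path:
    """Convert every manifest entry to an image array on disk.

    Writes one ``<id>.npy`` per record plus an ``index.csv`` mapping
    id -> image path + label.  Per-record failures are logged and skipped;
    the index lists only successes.  Deterministic given identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    failures = []
    for path, label in manifest.entries:
        try:
            rec = read_record(path, label=label, target_rate=target_rate)
            img = record_to_image(rec, cfg)
        except Exception as e:
            logger.warning("skipping %s: %s", path, e)
            failures.append((str(path), str(e)))
            continue
        npy = out_dir / f"{rec.id}.npy"
        np.save(npy, img.pixels.astype(np.float32))
        rows.append((rec.id, npy.name, label))
    index = out_dir / "index.csv"
    with open(index, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "image", "label"])
        w.writerows(rows)
    if failures:
        logger.warning("batch_convert: %d of %d records failed", len(failures), len(manifest))
    return index


def load_image_store(index_path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Load a batch_convert output: (images (N,H,W) float32, ids, labels)."""
    index_path = Path(index_path)
    images, ids, labels = [], [], []
    with open(index_path, newline="") as fh:
        for row in csv.DictReader(fh):
            images.append(np.load(index_path.parent / row["image"]))
            ids.append(row["id"])
            labels.append(row["label"])
    if not images:
        raise ValueError(f"empty image index: {index_path}")
    return np.stack(images), ids, labels
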