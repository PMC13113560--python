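"""Log-mel spectrogram frontend for bioacoustic recordings.

A raw recording (any sample rate, mono or multichannel) is converted into the
fixed-size, normalized time-frequency matrix the audio encoder consumes:

1. decode and average channels to mono, resample to 16 kHz;
2. STFT with a 1024-sample Hann window and 320-sample hop, centered
   (reflect-padded) framing;
3. project the power spectrum onto 64 triangular mel filters (HTK mel scale)
   spanning 50-8000 Hz and take the natural log (floored);
4. center-crop or zero-pad the time axis to 501 frames;
5. standardize the whole matrix to zero mean / unit variance per sample.

A 10 s clip at 16 kHz yields exactly 64 x 501: floor(160000/320) + 1 = 501
frames under centered framing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly, get_window

__all__ = [
    "FrontendParams",
    "Waveform",
    "LogMelSpectrogram",
    "load_and_resample",
    "logmel_spectrogram",
    "fit_time_axis",
    "normalize_spectrogram",
    "compute_logmel",
    "mel_filterbank",
    "mel_center_frequencies",
    "save_spectrogram",
    "load_spectrogram",
]


@dataclass(frozen=True)
class FrontendParams:
    """STFT / mel / shaping parameters of the audio frontend.

    Defaults produce the canonical normalized 64 x 501 spectrogram from a
    10 s clip.
    """

    target_rate: int = 16000
    win_length: int = 1024
    hop_length: int = 320
    n_mels: int = 64
    f_min: float = 50.0
    f_max: float = 8000.0
    target_frames: int = 501
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if not (0 <= self.f_min < self.f_max <= self.target_rate / 2):
            raise ValueError(
                f"need 0 <= f_min < f_max <= Nyquist, got "
                f"({self.f_min}, {self.f_max}) at rate {self.target_rate}"
            )
        if self.hop_length > self.win_length:
            raise ValueError("hop_length must not exceed win_length")
        if self.hop_length <= 0 or self.win_length <= 0:
            raise ValueError("window and hop must be positive")
        if self.target_frames < 1:
            raise ValueError("target_frames must be >= 1")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "FrontendParams":
        """Build from a config dict (the ``frontend`` section)."""
        return cls(**{k: v for k, v in cfg.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal with its sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D)")
        if samples.size == 0:
            raise ValueError("Waveform is empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class LogMelSpectrogram:
    """Log-amplitude mel spectrogram, shape ``(n_mels, n_frames)``."""

    values: np.ndarray
    params: FrontendParams

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("spectrogram must be 2-D (n_mels, n_frames)")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrogram contains non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n_mels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Map integer PCM to [-1, 1]; pass floats through."""
    if samples.dtype == np.int16:
        return samples / 32768.0
    if samples.dtype == np.int32:
        return samples / 2147483648.0
    if samples.dtype == np.uint8:
        return (samples.astype(np.float64) - 128.0) / 128.0
    return samples.astype(np.float64)


def load_and_resample(
    source: str | Path | Waveform, params: FrontendParams | None = None
) -> Waveform:
    """Load audio, average channels to mono, resample to ``target_rate``.

    ``source`` may be a WAV path or an already-loaded :class:`Waveform`.
    """
    params = params or FrontendParams()
    if isinstance(source, Waveform):
        wave = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"audio file not found: {path}")
        try:
            rate, samples = wavfile.read(str(path))
        except Exception as exc:  # noqa: BLE001 - rewrap with path context
            raise ValueError(f"could not decode audio file {path}: {exc}") from exc
        if samples.size == 0:
            raise ValueError(f"audio file {path} holds a zero-length signal")
        samples = _to_float(np.asarray(samples))
        if samples.ndim == 2:  # (n, channels) -> mono before resampling
            samples = samples.mean(axis=1)
        wave = Waveform(samples=samples, sample_rate=int(rate))

    if wave.sample_rate == params.target_rate:
        return wave
    g = math.gcd(wave.sample_rate, params.target_rate)
    resampled = resample_poly(
        wave.samples, params.target_rate // g, wave.sample_rate // g
    )
    return Waveform(samples=resampled, sample_rate=params.target_rate)


def mel_center_frequencies(params: FrontendParams) -> np.ndarray:
    """Center frequencies (Hz) of the triangular mel filters."""
    return _mel_points(params)[1:-1]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def _mel_points(params: FrontendParams) -> np.ndarray:
    mels = np.linspace(
        _hz_to_mel(params.f_min), _hz_to_mel(params.f_max), params.n_mels + 2
    )
    return _mel_to_hz(mels)


def mel_filterbank(params: FrontendParams) -> np.ndarray:
    """Triangular mel filterbank, shape ``(n_mels, win_length//2 + 1)``.

    HTK mel scale, unit-peak triangles (no area normalization).
    """
    n_fft_bins = params.win_length // 2 + 1
    fft_freqs = np.fft.rfftfreq(params.win_length, d=1.0 / params.target_rate)
    pts = _mel_points(params)
    weights = np.zeros((params.n_mels, n_fft_bins))
    for i in range(params.n_mels):
        lower = (fft_freqs - pts[i]) / max(pts[i + 1] - pts[i], 1e-12)
        upper = (pts[i + 2] - fft_freqs) / max(pts[i + 2] - pts[i + 1], 1e-12)
        weights[i] = np.maximum(0.0, np.minimum(lower, upper))
    return weights


def _frame_count(n_samples: int, hop_length: int) -> int:
    # centered framing: one frame anchored at every hop multiple in-signal
    return n_samples // hop_length + 1


def logmel_spectrogram(w: Waveform, params: FrontendParams | None = None) -> LogMelSpectrogram:
    """STFT power -> mel projection -> floored natural log.

    Centered (reflect-padded) framing: ``floor(L / hop) + 1`` frames for an
    L-sample input.
    """
    params = params or FrontendParams()
    if w.sample_rate != params.target_rate:
        raise ValueError(
            f"waveform rate {w.sample_rate} != frontend rate {params.target_rate}; "
            "call load_and_resample first"
        )
    x = w.samples
    if x.size < params.hop_length:
        raise ValueError(
            f"waveform of {x.size} samples is shorter than one hop "
            f"({params.hop_length})"
        )
    half = params.win_length // 2
    padded = np.pad(x, half, mode="reflect")
    n_frames = _frame_count(x.size, params.hop_length)
    window = get_window("hann", params.win_length, fftbins=True)
    idx = (
        np.arange(params.win_length)[None, :]
        + params.hop_length * np.arange(n_frames)[:, None]
    )
    frames = padded[idx] * window
    power = np.abs(np.fft.rfft(frames, n=params.win_length, axis=1)) ** 2
    mel_power = power @ mel_filterbank(params).T  # (n_frames, n_mels)
    values = np.log(np.maximum(mel_power, params.log_floor)).T
    return LogMelSpectrogram(values=values, params=params)


def fit_time_axis(s: LogMelSpectrogram, target_frames: int | None = None) -> LogMelSpectrogram:
    """Center-crop or symmetrically zero-pad the time axis to ``target_frames``.

    When the excess (or deficit) is odd the extra column is dropped from (or
    added to) the trailing side.
    """
    if target_frames is None:
        target_frames = s.params.target_frames
    if target_frames < 1:
        raise ValueError("target_frames must be >= 1")
    n = s.n_frames
    if n == target_frames:
        values = s.values
    elif n > target_frames:
        left = (n - target_frames) // 2
        values = s.values[:, left : left + target_frames]
    else:
        deficit = target_frames - n
        left = deficit // 2
        values = np.pad(s.values, ((0, 0), (left, deficit - left)))
    params = replace(s.params, target_frames=target_frames)
    return LogMelSpectrogram(values=values, params=params)


def normalize_spectrogram(s: LogMelSpectrogram, eps: float = 1e-8) -> LogMelSpectrogram:
    """Per-sample standardization over all cells; constant input -> zeros."""
    v = s.values
    std = v.std()
    values = (v - v.mean()) / max(std, eps)
    return LogMelSpectrogram(values=values, params=s.params)


def compute_logmel(
    source: str | Path | Waveform, params: FrontendParams | None = None
) -> LogMelSpectrogram:
    """Full pipeline: load/resample -> log-mel -> fit time axis -> normalize."""
    params = params or FrontendParams()
    wave = load_and_resample(source, params)
    spec = logmel_spectrogram(wave, params)
    spec = fit_time_axis(spec, params.target_frames)
    return normalize_spectrogram(spec)


def save_spectrogram(path: str | Path, s: LogMelSpectrogram) -> None:
    """Cache a spectrogram as ``.npy`` with a JSON parameter sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), s.values)
    path.with_suffix(".json").write_text(json.dumps(asdict(s.params), indent=2))


def load_spectrogram(path: str | Path) -> LogMelSpectrogram:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    params = FrontendParams(**json.loads(path.with_suffix(".json").read_text()))
    return LogMelSpectrogram(values=values, params=params)
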