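"""1D signal preprocessing: filtering, resampling, padding, input assembly.

The chain mirrors standard AI-ECG practice: zero-phase 0.5–100 Hz band-pass,
60 Hz powerline notch, resampling to 400 Hz, then symmetric zero-padding to
the next power of two (4096 samples for a 10-s recording). Models consume
only the 8 independent leads, optionally masked to the asynchronous 2.5-s
paper-layout windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signals import ECGSignal, INDEPENDENT_LEADS


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter corner frequencies and output rate.

    band_low/band_high: band-pass corners in Hz. notch: powerline frequency
    in Hz (60 for US data; set 50 where applicable). fs_out: output rate.
    """

    band_low: float = 0.5
    band_high: float = 100.0
    notch: float = 60.0
    notch_q: float = 30.0
    fs_out: float = 400.0
    bp_order: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= self.fs_out / 2:
            raise ValueError("band_high must be below the output Nyquist rate")


DEFAULT_CONFIG = PreprocessConfig()


def apply_filters(x: np.ndarray, fs: float, config: PreprocessConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Zero-phase band-pass + notch along the last axis.

    Butterworth band-pass (order ``bp_order``) and an IIR notch, both run
    forward-backward (filtfilt) so the trace is not phase-shifted. The upper
    band edge is clipped just below the input Nyquist frequency when the
    input rate is low (e.g. pixel-rate signals from the digitizer).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    nyq = fs / 2.0
    high = min(config.band_high, 0.95 * nyq)
    # separate high/low-pass stages in ba form so Gustafsson edge handling is
    # available; it matters on short asynchronous windows where reflection
    # padding of a truncated beat distorts the sub-Hz response
    bh, ah = sps.butter(config.bp_order, config.band_low, btype="highpass", fs=fs)
    bl, al = sps.butter(config.bp_order, high, btype="lowpass", fs=fs)
    y = sps.filtfilt(bh, ah, x, axis=-1, method="gust")
    y = sps.filtfilt(bl, al, y, axis=-1, method="gust")
    if config.notch < nyq:
        b, a = sps.iirnotch(config.notch, config.notch_q, fs=fs)
        y = sps.filtfilt(b, a, y, axis=-1, method="gust")
    return y


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase rational resampling along the last axis."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)


def filter_resample(signal: ECGSignal, config: PreprocessConfig = DEFAULT_CONFIG) -> ECGSignal:
    """Band-pass + notch, then resample to ``config.fs_out``."""
    y = apply_filters(signal.samples, signal.fs, config)
    y = resample_to(y, signal.fs, config.fs_out)
    return ECGSignal(y, config.fs_out, signal.lead_names)


def pad_power_of_two(samples: np.ndarray) -> np.ndarray:
    """Symmetric zero-padding of the last axis to the next power of two.

    A 4000-sample (10 s at 400 Hz) lead becomes 4096 with 48 zeros at each
    end; lengths already a power of two pass through unchanged. For odd
    deficits the extra zero goes at the end.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[-1]
    target = 1 << (n - 1).bit_length()
    if target == n:
        return x
    before = (target - n) // 2
    after = target - n - before
    pad = [(0, 0)] * (x.ndim - 1) + [(before, after)]
    return np.pad(x, pad)


def select_independent_leads(signal: ECGSignal) -> ECGSignal:
    """Keep the 8 independent leads (I, II, V1–V6), in that order."""
    missing = [name for name in INDEPENDENT_LEADS if name not in signal.lead_names]
    if missing:
        raise ValueError(f"missing lead(s): {', '.join(missing)}")
    if set(signal.lead_names) == set(INDEPENDENT_LEADS):
        raise ValueError("signal already reduced to the 8 independent leads (III absent)")
    rows = np.stack([signal.lead(name) for name in INDEPENDENT_LEADS])
    return ECGSignal(rows, signal.fs, INDEPENDENT_LEADS)


def apply_async_mask(signal: ECGSignal, lead_columns: dict[str, int],
                     seconds_per_column: float = 2.5) -> ECGSignal:
    """Zero each lead outside its paper-layout column window.

    Lead in column c keeps samples in [c*2.5 s, (c+1)*2.5 s) and is zero
    elsewhere, reproducing the asynchronous acquisition of a printed page.
    Applied on the unpadded frame so the window arithmetic is exact.
    """
    out = signal.samples.copy()
    win = int(round(seconds_per_column * signal.fs))
    for i, name in enumerate(signal.lead_names):
        if name not in lead_columns:
            raise ValueError(f"lead {name!r} has no column assignment")
        c = lead_columns[name]
        lo, hi = c * win, (c + 1) * win
        out[i, :lo] = 0.0
        out[i, hi:] = 0.0
    return ECGSignal(out, signal.fs, signal.lead_names)


def assemble_model_input(
    signal: ECGSignal,
    config: PreprocessConfig = DEFAULT_CONFIG,
    lead_columns: dict[str, int] | None = None,
    already_filtered: bool = False,
) -> np.ndarray:
    """Full 1D input pipeline: filter → resample → (async mask) → 8 leads → pad.

    Returns a (4096, 8) array for a 10-s recording. Pass ``lead_columns``
    to produce the asynchronous 2.5-s representation; omit it for the
    synchronous 10-s one. ``already_filtered`` skips the filter/resample
    stage for signals that went through it upstream (e.g. digitized output).
    """
    sig = signal if already_filtered else filter_resample(signal, config)
    if lead_columns is not None:
        sig = apply_async_mask(sig, lead_columns)
    sig = select_independent_leads(sig)
    return pad_power_of_two(sig.samples).T
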