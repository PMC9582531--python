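"""Morlet decomposition, gait-cycle warping, ERSP and GPM computation.

Power is decomposed on a linear frequency grid with complex Morlet wavelets,
gait cycles are cut between consecutive right-heel strikes, gated on a
time-domain amplitude threshold, linearly warped onto 100 phase bins
(bin 0 at the right heel strike), averaged, expressed in dB against the
time-averaged standing power, and finally zero-meaned across phase per
frequency to isolate within-cycle modulation (the GPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from gaitgpm.gait import GaitCycle
from gaitgpm.preprocess import EEGRecording


@dataclass
class TFParams:
    freqs_hz: np.ndarray = field(default_factory=lambda: np.arange(2.0, 61.0, 2.0))
    stats_band_hz: tuple[float, float] = (6.0, 40.0)
    n_phase_bins: int = 100
    cycle_amp_threshold_uv: float = 350.0
    # wavelet width: linear in frequency between the two anchors
    n_cycles_rule: tuple[float, float] = (3.0, 8.0)  # at min and max frequency
    fixed_n_cycles: float | None = None

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.n_phase_bins < 2:
            raise ValueError("need at least 2 phase bins")

    def n_cycles(self) -> np.ndarray:
        if self.fixed_n_cycles is not None:
            return np.full(len(self.freqs_hz), float(self.fixed_n_cycles))
        f = self.freqs_hz
        lo, hi = self.n_cycles_rule
        return lo + (hi - lo) * (f - f[0]) / max(f[-1] - f[0], 1e-12)


@dataclass
class TFPower:
    """Power (μV²) per channel x frequency x sample, with edge flags."""

    power: np.ndarray          # (n_ch, n_freq, n_samp), float32
    freqs_hz: np.ndarray
    fs: float
    edge: np.ndarray           # (n_freq, n_samp) bool: inside a half-wavelet of an edge

    @property
    def n_samples(self) -> int:
        return self.power.shape[-1]


@dataclass
class BaselinePower:
    power: np.ndarray  # (n_ch, n_freq), μV², strictly positive
    freqs_hz: np.ndarray
    duration_s: float


@dataclass
class GaitERSP:
    values_db: np.ndarray  # (n_ch, n_freq, n_phase)
    freqs_hz: np.ndarray
    ch_names: list[str]
    n_cycles: int
    condition: str = ""


# GPM shares the container; constructed via ersp_to_gpm
GPM = GaitERSP


def _morlet(freq: float, n_cyc: float, fs: float) -> np.ndarray:
    sigma_t = n_cyc / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return wav / np.sqrt(np.sum(np.abs(wav) ** 2))


def morlet_power(rec: EEGRecording, params: TFParams | None = None) -> TFPower:
    """Squared-magnitude Morlet convolution on the configured grid.

    Wavelets are L2-normalized; a pure sinusoid of amplitude ``a`` at a grid
    frequency therefore yields power proportional to ``a**2``, which is all
    that dB baselining requires.
    """
    params = params or TFParams()
    if rec.fs < 2 * params.freqs_hz[-1]:
        raise ValueError("sampling rate below Nyquist for the frequency grid")
    n = rec.n_samples
    ncyc = params.n_cycles()
    widest = int(np.ceil(5 * ncyc[0] / (2 * np.pi * params.freqs_hz[0]) * rec.fs)) * 2 + 1
    if n < widest:
        raise ValueError("recording shorter than the widest wavelet")
    power = np.empty((rec.n_channels, len(params.freqs_hz), n), dtype=np.float32)
    edge = np.zeros((len(params.freqs_hz), n), dtype=bool)
    wavelets = [_morlet(f0, nc, rec.fs) for f0, nc in zip(params.freqs_hz, ncyc)]
    # single forward FFT of the data, reused across all wavelets
    from scipy.fft import fft, ifft, next_fast_len

    nfft = next_fast_len(n + max(len(w) for w in wavelets) - 1)
    X = fft(rec.data, nfft, axis=-1)
    for fi, wav in enumerate(wavelets):
        half = (len(wav) - 1) // 2
        W = fft(wav, nfft)
        conv = ifft(X * W[np.newaxis, :], axis=-1)[:, half:half + n]
        power[:, fi, :] = (np.abs(conv) ** 2).astype(np.float32)
        edge[fi, :half] = True
        edge[fi, n - half:] = True
    return TFPower(power, params.freqs_hz.copy(), rec.fs, edge)


def standing_baseline_power(tf: TFPower, intervals: list[tuple[float, float]],
                            min_duration_s: float = 30.0) -> BaselinePower:
    """Time-mean power per channel x frequency over standing intervals.

    Edge-flagged samples are excluded.  Multiple disjoint intervals are
    pooled, which weights them by their (unflagged) duration.
    """
    masks = np.zeros(tf.n_samples, dtype=bool)
    for t0, t1 in intervals:
        i0, i1 = int(round(t0 * tf.fs)), int(round(t1 * tf.fs))
        masks[max(i0, 0):min(i1, tf.n_samples)] = True
    out = np.empty(tf.power.shape[:2])
    total = 0.0
    for fi in range(tf.power.shape[1]):
        sel = masks & ~tf.edge[fi]
        if fi == 0:
            total = sel.sum() / tf.fs
        if sel.sum() / tf.fs < min_duration_s:
            raise ValueError(
                f"standing interval too short: {sel.sum() / tf.fs:.1f} s unflagged "
                f"(< {min_duration_s} s) at {tf.freqs_hz[fi]} Hz")
        out[:, fi] = tf.power[:, fi, sel].mean(axis=-1)
    if np.any(out <= 0):
        raise ValueError("zero baseline power: dB baseline undefined")
    return BaselinePower(out, tf.freqs_hz.copy(), total)


def extract_and_warp_cycles(tf: TFPower, rec: EEGRecording,
                            cycles: list[GaitCycle],
                            params: TFParams | None = None
                            ) -> tuple[np.ndarray, dict]:
    """Per-cycle power warped to the uniform phase grid.

    Returns (segments (n_kept, n_ch, n_freq, n_bins), bookkeeping dict).
    A cycle is excluded when any time-domain sample within it exceeds the
    amplitude threshold on any channel.
    """
    params = params or TFParams()
    nb = params.n_phase_bins
    kept: list[np.ndarray] = []
    n_excluded = 0
    t = np.arange(tf.n_samples) / tf.fs
    for cyc in cycles:
        if not cyc.valid:
            continue
        i0 = int(np.ceil(cyc.rhs * rec.fs))
        i1 = int(np.floor(cyc.rhs_next * rec.fs))
        if i1 <= i0 + 2 or i1 > rec.n_samples:
            n_excluded += 1
            continue
        if np.abs(rec.data[:, i0:i1 + 1 if i1 < rec.n_samples else i1]).max() \
                > params.cycle_amp_threshold_uv:
            n_excluded += 1
            continue
        # linear interpolation of the power envelope onto the phase grid
        tq = cyc.rhs + (cyc.rhs_next - cyc.rhs) * (np.arange(nb) / nb)
        seg_t = t[i0:i1 + 1] if i1 + 1 <= tf.n_samples else t[i0:i1]
        block = tf.power[:, :, i0:i0 + len(seg_t)].astype(float)
        # vectorized np.interp over the (channel, freq) leading axes
        idx = np.clip(np.searchsorted(seg_t, tq) - 1, 0, len(seg_t) - 2)
        w = (tq - seg_t[idx]) / (seg_t[idx + 1] - seg_t[idx])
        warped = block[:, :, idx] * (1 - w) + block[:, :, idx + 1] * w
        kept.append(warped)
    info = {"n_valid": sum(c.valid for c in cycles), "n_excluded": n_excluded,
            "n_kept": len(kept)}
    segments = np.stack(kept) if kept else np.empty((0, tf.power.shape[0],
                                                     tf.power.shape[1], nb))
    return segments, info


def average_to_ersp(segments: np.ndarray, baseline: BaselinePower,
                    ch_names: list[str], condition: str = "") -> GaitERSP:
    """ERSP = 10*log10(mean cycle power / standing baseline power)."""
    if segments.shape[0] < 1:
        raise ValueError("need at least one warped cycle")
    if np.any(baseline.power <= 0):
        raise ValueError("baseline power must be strictly positive")
    mean_power = segments.mean(axis=0)
    vals = 10.0 * np.log10(mean_power / baseline.power[:, :, np.newaxis])
    return GaitERSP(vals, baseline.freqs_hz.copy(), list(ch_names),
                    n_cycles=segments.shape[0], condition=condition)


def ersp_to_gpm(ersp: GaitERSP) -> GPM:
    """Subtract each (channel, frequency) row's mean across phase bins."""
    if not np.all(np.isfinite(ersp.values_db)):
        raise ValueError("ERSP contains non-finite values")
    vals = ersp.values_db - ersp.values_db.mean(axis=-1, keepdims=True)
    return GaitERSP(vals, ersp.freqs_hz.copy(), list(ersp.ch_names),
                    ersp.n_cycles, ersp.condition)
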