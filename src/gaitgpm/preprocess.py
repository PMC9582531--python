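"""EEG cleaning chain with testable stages and pluggable stand-ins.

Stage order: resample/band-pass -> bad-channel detection -> (burst-correction
hook) -> line-noise removal -> spherical interpolation of bads -> full-rank
common average reference -> ICA-based eye-artifact removal.

Externally defined black-box stages (burst correction, the mixture-ICA
decomposition and the component classifier of the original tool chain) are
replaced by documented stand-ins behind the same contracts: a no-op hook,
FastICA with a fixed seed, and a heuristic eye score (frontal topography
weight x low-frequency power fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from gaitgpm.montage import ChannelLayout, position_for


@dataclass
class EEGRecording:
    """Channel x sample EEG matrix in microvolts with layout and events."""

    data: np.ndarray  # (n_channels, n_samples), μV
    fs: float
    layout: ChannelLayout
    events: list[tuple[str, float]] = field(default_factory=list)
    bads: set[str] = field(default_factory=set)
    reference: str = "FCz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data must be (n_channels, n_samples) matching layout")
        dur = self.duration
        for label, lat in self.events:
            if not 0 <= lat <= dur:
                raise ValueError(f"event {label!r} at {lat} s outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.fs, self.layout,
                            list(self.events), set(self.bads), self.reference)

    def event_latency(self, label: str) -> float:
        for lab, lat in self.events:
            if lab == label:
                return lat
        raise KeyError(label)


@dataclass
class PreprocParams:
    target_rate_hz: float = 250.0
    band_hz: tuple[float, float] = (0.2, 60.0)
    flatline_s: float = 5.0
    corr_floor: float = 0.8
    line_noise_criterion: float = 4.0
    asr_cutoff_sd: float = 20.0  # consumed by the burst-correction hook only
    epoch_amp_threshold_uv: float = 350.0
    jointprob_sd: float = 3.0
    eye_prob_cutoff: float = 0.90
    line_freq_hz: float = 50.0
    ica_highpass_hz: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band edges must be ordered and positive")


@dataclass
class ICDecomposition:
    unmixing: np.ndarray  # (n_comp, n_channels)
    mixing: np.ndarray    # (n_channels, n_comp)
    mean: np.ndarray      # (n_channels,)
    eye_scores: np.ndarray
    removed: list[int]


def fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis with delay compensation.

    Edges are reflection-padded by half the kernel length.
    """
    taps = np.asarray(taps)
    half = (len(taps) - 1) // 2
    pad = min(half, data.shape[-1] - 1)
    padded = np.concatenate(
        [data[..., 1:pad + 1][..., ::-1], data, data[..., -pad - 1:-1][..., ::-1]],
        axis=-1)
    out = signal.fftconvolve(padded, taps[np.newaxis, :] if data.ndim == 2 else taps,
                             mode="full", axes=-1)
    start = half + pad
    return out[..., start:start + data.shape[-1]]


def _bandpass_taps(fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    # transition reaching from ~lo/4 (stopband) up to the passband edge
    n = int(3.3 / (lo * 0.75) * fs) | 1
    return signal.firwin(n, [lo * 0.625, hi * 1.05], pass_zero=False, fs=fs)


def resample_and_filter(rec: EEGRecording, params: PreprocParams | None = None) -> EEGRecording:
    """Downsample to the target rate, then zero-phase FIR band-pass."""
    params = params or PreprocParams()
    if rec.fs < 2 * params.band_hz[1]:
        raise ValueError("sampling rate below Nyquist requirement for the upper band edge")
    data, fs = rec.data, rec.fs
    if fs != params.target_rate_hz:
        from fractions import Fraction

        frac = Fraction(params.target_rate_hz / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        fs = params.target_rate_hz
    data = fir_zero_phase(data, _bandpass_taps(fs, params.band_hz))
    return EEGRecording(data, fs, rec.layout, list(rec.events), set(rec.bads), rec.reference)


def _spline_gram(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) evaluated via a Legendre series."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness) / (4 * np.pi)
    # legval expects coefficients from degree 0
    c = np.concatenate([[0.0], coef])
    return np.polynomial.legendre.legval(np.clip(cosang, -1.0, 1.0), c)


def _interpolation_operator(pos_good: np.ndarray, pos_bad: np.ndarray,
                            reg: float = 1e-5) -> np.ndarray:
    """Operator A with V_bad = A @ V_good (spherical-spline interpolation)."""
    k = len(pos_good)
    G = _spline_gram(pos_good @ pos_good.T) + reg * np.eye(k)
    Gb = _spline_gram(pos_bad @ pos_good.T)
    C = np.zeros((k + 1, k + 1))
    C[:k, :k] = G
    C[:k, k] = 1.0
    C[k, :k] = 1.0
    Cinv = np.linalg.solve(C, np.eye(k + 1))
    return np.hstack([Gb, np.ones((len(pos_bad), 1))]) @ Cinv[:, :k]


def find_bad_channels(rec: EEGRecording, params: PreprocParams | None = None) -> set[str]:
    """Flag flatline, poorly correlated, and line-noise-dominated channels."""
    params = params or PreprocParams()
    if rec.n_channels < 8:
        raise ValueError("bad-channel detection needs at least 8 channels")
    bads: set[str] = set()
    X, fs, names = rec.data, rec.fs, rec.layout.names

    # 1) flatline for >= flatline_s
    min_run = int(params.flatline_s * fs)
    for i, name in enumerate(names):
        flat = np.abs(np.diff(X[i])) < 1e-10
        if flat.size and _longest_run(flat) >= min_run:
            bads.add(name)

    # 2) correlation with the spherical-spline prediction from all others
    pos = rec.layout.positions
    for i, name in enumerate(names):
        if name in bads:
            continue
        others = [j for j in range(rec.n_channels) if j != i and names[j] not in bads]
        A = _interpolation_operator(pos[others], pos[i:i + 1])
        pred = (A @ X[others]).ravel()
        denom = np.std(pred) * np.std(X[i])
        r = 0.0 if denom == 0 else float(np.corrcoef(pred, X[i])[0, 1])
        if r < params.corr_floor:
            bads.add(name)

    # 3) line-noise-to-signal ratio, robust z across channels
    f, psd = signal.welch(X, fs=fs, nperseg=min(int(4 * fs), rec.n_samples))
    line_band = (f >= params.line_freq_hz - 1) & (f <= params.line_freq_hz + 1)
    sig_band = (f >= 1) & (f <= 45)
    if line_band.any() and sig_band.any():
        ratio = psd[:, line_band].mean(axis=1) / psd[:, sig_band].mean(axis=1)
        med = np.median(ratio)
        mad = np.median(np.abs(ratio - med)) * 1.4826
        if mad > 0:
            z = (ratio - med) / mad
            for i, name in enumerate(names):
                if z[i] > params.line_noise_criterion:
                    bads.add(name)
    return bads


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[::2]))


def interpolate_bads(rec: EEGRecording) -> EEGRecording:
    """Replace bad channels by spherical-spline interpolation from good ones."""
    if not rec.bads:
        return rec.copy()
    names = rec.layout.names
    good = [i for i, n in enumerate(names) if n not in rec.bads]
    bad = [i for i, n in enumerate(names) if n in rec.bads]
    if len(good) < 4:
        raise ValueError("too few good channels for spherical interpolation")
    pos = rec.layout.positions
    A = _interpolation_operator(pos[good], pos[bad])
    out = rec.copy()
    out.data[bad] = A @ out.data[good]
    out.bads = set()  # interpolated; original set belongs in provenance
    return out


def rereference_car(rec: EEGRecording) -> EEGRecording:
    """Full-rank common average reference.

    The original online reference channel is reconstructed (an all-zero
    channel appended before averaging), so the re-referenced data keep full
    rank and the reference's signal is recoverable.
    """
    if rec.n_channels < 2:
        raise ValueError("common average undefined for a single channel")
    out = rec.copy()
    if rec.reference and rec.reference not in rec.layout.names and rec.reference != "CAR":
        names = rec.layout.names + [rec.reference]
        pos = np.vstack([rec.layout.positions, position_for(rec.reference)])
        layout = ChannelLayout(names=names, positions=pos, reference=rec.reference)
        data = np.vstack([rec.data, np.zeros((1, rec.n_samples))])
        out = EEGRecording(data, rec.fs, layout, list(rec.events), set(rec.bads), rec.reference)
    out.data -= out.data.mean(axis=0, keepdims=True)
    out.reference = "CAR"
    return out


def remove_line_noise(rec: EEGRecording, params: PreprocParams | None = None) -> EEGRecording:
    """Subtract a sliding-window least-squares fit of the line sinusoid.

    Stand-in for the dedicated line-noise tool: per overlapping Hann window,
    sine and cosine at the line frequency (and in-band harmonics) are fitted
    per channel and the windowed fit is subtracted via overlap-add.
    """
    params = params or PreprocParams()
    f0, fs = params.line_freq_hz, rec.fs
    if fs <= 2 * f0:
        raise ValueError("sampling rate too low for line-noise removal")
    win_len = int(round(2.0 * fs))
    hop = win_len // 2
    n = rec.n_samples
    if n < win_len:
        win_len, hop = n, max(1, n // 2)
    window = np.hanning(win_len)
    freqs = [f0 * k for k in range(1, int(fs / 2 / f0) + 1) if f0 * k < fs / 2 * 0.95]
    t = np.arange(n) / fs
    fitted = np.zeros_like(rec.data)
    weight = np.zeros(n)
    starts = list(range(0, max(1, n - win_len + 1), hop))
    if starts[-1] + win_len < n:
        starts.append(n - win_len)
    for s in starts:
        sl = slice(s, s + win_len)
        tt = t[sl]
        basis = np.vstack([fn(2 * np.pi * fq * tt) for fq in freqs for fn in (np.sin, np.cos)]).T
        coef, *_ = np.linalg.lstsq(basis, rec.data[:, sl].T, rcond=None)
        fitted[:, sl] += (basis @ coef).T * window
        weight[sl] += window
    good = weight > 1e-12
    fitted[:, good] /= weight[good]
    out = rec.copy()
    out.data = rec.data - fitted
    return out


def reject_artifact_epochs(rec: EEGRecording, epoch_len_s: float,
                           params: PreprocParams | None = None) -> np.ndarray:
    """Keep-mask over consecutive non-overlapping epochs.

    An epoch is dropped if any sample exceeds the absolute amplitude
    threshold, or if any channel's mean negative log-probability (under that
    channel's empirical amplitude distribution) is more than ``jointprob_sd``
    standard deviations above the epoch population mean.
    """
    params = params or PreprocParams()
    if epoch_len_s <= 0:
        raise ValueError("epoch length must be positive")
    ep = int(round(epoch_len_s * rec.fs))
    n_ep = rec.n_samples // ep
    if n_ep == 0:
        return np.zeros(0, dtype=bool)
    X = rec.data[:, :n_ep * ep].reshape(rec.n_channels, n_ep, ep)

    keep = np.abs(X).max(axis=(0, 2)) <= params.epoch_amp_threshold_uv

    # empirical per-channel amplitude log-density via histogram
    nll = np.empty((rec.n_channels, n_ep))
    for c in range(rec.n_channels):
        x = rec.data[c, :n_ep * ep]
        hist, edges = np.histogram(x, bins=100, density=True)
        idx = np.clip(np.digitize(X[c], edges) - 1, 0, 99)
        logp = np.log(np.maximum(hist[idx], 1e-12))
        nll[c] = -logp.mean(axis=1)
    mu = nll.mean(axis=1, keepdims=True)
    sd = nll.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    z = (nll - mu) / sd
    keep &= (z.max(axis=0) <= params.jointprob_sd)
    return keep


def ica_eye_removal(rec: EEGRecording, params: PreprocParams | None = None,
                    seed: int = 0) -> tuple[EEGRecording, ICDecomposition]:
    """Remove eye-movement/blink components identified by a heuristic score.

    The decomposition is fitted on a 1 Hz high-passed copy restricted to
    clean 1-s epochs; the unmixing weights are then applied to the original
    recording.  A component's eye score is its low-frequency (<3 Hz) source
    power fraction scaled by the frontal concentration of its topography,
    mapped to [0, 1]; components scoring above the cutoff are removed.
    """
    params = params or PreprocParams()
    taps = signal.firwin(int(3.3 / (params.ica_highpass_hz / 2) * rec.fs) | 1,
                         params.ica_highpass_hz / 2, pass_zero=False, fs=rec.fs)
    hp = rec.copy()
    hp.data = fir_zero_phase(rec.data, taps)
    keep = reject_artifact_epochs(hp, 1.0, params)
    ep = int(round(rec.fs))
    segs = [hp.data[:, i * ep:(i + 1) * ep] for i in np.flatnonzero(keep)]
    fit_data = np.concatenate(segs, axis=1) if segs else hp.data

    # rank after a common average reference is n_channels - 1
    ev = np.linalg.eigvalsh(np.cov(fit_data))
    rank = int((ev > ev.max() * 1e-10).sum())
    n_comp = min(rank, rec.n_channels)

    ica = S_fit = None
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        for tol in (1e-3, 1e-2):  # retry once with a looser tolerance
            try:
                # deflation: robust to the near-degenerate sensor-noise
                # eigenvalue cluster that stalls the symmetric variant
                ica = FastICA(n_components=n_comp, random_state=seed,
                              algorithm="deflation", max_iter=500, tol=tol,
                              whiten="unit-variance")
                S_fit = ica.fit_transform(fit_data.T).T
                break
            except ConvergenceWarning as err:
                last_err = err
    if S_fit is None:
        raise RuntimeError(
            f"ICA failed to converge on {n_comp} components / "
            f"{fit_data.shape[1]} samples: {last_err}")

    mixing = ica.mixing_  # (n_channels, n_comp)
    unmixing = ica.components_
    mean = ica.mean_

    frontal = rec.layout.indices("frontal")
    scores = np.empty(n_comp)
    for k in range(n_comp):
        a = np.abs(mixing[:, k])
        f_ratio = a[frontal].mean() / max(a.mean(), 1e-30)
        fvec = np.fft.rfftfreq(S_fit.shape[1], 1 / rec.fs)
        pxx = np.abs(np.fft.rfft(S_fit[k])) ** 2
        low = pxx[fvec < 3.0].sum() / max(pxx.sum(), 1e-30)
        # sqrt maps the [0,1] low-frequency fraction onto a probability-like
        # scale where stereotyped blink sources land above 0.9
        scores[k] = float(np.sqrt(np.clip(low, 0, 1)) * min(f_ratio / 1.5, 1.0))

    removed = [k for k in range(n_comp) if scores[k] > params.eye_prob_cutoff]
    decomp = ICDecomposition(unmixing, mixing, mean, scores, removed)
    if not removed:
        return rec.copy(), decomp
    kept = [k for k in range(n_comp) if k not in removed]
    S = unmixing @ (rec.data - mean[:, None])
    out = rec.copy()
    out.data = mixing[:, kept] @ S[kept] + mean[:, None]
    return out, decomp


BurstHook = Callable[[EEGRecording, float], EEGRecording]


def run_preprocessing(rec: EEGRecording, params: PreprocParams | None = None,
                      seed: int = 0, burst_hook: BurstHook | None = None
                      ) -> tuple[EEGRecording, dict]:
    """Full chain with a per-stage provenance log."""
    params = params or PreprocParams()
    prov: dict = {"stages": [], "params": {k: getattr(params, k) for k in vars(params)}}

    rec = resample_and_filter(rec, params)
    prov["stages"].append({"stage": "resample_and_filter", "fs": rec.fs})

    bads = find_bad_channels(rec, params)
    rec = replace_bads(rec, bads)
    prov["stages"].append({"stage": "find_bad_channels", "n_bads": len(bads),
                           "bads": sorted(bads)})

    if burst_hook is not None:
        rec = burst_hook(rec, params.asr_cutoff_sd)
        prov["stages"].append({"stage": "burst_correction", "cutoff_sd": params.asr_cutoff_sd})
    else:
        prov["stages"].append({"stage": "burst_correction", "skipped": True})

    rec = remove_line_noise(rec, params)
    prov["stages"].append({"stage": "remove_line_noise", "line_hz": params.line_freq_hz})

    rec = interpolate_bads(rec)
    prov["stages"].append({"stage": "interpolate_bads", "interpolated": sorted(bads)})

    rec = rereference_car(rec)
    prov["stages"].append({"stage": "rereference_car", "n_channels": rec.n_channels})

    rec, decomp = ica_eye_removal(rec, params, seed=seed)
    prov["stages"].append({
        "stage": "ica_eye_removal", "n_components": len(decomp.eye_scores),
        "n_removed": len(decomp.removed),
        "n_kept": len(decomp.eye_scores) - len(decomp.removed),
        "removed": decomp.removed,
    })
    return rec, prov


def replace_bads(rec: EEGRecording, bads: set[str]) -> EEGRecording:
    out = rec.copy()
    out.bads = set(bads)
    return out


# re-exported for callers composing their own chains
__all__ = [
    "EEGRecording", "PreprocParams", "ICDecomposition",
    "resample_and_filter", "find_bad_channels", "interpolate_bads",
    "rereference_car", "remove_line_noise", "reject_artifact_epochs",
    "ica_eye_removal", "run_preprocessing", "fir_zero_phase",
]
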