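"""Synthetic accelerometer + EEG study generation with ground truth.

Waveform shapes are free choices; the contract is that the standard
detection rules recover the planted events, that planted gait-phase power
modulations are recoverable by the spectral pipeline, and that artifact
structure (double-support EMG bursts, line noise, blinks) is controllable.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sstats

from gaitgpm import io
from gaitgpm.gait import AccelTrace
from gaitgpm.montage import STANDARD_16, make_layout
from gaitgpm.preprocess import EEGRecording

CONDITIONS = ("even_ST", "even_DT", "uneven_ST", "uneven_DT")

# Within-stride relative event offsets.  With these, double support spans
# roughly 0-10% (RHS..LTO) and 50-62% (LHS..RTO) of the cycle.
DEFAULT_OFFSETS = {"lto": 0.10, "lhs": 0.50, "rto": 0.62}


@dataclass
class GaitTimeline:
    """Planted stride structure: RHS latencies per bout + relative offsets."""

    rhs_by_bout: list[np.ndarray]  # each sorted, seconds
    offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    mean_stride_s: float = 1.0
    sd_stride_s: float = 0.0
    bouts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        o = self.offsets
        if not 0 < o["lto"] < o["lhs"] < o["rto"] < 1:
            raise ValueError("event order requires 0 < lto < lhs < rto < 1")
        for rhs in self.rhs_by_bout:
            if np.any(np.diff(rhs) <= 0):
                raise ValueError("stride durations must be positive")

    @property
    def n_strides(self) -> int:
        return sum(max(0, len(r) - 1) for r in self.rhs_by_bout)

    def stride_durations(self) -> np.ndarray:
        if not self.rhs_by_bout:
            return np.empty(0)
        return np.concatenate([np.diff(r) for r in self.rhs_by_bout])

    def event_latencies(self) -> dict[str, np.ndarray]:
        """All planted event latencies (s) by type."""
        out: dict[str, list[float]] = {"RHS": [], "LTO": [], "LHS": [], "RTO": []}
        for rhs in self.rhs_by_bout:
            out["RHS"].extend(rhs)
            for a, d in zip(rhs[:-1], np.diff(rhs)):
                out["LTO"].append(a + self.offsets["lto"] * d)
                out["LHS"].append(a + self.offsets["lhs"] * d)
                out["RTO"].append(a + self.offsets["rto"] * d)
        return {k: np.asarray(sorted(v)) for k, v in out.items()}

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Gait phase in [0, 1) at times t; NaN outside strides."""
        t = np.asarray(t, dtype=float)
        phase = np.full(t.shape, np.nan)
        for rhs in self.rhs_by_bout:
            if len(rhs) < 2:
                continue
            idx = np.searchsorted(rhs, t, side="right") - 1
            ok = (idx >= 0) & (idx < len(rhs) - 1)
            i = idx[ok]
            phase[ok] = (t[ok] - rhs[i]) / (rhs[i + 1] - rhs[i])
        return phase

    @property
    def duration(self) -> float:
        ends = [b[1] for b in self.bouts] + [r[-1] for r in self.rhs_by_bout if len(r)]
        return max(ends) if ends else 0.0


@dataclass
class BandSpec:
    """One gait-phase-locked oscillation: carrier frequency and a cosine
    modulation profile in dB (peak-to-trough = depth)."""

    freq_hz: float
    depth_db: float
    peak_phase: float = 0.05     # phase fraction of maximal power
    cycles_per_stride: int = 2   # modulation periodicity within a stride
    amplitude_uv: float = 4.0

    def profile_db(self, phase: np.ndarray) -> np.ndarray:
        return (self.depth_db / 2.0) * np.cos(
            2 * np.pi * self.cycles_per_stride * (phase - self.peak_phase))


def default_bands(depth_db: float = 2.0) -> dict[str, BandSpec]:
    # theta/alpha peak during double support; beta dips there (sign flip)
    return {
        "theta": BandSpec(6.0, depth_db, peak_phase=0.08),
        "alpha": BandSpec(12.0, depth_db, peak_phase=0.05),
        "beta": BandSpec(24.0, -depth_db, peak_phase=0.05),
    }


@dataclass
class SyntheticStudySpec:
    n_subjects: int = 6
    stride_mean_s: dict[str, float] = field(default_factory=lambda: {
        "even_ST": 1.00, "even_DT": 1.05, "uneven_ST": 1.10, "uneven_DT": 1.15})
    stride_sd_s: dict[str, float] = field(default_factory=lambda: {
        "even_ST": 0.02, "even_DT": 0.025, "uneven_ST": 0.04, "uneven_DT": 0.045})
    band_depth_db: dict[str, dict[str, float]] = field(default_factory=lambda: {
        c: {"theta": 2.0, "alpha": 2.0, "beta": -2.0} for c in CONDITIONS})
    depth_subject_sd_db: float = 0.3
    artifact_gain_db: float = 6.0
    line_amp_uv: float = 2.0
    blink_rate_hz: float = 0.25
    standing_s: float = 60.0
    walking_s: float = 60.0
    accel_noise_sd_g: float = 0.02
    eeg_noise_uv: float = 8.0
    eeg_sensor_noise_uv: float = 1.5
    fs_eeg: float = 250.0
    fs_accel: float = 250.0
    channels: list[str] = field(default_factory=lambda: list(STANDARD_16))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("standing_s", "walking_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.channels) < 8:
            raise ValueError("montage needs >= 8 channels")


@dataclass
class GroundTruth:
    events_left: dict[str, np.ndarray]
    events_right: dict[str, np.ndarray]
    band_profiles_db: dict[str, np.ndarray]  # band -> 100-bin dB profile
    band_freqs_hz: dict[str, float]
    artifact_channels: list[str]
    artifact_gain_db: float


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(list(keys))


def generate_timeline(mean_stride_s: float, sd_stride_s: float,
                      bouts: list[tuple[float, float]], seed: int = 0,
                      offsets: dict[str, float] | None = None) -> GaitTimeline:
    """Strides with truncated-normal durations filling the given bouts."""
    lo, hi = 0.5, 1.5
    if not lo < mean_stride_s < hi:
        raise ValueError(
            f"mean stride time {mean_stride_s} s outside plausible bounds ({lo}, {hi}) s")
    rng = _rng(seed)
    rhs_by_bout: list[np.ndarray] = []
    for t0, t1 in bouts:
        rhs = [t0]
        while True:
            if sd_stride_s > 0:
                a, b = (lo - mean_stride_s) / sd_stride_s, (hi - mean_stride_s) / sd_stride_s
                d = float(sstats.truncnorm.rvs(a, b, loc=mean_stride_s,
                                               scale=sd_stride_s, random_state=rng))
            else:
                d = mean_stride_s
            if rhs[-1] + d > t1 + 1e-9:
                break
            rhs.append(rhs[-1] + d)
        rhs_by_bout.append(np.asarray(rhs))
    return GaitTimeline(rhs_by_bout, dict(offsets or DEFAULT_OFFSETS),
                        mean_stride_s, sd_stride_s, list(bouts))


def _gauss_bump(t: np.ndarray, center: float, sigma: float, amp: float,
                out: np.ndarray, fs: float) -> None:
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(len(t), int((center + 5 * sigma) * fs) + 1)
    if hi > lo:
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)


def generate_accel(timeline: GaitTimeline, fs: float = 250.0,
                   noise_sd: float = 0.0, seed: int = 0,
                   duration_s: float | None = None
                   ) -> tuple[AccelTrace, AccelTrace, GroundTruth]:
    """Two-foot accelerometry whose planted events the detector recovers.

    Per stride each foot carries: a broad mid-swing vertical bump (> 0.6 g
    after 6 Hz smoothing, the step marker), a narrow heel-strike transient
    at the true heel strike (> 0.6 g at 30 Hz, < 0.6 g at 6 Hz), and a
    symmetric pair of anterior-posterior bumps straddling the true toe-off
    whose latency mean equals it exactly.
    """
    if fs < 100:
        raise ValueError("accelerometer rate must be >= 100 Hz")
    dur = duration_s if duration_s is not None else timeline.duration + 1.0
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    rng = _rng(seed, 17)

    vert = {"left": np.zeros(n), "right": np.zeros(n)}
    ap = {"left": np.zeros(n), "right": np.zeros(n)}
    off = timeline.offsets

    def midswing(center: float, out: np.ndarray) -> None:
        # narrow main bump + small trailing shoulder: the shoulder pulls the
        # 6 Hz-smoothed peak (the step marker) systematically *behind* the
        # 30 Hz peak, so the marker never precedes a supra-threshold
        # mid-swing maximum, while the shoulder itself stays < 0.6 g.
        _gauss_bump(t, center, 0.030, 1.2, out, fs)
        _gauss_bump(t, center + 0.06, 0.050, 0.4, out, fs)

    for rhs in timeline.rhs_by_bout:
        durs = np.diff(rhs)
        for a, d in zip(rhs[:-1], durs):
            # right foot: swing RTO -> next RHS; mid-swing between them
            midswing(a + (off["rto"] + 1.0) / 2 * d, vert["right"])
            _gauss_bump(t, a + d, 0.012, 1.2, vert["right"], fs)  # heel strike
            to_r = a + off["rto"] * d
            _gauss_bump(t, to_r - 0.03, 0.010, 0.5, ap["right"], fs)
            _gauss_bump(t, to_r + 0.03, 0.010, 0.5, ap["right"], fs)
            # left foot: swing LTO -> LHS; mid-swing between them
            midswing(a + (off["lto"] + off["lhs"]) / 2 * d, vert["left"])
            _gauss_bump(t, a + off["lhs"] * d, 0.012, 1.2, vert["left"], fs)
            to_l = a + off["lto"] * d
            _gauss_bump(t, to_l - 0.03, 0.010, 0.5, ap["left"], fs)
            _gauss_bump(t, to_l + 0.03, 0.010, 0.5, ap["left"], fs)
        if len(rhs) >= 2:
            # mid-swing marker preceding the first RHS of the bout
            d0 = durs[0]
            ms0 = rhs[0] - (1.0 - (off["rto"] + 1.0) / 2) * d0
            if ms0 - 0.35 > 0:
                midswing(ms0, vert["right"])
            _gauss_bump(t, rhs[0], 0.012, 1.2, vert["right"], fs)

    for d in (vert, ap):
        for foot in d:
            d[foot] += rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0

    ev = timeline.event_latencies()
    truth = GroundTruth(
        events_left={"LHS": ev["LHS"], "LTO": ev["LTO"]},
        events_right={"RHS": ev["RHS"], "RTO": ev["RTO"]},
        band_profiles_db={}, band_freqs_hz={}, artifact_channels=[],
        artifact_gain_db=0.0)
    left = AccelTrace(vert["left"], ap["left"], fs, "left")
    right = AccelTrace(vert["right"], ap["right"], fs, "right")
    return left, right, truth


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                scale: float) -> np.ndarray:
    """Approximately 1/f-weighted noise, unit-free scale in μV.

    Laplace innovations keep the sources super-Gaussian (as cortical EEG
    sources are), which an ICA stage can actually separate.
    """
    white = rng.laplace(0.0, 1.0, (n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1 / fs)
    w = 1.0 / np.maximum(f, 1.0) ** 0.5
    out = np.fft.irfft(spec * w, n=n, axis=-1)
    return scale * out / out.std(axis=-1, keepdims=True)


def _background(rng: np.random.Generator, positions: np.ndarray, n: int,
                fs: float, scale: float, sensor_noise: float,
                n_sources: int = 12) -> np.ndarray:
    """Spatially smooth background: pink-noise sources with Gaussian
    scalp topographies, plus small independent sensor noise.

    Spatial smoothness matters: the neighbour-correlation bad-channel rule
    assumes scalp channels share most of their variance, as real EEG does.
    """
    n_ch = len(positions)
    k = min(n_sources, n_ch)
    centers = rng.standard_normal((k, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers[:, 2] = np.abs(centers[:, 2])  # sources under the upper scalp
    d = np.linalg.norm(positions[:, None, :] - centers[None, :, :], axis=-1)
    topo = np.exp(-(d / 1.1) ** 2)
    src = _pink_noise(rng, k, n, fs, 1.0)
    mix = topo @ src
    mix *= scale / mix.std(axis=-1, keepdims=True).clip(1e-12)
    if sensor_noise > 0:
        mix += rng.standard_normal((n_ch, n)) * sensor_noise
    return mix


def generate_eeg(timeline: GaitTimeline, spec: SyntheticStudySpec,
                 condition: str, seed: int = 0,
                 standing_s: float | None = None,
                 bands: dict[str, BandSpec] | None = None,
                 ) -> tuple[EEGRecording, GroundTruth]:
    """EEG with gait-phase-locked band power plus controllable artifacts.

    The recording starts with a standing segment of stationary power
    (markers ``standing_start``/``standing_end``) followed by the walking
    data aligned to ``timeline`` (shifted by the standing duration; marker
    ``walking_start``).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    layout = make_layout(spec.channels)
    n_ch = layout.n_channels
    fs = spec.fs_eeg
    stand = spec.standing_s if standing_s is None else standing_s
    walk_dur = timeline.duration + 1.0
    n_stand = int(round(stand * fs))
    n_walk = int(round(walk_dur * fs))
    n = n_stand + n_walk
    t = np.arange(n) / fs
    rng = _rng(seed, 23)

    data = _background(rng, layout.positions, n, fs, spec.eeg_noise_uv,
                       spec.eeg_sensor_noise_uv)

    # gait-phase-locked oscillations, strongest around the vertex
    if bands is None:
        bands = {}
        for name, b in default_bands().items():
            depth = spec.band_depth_db.get(condition, {}).get(name, b.depth_db)
            depth += rng.normal(0.0, spec.depth_subject_sd_db)
            bands[name] = BandSpec(b.freq_hz, depth, b.peak_phase,
                                   b.cycles_per_stride, b.amplitude_uv)
    cz = layout.positions[layout.index("Cz")] if "Cz" in layout.names else np.array([0, 0, 1.0])
    dist = np.linalg.norm(layout.positions - cz, axis=1)
    topo = np.exp(-(dist / 0.8) ** 2)

    phase_walk = timeline.phase_at(t[n_stand:] - stand)
    profiles: dict[str, np.ndarray] = {}
    grid = (np.arange(100) + 0.5) / 100.0
    for name, b in bands.items():
        mod_db = np.zeros(n)
        in_stride = ~np.isnan(phase_walk)
        mod_db[n_stand:][in_stride] = b.profile_db(phase_walk[in_stride])
        amp = b.amplitude_uv * 10.0 ** (mod_db / 20.0)
        carrier = np.sin(2 * np.pi * b.freq_hz * t + rng.uniform(0, 2 * np.pi))
        data += topo[:, None] * (amp * carrier)[None, :]
        profiles[name] = b.profile_db(grid)

    # double-support broadband EMG-like bursts on the neck/lateral set
    art_names = layout.sets["neck"] + layout.sets["lateral"]
    art_idx = [layout.index(c) for c in art_names]
    if spec.artifact_gain_db != 0.0 and art_idx:
        # few shared muscle sources with smooth projections: neighbouring
        # artifact channels must stay correlated (> the bad-channel floor)
        anchors = np.array([[-0.9, -0.3, -0.3], [0.9, -0.3, -0.3], [0.0, -0.9, -0.2]])
        d = np.linalg.norm(layout.positions[art_idx][:, None, :] - anchors[None], axis=-1)
        W = np.exp(-(d / 0.9) ** 2)
        src = rng.standard_normal((len(anchors), n))
        b_hi, a_hi = _butter_band(fs)
        from scipy.signal import sosfiltfilt
        src = sosfiltfilt(b_hi, src)  # band-limit 15-60 Hz
        emg = W @ src
        emg *= 3.0 / emg.std(axis=-1, keepdims=True)
        ds = np.zeros(n)
        ph = phase_walk
        in_ds = (~np.isnan(ph)) & (((ph >= 0) & (ph < 0.15)) | ((ph >= 0.5) & (ph < 0.65)))
        ds[n_stand:][in_ds] = 1.0
        # smooth the gate to avoid clicks
        from scipy.ndimage import gaussian_filter1d
        ds = gaussian_filter1d(ds, 0.02 * fs)
        gain = 1.0 + (10.0 ** (spec.artifact_gain_db / 20.0) - 1.0) * ds
        data[art_idx] += emg * gain

    if spec.line_amp_uv > 0:
        ch_gain = rng.uniform(0.5, 1.5, n_ch)
        data += ch_gain[:, None] * spec.line_amp_uv * np.sin(2 * np.pi * 50.0 * t)[None, :]

    if spec.blink_rate_hz > 0:
        n_blinks = rng.poisson(spec.blink_rate_hz * n / fs)
        blink_t = np.sort(rng.uniform(0.5, n / fs - 0.5, n_blinks))
        blink = np.zeros(n)
        for bt in blink_t:
            _gauss_bump(t, bt, 0.10, 120.0, blink, fs)
        fr = layout.indices("frontal")
        w = np.zeros(n_ch)
        w[fr] = np.clip(layout.positions[fr, 1], 0, None)  # anterior weighting
        data += w[:, None] * blink[None, :]

    events = [("standing_start", 0.0), ("standing_end", stand),
              ("walking_start", stand), (f"condition/{condition}", stand)]
    for b0, b1 in (timeline.bouts or []):
        events += [("bout_start", stand + b0), ("bout_end", min(stand + b1, n / fs))]

    rec = EEGRecording(data, fs, layout, events, reference="FCz")
    ev = timeline.event_latencies()
    truth = GroundTruth(
        events_left={k: ev[k] + stand for k in ("LHS", "LTO")},
        events_right={k: ev[k] + stand for k in ("RHS", "RTO")},
        band_profiles_db=profiles,
        band_freqs_hz={k: b.freq_hz for k, b in bands.items()},
        artifact_channels=art_names if spec.artifact_gain_db != 0 else [],
        artifact_gain_db=spec.artifact_gain_db)
    return rec, truth


def _butter_band(fs: float):
    from scipy.signal import butter

    sos = butter(4, [15.0, min(60.0, fs / 2 * 0.9)], btype="band", fs=fs, output="sos")
    return sos, None


def generate_subject_condition(spec: SyntheticStudySpec, subject: int,
                               condition: str, with_standing: bool = True):
    """Timeline + accel + EEG for one subject x condition cell."""
    ci = CONDITIONS.index(condition)
    seed = [spec.seed, subject, ci]
    timeline = generate_timeline(
        spec.stride_mean_s[condition], spec.stride_sd_s[condition],
        bouts=[(1.0, 1.0 + spec.walking_s)], seed=_mix(seed, 1))
    left, right, truth_a = generate_accel(
        timeline, spec.fs_accel, spec.accel_noise_sd_g, seed=_mix(seed, 2))
    rec, truth = generate_eeg(
        timeline, spec, condition, seed=_mix(seed, 3),
        standing_s=spec.standing_s if with_standing else 0.0)
    return timeline, left, right, rec, truth


def _mix(keys: list[int], stage: int) -> int:
    ss = np.random.SeedSequence(keys + [stage])
    return int(ss.generate_state(1)[0])


def generate_study(spec: SyntheticStudySpec, out_dir: str | Path,
                   overwrite: bool = False) -> Path:
    """Write a BIDS-like study layout plus a ground-truth manifest.

    Per subject: one standing ("rest") recording and one recording per
    condition, each with accelerometer tables and a gait-event table.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"spec": {k: v for k, v in vars(spec).items()}, "subjects": {}}
    for s in range(1, spec.n_subjects + 1):
        sub = f"sub-{s:02d}"
        sdir = out / sub
        # standing baseline recording
        tl0 = GaitTimeline([np.empty(0)], bouts=[])
        rest, _ = generate_eeg(tl0, spec, "even_ST",
                               seed=_mix([spec.seed, s], 99), standing_s=spec.standing_s)
        io.write_brainvision(sdir / f"{sub}_task-rest_eeg", rest.data, rest.fs,
                             rest.layout.names, rest.events)
        subj_entry: dict = {"rest": f"{sub}_task-rest_eeg.vhdr", "conditions": {}}
        for cond in CONDITIONS:
            tl, left, right, rec, truth = generate_subject_condition(
                spec, s, cond, with_standing=False)
            base = f"{sub}_task-{cond}"
            io.write_brainvision(sdir / f"{base}_eeg", rec.data, rec.fs,
                                 rec.layout.names, rec.events)
            t = np.arange(left.n_samples) / left.fs
            io.write_accel_table(sdir / f"{base}_accel-left.tsv", t, left.vertical,
                                 left.anterior_posterior)
            io.write_accel_table(sdir / f"{base}_accel-right.tsv", t, right.vertical,
                                 right.anterior_posterior)
            ev = tl.event_latencies()
            subj_entry["conditions"][cond] = {
                "eeg": f"{base}_eeg.vhdr",
                "true_events": {k: v.tolist() for k, v in ev.items()},
                "band_profiles_db": {k: v.tolist() for k, v in truth.band_profiles_db.items()},
                "band_freqs_hz": truth.band_freqs_hz,
                "artifact_channels": truth.artifact_channels,
                "artifact_gain_db": truth.artifact_gain_db,
                "n_strides": tl.n_strides,
            }
        manifest["subjects"][sub] = subj_entry
    io.write_json(out / "ground_truth.json", manifest)
    return out
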