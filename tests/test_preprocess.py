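import numpy as np
import pytest

from gaitgpm import preprocess, synthetic
from gaitgpm.montage import STANDARD_16, make_layout
from gaitgpm.preprocess import EEGRecording, PreprocParams

FS = 250.0


def _rec(data, layout, fs=FS, **kw):
    return EEGRecording(np.asarray(data, float), fs, layout, **kw)


@pytest.fixture(scope="module")
def base_rec(layout16, smooth_noise16):
    return _rec(smooth_noise16.copy(), layout16)


class TestResampleAndFilter:
    def test_10hz_amplitude_within_1pct(self, layout16):
        t = np.arange(int(20 * FS)) / FS
        x = 10 * np.cos(2 * np.pi * 10 * t)
        rec = _rec(np.tile(x, (16, 1)), layout16)
        out = preprocess.resample_and_filter(rec)
        mid = slice(int(5 * FS), int(15 * FS))
        assert np.abs(out.data[0, mid]).max() == pytest.approx(10.0, rel=0.01)

    def test_slow_drift_attenuated(self, layout16):
        t = np.arange(int(120 * FS)) / FS
        x = 10 * np.sin(2 * np.pi * 0.05 * t)
        rec = _rec(np.tile(x, (16, 1)), layout16)
        out = preprocess.resample_and_filter(rec)
        # amplitude at 0.05 Hz via least-squares sinusoid fit (own oracle)
        basis = np.column_stack([np.sin(2 * np.pi * 0.05 * t),
                                 np.cos(2 * np.pi * 0.05 * t)])
        coef, *_ = np.linalg.lstsq(basis, out.data[0], rcond=None)
        atten_db = 20 * np.log10(10.0 / np.hypot(*coef))
        assert atten_db > 10

    def test_dc_removed(self, layout16):
        rec = _rec(np.full((16, int(30 * FS)), 50.0), layout16)
        out = preprocess.resample_and_filter(rec)
        assert np.abs(out.data).max() < 0.5  # < 1% of the 50 μV offset

    def test_downsampling_from_500(self, layout16):
        t = np.arange(int(10 * 500.0)) / 500.0
        rec = _rec(np.tile(5 * np.cos(2 * np.pi * 10 * t), (16, 1)), layout16,
                   fs=500.0)
        out = preprocess.resample_and_filter(rec)
        assert out.fs == 250.0
        assert out.n_samples == 10 * 250

    def test_nyquist_guard(self, layout16):
        rec = _rec(np.zeros((16, 1000)), layout16, fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess.resample_and_filter(rec)


class TestFindBadChannels:
    def test_flatline_flagged(self, base_rec):
        rec = base_rec.copy()
        i = rec.layout.index("C3")
        rec.data[i, 1000:1000 + int(6 * FS)] = 3.14
        assert "C3" in preprocess.find_bad_channels(rec)

    def test_uncorrelated_noise_flagged(self, base_rec):
        rec = base_rec.copy()
        i = rec.layout.index("Pz")
        rec.data[i] = np.random.default_rng(1).normal(0, 10, rec.n_samples)
        assert "Pz" in preprocess.find_bad_channels(rec)

    def test_line_noise_flagged(self, base_rec):
        rec = base_rec.copy()
        t = np.arange(rec.n_samples) / FS
        i = rec.layout.index("T8")
        rec.data[i] += 80 * np.sin(2 * np.pi * 50 * t)
        assert "T8" in preprocess.find_bad_channels(rec)

    def test_clean_data_mostly_unflagged(self, base_rec):
        assert len(preprocess.find_bad_channels(base_rec)) <= 2

    def test_needs_8_channels(self):
        lay = make_layout(["Fz", "Cz", "Pz", "Oz"])
        with pytest.raises(ValueError, match="8 channels"):
            preprocess.find_bad_channels(_rec(np.zeros((4, 2500)), lay))


class TestInterpolateBads:
    def test_constant_field_reproduced(self, layout16):
        sig = np.sin(np.arange(2500) / 50.0)
        rec = _rec(np.tile(sig, (16, 1)), layout16, bads={"C3"})
        out = preprocess.interpolate_bads(rec)
        i = layout16.index("C3")
        err = np.abs(out.data[i] - sig).max() / max(np.abs(sig).max(), 1e-30)
        assert err < 1e-6

    def test_leave_one_out_smooth_field(self, layout16):
        # smooth dipolar-like topography: interpolation should track it
        rng = np.random.default_rng(3)
        src = rng.normal(0, 1, (3, 2500))
        centers = np.array([[0.3, 0.2, 0.9], [-0.4, 0.1, 0.9], [0.0, -0.6, 0.7]])
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        topo = np.exp(-np.linalg.norm(
            layout16.positions[:, None] - centers[None], axis=-1) ** 2)
        data = topo @ src
        rec = _rec(data, layout16, bads={"Cz"})
        out = preprocess.interpolate_bads(rec)
        i = layout16.index("Cz")
        r = np.corrcoef(out.data[i], data[i])[0, 1]
        assert r > 0.95

    def test_zero_variance_in_zero_out(self, layout16):
        rec = _rec(np.zeros((16, 2500)), layout16, bads={"Cz"})
        out = preprocess.interpolate_bads(rec)
        assert np.abs(out.data).max() == 0.0

    def test_too_few_good_channels(self, layout16):
        rec = _rec(np.zeros((16, 2500)), layout16,
                   bads=set(layout16.names[:-3]))
        with pytest.raises(ValueError, match="too few good"):
            preprocess.interpolate_bads(rec)


class TestRereferenceCar:
    def test_zero_mean_per_sample(self, base_rec):
        out = preprocess.rereference_car(base_rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_reference_channel_reconstructed(self, base_rec):
        out = preprocess.rereference_car(base_rec)
        assert "FCz" in out.layout.names
        assert out.n_channels == base_rec.n_channels + 1
        assert out.reference == "CAR"

    def test_idempotent(self, base_rec):
        once = preprocess.rereference_car(base_rec)
        twice = preprocess.rereference_car(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        assert twice.n_channels == once.n_channels

    def test_single_channel_errors(self):
        lay = make_layout(["Cz"])
        with pytest.raises(ValueError, match="single channel"):
            preprocess.rereference_car(_rec(np.zeros((1, 100)), lay))


class TestRemoveLineNoise:
    def _psd(self, x):
        from scipy import signal as sg

        return sg.welch(x, FS, nperseg=2048)

    def test_reduction_and_band_preservation(self, layout16):
        t = np.arange(int(60 * FS)) / FS
        rng = np.random.default_rng(0)
        data = (10 * np.sin(2 * np.pi * 10 * t) + 20 * np.sin(2 * np.pi * 50 * t)
                + rng.normal(0, 1, (16, len(t))))
        rec = _rec(data, layout16)
        out = preprocess.remove_line_noise(rec)
        f, pa = self._psd(rec.data[0])
        f, pb = self._psd(out.data[0])
        m50 = (f >= 49) & (f <= 51)
        assert 10 * np.log10(pa[m50].sum() / pb[m50].sum()) >= 15
        outb = (f > 5) & (f < 45)
        assert np.abs(10 * np.log10(pb[outb] / pa[outb])).max() < 1.0
        # 10 Hz amplitude preserved within 2%
        basis = np.column_stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        coef, *_ = np.linalg.lstsq(basis, out.data[0], rcond=None)
        assert np.hypot(*coef) == pytest.approx(10.0, rel=0.02)

    def test_halved_amplitude_still_reduced(self, layout16):
        t = np.arange(int(30 * FS)) / FS
        rng = np.random.default_rng(1)
        data = 10 * np.sin(2 * np.pi * 50 * t) + rng.normal(0, 0.5, (16, len(t)))
        rec = _rec(data, layout16)
        out = preprocess.remove_line_noise(rec)
        f, pa = self._psd(rec.data[0])
        f, pb = self._psd(out.data[0])
        m50 = (f >= 49) & (f <= 51)
        assert 10 * np.log10(pa[m50].sum() / pb[m50].sum()) >= 15

    def test_noop_without_line_component(self, base_rec):
        out = preprocess.remove_line_noise(base_rec)
        f, pa = self._psd(base_rec.data)
        f, pb = self._psd(out.data)
        assert abs(10 * np.log10(pb.mean() / pa.mean())) < 0.5


class TestRejectArtifactEpochs:
    def test_spike_epoch_rejected(self, base_rec):
        rec = base_rec.copy()
        rec.data[3, int(5.5 * FS)] = 400.0
        keep = preprocess.reject_artifact_epochs(rec, 1.0)
        assert not keep[5]

    def test_gaussian_data_mostly_kept(self, layout16):
        rng = np.random.default_rng(5)
        rec = _rec(rng.normal(0, 10, (16, int(60 * FS))), layout16)
        keep = preprocess.reject_artifact_epochs(rec, 1.0)
        assert keep.mean() >= 0.95

    def test_empty_recording(self, layout16):
        rec = _rec(np.zeros((16, 10)), layout16)
        keep = preprocess.reject_artifact_epochs(rec, 1.0)
        assert keep.size == 0


@pytest.fixture(scope="module")
def blink_pair():
    """Same-seed recordings with and without blinks (all else identical)."""
    spec = dict(walking_s=30.0, standing_s=10.0, artifact_gain_db=0.0,
                line_amp_uv=0.0)
    tl = synthetic.generate_timeline(1.0, 0.02, [(1.0, 31.0)], seed=6)
    with_b, _ = synthetic.generate_eeg(
        tl, synthetic.SyntheticStudySpec(blink_rate_hz=0.4, **spec),
        "even_ST", seed=6)
    no_b, _ = synthetic.generate_eeg(
        tl, synthetic.SyntheticStudySpec(blink_rate_hz=0.0, **spec),
        "even_ST", seed=6)
    return with_b, no_b


class TestIcaEyeRemoval:
    def test_blink_variance_removed(self, blink_pair):
        with_b, no_b = blink_pair
        rec = preprocess.rereference_car(with_b)
        ref = preprocess.rereference_car(no_b)
        out, decomp = preprocess.ica_eye_removal(rec, seed=0)
        assert len(decomp.removed) >= 1
        fr = rec.layout.indices("frontal")
        blink_var = (rec.data[fr] - ref.data[fr]).var(axis=1).sum()
        resid_var = (out.data[fr] - ref.data[fr]).var(axis=1).sum()
        assert resid_var < 0.2 * blink_var  # > 80% of blink variance removed

    def test_no_eye_component_passthrough(self, blink_pair):
        _, no_b = blink_pair
        rec = preprocess.rereference_car(no_b)
        out, decomp = preprocess.ica_eye_removal(rec, seed=0)
        assert not decomp.removed
        assert np.allclose(out.data, rec.data, rtol=1e-6, atol=1e-9)

    def test_removed_variance_identity(self, blink_pair):
        with_b, _ = blink_pair
        rec = preprocess.rereference_car(with_b)
        out, decomp = preprocess.ica_eye_removal(rec, seed=0)
        if not decomp.removed:
            pytest.skip("no component crossed the removal cutoff")
        removed = rec.data - out.data
        lhs = rec.data.var(axis=1).sum() - out.data.var(axis=1).sum()
        rhs = removed.var(axis=1).sum()
        # exact when removed sources are uncorrelated with the retained ones;
        # back-projection to the unfiltered data leaves a small cross term
        assert lhs == pytest.approx(rhs, rel=0.1)

    def test_deterministic_given_seed(self, blink_pair):
        with_b, _ = blink_pair
        rec = preprocess.rereference_car(with_b)
        a, _ = preprocess.ica_eye_removal(rec, seed=0)
        b, _ = preprocess.ica_eye_removal(rec, seed=0)
        assert np.array_equal(a.data, b.data)


def test_full_chain_stage_order_and_provenance(layout16):
    spec = synthetic.SyntheticStudySpec(walking_s=20.0, standing_s=10.0)
    tl = synthetic.generate_timeline(1.0, 0.0, [(1.0, 21.0)], seed=8)
    rec, _ = synthetic.generate_eeg(tl, spec, "even_ST", seed=8)
    out, prov = preprocess.run_preprocessing(rec, seed=0)
    stages = [s["stage"] for s in prov["stages"]]
    assert stages == ["resample_and_filter", "find_bad_channels",
                      "burst_correction", "remove_line_noise",
                      "interpolate_bads", "rereference_car", "ica_eye_removal"]
    ica_stage = prov["stages"][-1]
    assert ica_stage["n_kept"] == ica_stage["n_components"] - ica_stage["n_removed"]
    assert np.all(np.isfinite(out.data))
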