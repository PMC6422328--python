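"""Decoder pipeline: segmentation, filtering, features, LDA, scoring."""

import json

import numpy as np
import pytest
from scipy import stats

from affectbci import (
    AffectModel,
    DEFAULT_BANDS,
    DEFAULT_CHANNELS,
    EEGRecording,
    Segment,
    SigmoidLDA,
    bandpass,
    calibrate,
    compute_baseline,
    extract_features,
    fit_lda,
    score,
    segment_stream,
    stream_scores,
)
from affectbci.synth import EffectSpec, Responder, ResponderConfig

from conftest import make_noise_recording

FS = 128.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "events, window_s, step_s, expected",
    [
        ([(0.0, 20.0, "happy")], 4.0, 0.5, 40),
        ([(0.0, 10.0, "idle")], 4.0, 0.5, 20),
        ([(0.0, 10.0, "happy")], 1.0, 1.0, 10),  # non-overlapping
        ([(0.0, 20.0, "happy"), (20.0, 10.0, "idle")], 4.0, 0.5, 60),
    ],
)
def test_segment_counts(events, window_s, step_s, expected):
    """Each period yields floor(duration / step) windows labeled by start."""
    total = max(o + d for o, d, _ in events) + 4.0
    rec = make_noise_recording(total, events, seed=1)
    segs = segment_stream(rec, window_s=window_s, step_s=step_s)
    assert len(segs) == expected
    n_win = int(window_s * FS)
    assert all(s.data.shape == (14, n_win) for s in segs)


def test_segment_period_shorter_than_step_warns():
    rec = make_noise_recording(10.0, [(0.0, 0.2, "happy")], seed=1)
    with pytest.warns(UserWarning, match="shorter than the step"):
        segs = segment_stream(rec)
    assert segs == []


def test_segment_windows_may_cross_period_boundary():
    rec = make_noise_recording(
        30.0, [(0.0, 20.0, "happy"), (20.0, 10.0, "idle")], seed=1
    )
    segs = segment_stream(rec, labels={"happy"})
    last = max(segs, key=lambda s: s.start)
    assert last.start == pytest.approx(19.5)  # extends 3.5 s into idle


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _sine_segment(freq, amp=1.0, dur=4.0, n_ch=1):
    t = np.arange(int(dur * FS)) / FS
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Segment(data=data, start=0.0, label="happy", fs=FS)


def test_bandpass_passband_gain():
    """A 10 Hz tone passes the alpha band at roughly unit amplitude."""
    seg = bandpass(_sine_segment(10.0), 8.0, 13.0)
    core = seg.data[0, 128:-128]  # away from segment edges
    assert np.max(np.abs(core)) == pytest.approx(1.0, abs=0.15)


def test_bandpass_stopband_attenuation():
    """A 50 Hz tone is crushed by the alpha band: < 1 % variance passes."""
    seg_in = _sine_segment(50.0)
    seg = bandpass(seg_in, 8.0, 13.0)
    assert seg.data[0].var() < 0.01 * seg_in.data[0].var()


def test_bandpass_zero_phase_symmetry():
    """Zero net phase: the filter introduces no group delay.

    Time-reversal symmetry holds away from the segment edges (IIR edge
    transients differ), and the cross-correlation between a band-limited
    input and its filtered version peaks at lag zero.
    """
    rng = np.random.default_rng(0)
    seg = Segment(
        data=rng.standard_normal((3, 1024)), start=0.0, label="idle", fs=FS
    )
    rev = Segment(data=seg.data[:, ::-1], start=0.0, label="idle", fs=FS)
    fwd = bandpass(seg, 8.0, 13.0).data
    bwd = bandpass(rev, 8.0, 13.0).data
    core = slice(256, -256)
    np.testing.assert_allclose(
        bwd[:, ::-1][:, core], fwd[:, core], atol=5e-3
    )
    # no delay: correlation of filtered output with a pre-filtered copy
    # of the input peaks at zero lag
    x = bandpass(seg, 8.0, 13.0).data[0]
    y = bandpass(Segment(x[None, :], 0.0, "idle", FS), 8.0, 13.0).data[0]
    lags = np.arange(-10, 11)
    corr = [np.dot(x[10:-10], np.roll(y, k)[10:-10]) for k in lags]
    assert lags[int(np.argmax(corr))] == 0


@pytest.mark.parametrize("lo, hi", [(0.0, 13.0), (13.0, 8.0), (30.0, 70.0)])
def test_bandpass_rejects_bad_edges(lo, hi):
    with pytest.raises(ValueError):
        bandpass(_sine_segment(10.0), lo, hi)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def test_feature_vector_length_and_order():
    rng = np.random.default_rng(1)
    seg = Segment(
        data=rng.standard_normal((14, 512)), start=0.0, label="happy", fs=FS
    )
    f = extract_features(seg)
    assert f.shape == (70,)
    assert np.all(np.isfinite(f))


def test_inband_sinusoid_feature_value():
    """An in-band sinusoid of amplitude A has variance A^2/2; after the
    zero-phase (forward-backward) filter the analytic expectation is
    log(A^2/2 * |H(f)|^4), |H| from the filter's frequency response."""
    from scipy import signal as sps

    from affectbci.decoder import _design_bandpass

    amp, freq = 3.0, 10.0
    seg = _sine_segment(freq, amp=amp, n_ch=2)
    f = extract_features(seg, band_defs=[("alpha", 8.0, 13.0)])
    sos = _design_bandpass(8.0, 13.0, FS, 2, 0.5)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
    expected = np.log(amp**2 / 2 * np.abs(h[0]) ** 4)
    assert f[0] == pytest.approx(expected, abs=0.05)


def test_amplitude_doubling_adds_log4():
    rng = np.random.default_rng(2)
    base = rng.standard_normal((1, 512))
    f1 = extract_features(Segment(base, 0.0, "happy", FS))
    f2 = extract_features(Segment(2 * base, 0.0, "happy", FS))
    np.testing.assert_allclose(f2 - f1, np.log(4.0), atol=1e-9)


def test_flat_channel_rejected():
    data = np.vstack([np.zeros(512), np.random.default_rng(0).standard_normal(512)])
    with pytest.raises(ValueError, match="dead channel"):
        extract_features(Segment(data, 0.0, "happy", FS))


def test_compute_baseline():
    v = np.arange(5.0)
    np.testing.assert_array_equal(compute_baseline([v]), v)
    np.testing.assert_array_equal(
        compute_baseline([v, -v]), np.zeros(5)
    )
    rng = np.random.default_rng(3)
    obs = rng.standard_normal((120, 70))
    np.testing.assert_allclose(
        compute_baseline(list(obs)), obs.mean(axis=0), atol=1e-12
    )
    with pytest.raises(ValueError):
        compute_baseline([])


# ---------------------------------------------------------------------------
# LDA and scoring
# ---------------------------------------------------------------------------

def test_fit_lda_matches_hand_linear_algebra():
    """3-point classes: w must equal inv(S1+S2) @ (mu2-mu1) computed
    independently with explicit inversion."""
    X_sad = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0]])
    X_happy = np.array([[3.0, 2.0], [4.0, 2.5], [3.5, 3.0]])
    w, b = fit_lda(X_sad, X_happy, ridge=0.0)
    S = np.cov(X_sad, rowvar=False) + np.cov(X_happy, rowvar=False)
    mu1, mu2 = X_sad.mean(0), X_happy.mean(0)
    w_hand = np.linalg.inv(S) @ (mu2 - mu1)
    np.testing.assert_allclose(w, w_hand, rtol=1e-10)
    assert b == pytest.approx(-w_hand @ (mu1 + mu2) / 2)


def test_fit_lda_isotropic_direction(rng):
    """Spherical classes: w is parallel to the mean difference."""
    mu = np.array([3.0, -2.0])
    X1 = rng.standard_normal((500, 2))
    X2 = rng.standard_normal((500, 2)) + mu
    w, _ = fit_lda(X1, X2, ridge=0.0)
    cos = w @ mu / (np.linalg.norm(w) * np.linalg.norm(mu))
    assert cos > 0.99


def test_fit_lda_symmetric_midpoint(rng):
    X1 = rng.normal(-1.0, 1.0, size=(2000, 1))
    X2 = rng.normal(+1.0, 1.0, size=(2000, 1))
    w, b = fit_lda(X1, X2)
    # discriminant w*x + b is zero at the empirical class midpoint
    mid = (X1.mean() + X2.mean()) / 2
    assert w[0] * mid + b == pytest.approx(0.0, abs=1e-12)
    assert abs(mid) < 0.1


def test_fit_lda_singular_raises():
    X1 = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    X2 = np.array([[3.0, 6.0], [3.0, 6.0], [3.0, 6.0]])
    with pytest.raises(np.linalg.LinAlgError, match="ridge"):
        fit_lda(X1, X2, ridge=0.0)


def _toy_model(w, b, alpha=2.0, n=None):
    n = n or len(w)
    return AffectModel(
        baseline=np.zeros(n),
        feat_mean=np.zeros(n),
        feat_sd=np.ones(n),
        w=np.asarray(w, dtype=float),
        b=b,
        alpha=alpha,
        ridge=0.0,
        band_defs=[("alpha", 8.0, 13.0)],
        channel_names=[f"ch{i}" for i in range(n)],
    )


def test_score_midpoint_and_sigmoid_values():
    model = _toy_model([1.0, 0.0], b=0.0)
    assert score(model, [0.0, 5.0]).value == pytest.approx(0.5)
    # alpha = 2, discriminant 1 -> 1 / (1 + e^-2)
    assert score(model, [1.0, 0.0]).value == pytest.approx(0.88079707, abs=1e-6)
    big = score(model, [100.0, 0.0]).value
    small = score(model, [-100.0, 0.0]).value
    assert 0.0 < small < 1e-6 and 1.0 - 1e-6 < big < 1.0


def test_score_monotone_in_discriminant():
    model = _toy_model([2.0], b=0.3, alpha=0.7)
    xs = np.linspace(-5, 5, 41)
    vals = [score(model, [x]).value for x in xs]
    assert np.all(np.diff(vals) > 0)


def test_score_rejects_length_mismatch():
    with pytest.raises(ValueError):
        score(_toy_model([1.0, 2.0], b=0.0), [1.0])


def test_sigmoid_lda_sklearn_contract(rng):
    from sklearn.base import clone

    est = SigmoidLDA(ridge=0.1, alpha=3.0)
    assert est.get_params()["alpha"] == 3.0
    est2 = clone(est).set_params(alpha=1.0)
    X = np.vstack(
        [rng.standard_normal((50, 3)), rng.standard_normal((50, 3)) + 2.0]
    )
    y = np.r_[np.zeros(50), np.ones(50)]
    est2.fit(X, y)
    assert est2.coef_.shape == (3,)
    assert est2.score(X, y) > 0.9
    s = est2.predict_score(X)
    assert np.all((s > 0) & (s < 1))


# ---------------------------------------------------------------------------
# calibration and online scoring
# ---------------------------------------------------------------------------

def test_calibration_counts_and_dimensionality(strong_model):
    assert strong_model.n_features == 70
    assert strong_model.n_obs == {"happy": 80, "sad": 80, "idle": 120}


def test_calibration_missing_label_named():
    rec = make_noise_recording(
        60.0,
        [(0.0, 20.0, "happy"), (20.0, 10.0, "idle"), (30.0, 20.0, "happy")],
        seed=4,
    )
    with pytest.raises(ValueError, match="'sad'"):
        calibrate(rec)


def test_label_swap_negates_weights(strong_rec):
    swapped = EEGRecording(
        samples=strong_rec.samples,
        fs=strong_rec.fs,
        channel_names=strong_rec.channel_names,
        events=[
            (o, d, {"happy": "sad", "sad": "happy"}.get(l, l))
            for o, d, l in strong_rec.events
        ],
    )
    m1 = calibrate(strong_rec)
    m2 = calibrate(swapped)
    np.testing.assert_allclose(m2.w, -m1.w, rtol=1e-8)
    assert m2.b == pytest.approx(-m1.b)


def test_planted_effect_recovered(strong_rec, strong_model):
    """Happy-period windows score above 0.5 on average, sad below."""
    segs = segment_stream(strong_rec, labels={"happy", "sad"})
    means = {"happy": [], "sad": []}
    for seg in segs[::4]:
        means[seg.label].append(
            strong_model.score_window(seg.data).value
        )
    assert np.mean(means["happy"]) > 0.6
    assert np.mean(means["sad"]) < 0.4


def test_standardized_features_zero_mean_unit_variance(strong_rec, strong_model):
    from affectbci.decoder import _segment_features

    segs = segment_stream(strong_rec, labels={"happy", "sad"})
    Z = np.array(
        [
            strong_model.prepare(
                _segment_features(s.data, strong_rec.fs, strong_model.band_defs)
            )
            for s in segs
        ]
    )
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)


def test_stream_scores_count_and_times(strong_model):
    rec = make_noise_recording(34.0, [], seed=5)
    scores = stream_scores(strong_model, rec)
    assert len(scores) == 61
    assert scores[0].time == pytest.approx(4.0)
    assert scores[-1].time == pytest.approx(34.0)
    np.testing.assert_allclose(
        np.diff([s.time for s in scores]), 0.5, atol=1e-9
    )


def test_stream_scores_montage_mismatch(strong_model):
    rec = make_noise_recording(10.0, [], seed=5)
    rec.channel_names = tuple(f"X{i}" for i in range(14))
    with pytest.raises(ValueError, match="montage"):
        stream_scores(strong_model, rec)


def test_stream_scores_trendless_on_stationary_noise(strong_model):
    """Stationary input gives no systematic score trend: the slope test
    is significant in about the nominal 5 % of seeded runs."""
    n_sig = 0
    for seed in range(20):
        rec = make_noise_recording(24.0, [], seed=200 + seed)
        vals = [s.value for s in stream_scores(strong_model, rec)]
        t = np.arange(len(vals))
        res = stats.linregress(t, vals)
        n_sig += res.pvalue < 0.05
    assert n_sig <= 4  # Binomial(20, 0.05): P(X > 4) < 0.003


def test_score_ramp_along_discriminant_direction():
    """Ramping the coupled-band amplitude drives a monotone score trend."""
    from affectbci.synth import make_responder_setup

    model, responder = make_responder_setup(21)
    cfg = responder.cfg
    # force the internal state upward deterministically
    responder.state = 0.0
    vals = []
    block = int(0.5 * model.fs)
    win = int(4 * model.fs)
    buf = np.zeros((14, 0))
    for k in range(60):
        responder.state = k / 59.0
        data = responder.next_block(block, "rest", None)
        responder.state = k / 59.0  # undo relaxation; pure ramp
        buf = np.hstack([buf, data])
        if buf.shape[1] >= win:
            vals.append(model.score_window(buf[:, -win:]).value)
    smoothed = np.convolve(vals, np.ones(8) / 8, mode="valid")
    res = stats.linregress(np.arange(len(smoothed)), smoothed)
    assert res.slope > 0
    assert res.pvalue < 1e-6


def test_model_json_roundtrip(strong_model, tmp_path):
    path = tmp_path / "model.json"
    strong_model.save(path)
    back = AffectModel.load(path)
    np.testing.assert_array_equal(back.w, strong_model.w)
    np.testing.assert_array_equal(back.baseline, strong_model.baseline)
    np.testing.assert_array_equal(back.feat_sd, strong_model.feat_sd)
    assert back.b == strong_model.b
    assert back.band_defs == strong_model.band_defs
    assert back.channel_names == strong_model.channel_names
    assert back.n_obs == strong_model.n_obs
    # identical scores after the round trip
    rng = np.random.default_rng(0)
    window = rng.standard_normal((14, 512))
    assert back.score_window(window).value == pytest.approx(
        strong_model.score_window(window).value, abs=1e-12
    )


def test_pipeline_determinism(strong_rec):
    m1 = calibrate(strong_rec)
    m2 = calibrate(strong_rec)
    np.testing.assert_array_equal(m1.w, m2.w)
    np.testing.assert_array_equal(m1.baseline, m2.baseline)


def test_resampling_path():
    rec = make_noise_recording(10.0, [], seed=6, fs=256.0)
    res = rec.resampled(128.0)
    assert res.fs == 128.0
    assert res.samples.shape[1] == 1280
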