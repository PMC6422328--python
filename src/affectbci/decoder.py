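"""EEG affect decoding: band-power features and closed-form LDA scoring.

The decoding pipeline mirrors a classic two-class band-power BCI design:

1. extract the labeled listening periods (happy / sad) and idle periods
   from the continuous recording;
2. cut them into 4-s segments stepped every 0.5 s (87.5 % overlap);
3. band-pass each segment independently into five bands — theta 4–7,
   alpha 8–13, low beta 14–21, high beta 22–29, gamma 30–47 Hz — with a
   2nd-order zero-phase Chebyshev type-I filter;
4. take the natural log of the per-channel variance of each band-filtered
   segment: 14 channels x 5 bands = 70 features per observation;
5. average the idle observations into a baseline vector and subtract it
   from every observation;
6. standardize the two classes of interest feature-wise;
7. fit a closed-form linear discriminant
   ``w = (S1 + S2 + ridge*I)^-1 (mu_happy - mu_sad)``
   with the decision threshold at the class-mean midpoint;
8. squash the discriminant through a sigmoid of steepness ``alpha`` into
   the continuous control score s in (0, 1): 0 = sad, 1 = happy.

Windows are labeled by the period containing their *start* sample and may
extend past the period boundary — the same convention the online system
uses, and the one under which a 20-s listening period stepped at 0.5 s
yields 40 observations (80 per class over two presentations, 120 idle
over six 10-s idle periods).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_BANDS",
    "EEGRecording",
    "Segment",
    "Score",
    "AffectModel",
    "SigmoidLDA",
    "AffectDecoder",
    "segment_stream",
    "bandpass",
    "extract_features",
    "compute_baseline",
    "fit_lda",
    "score",
    "calibrate",
    "stream_scores",
]

#: 14-channel consumer-headset montage (10-20 positions).
DEFAULT_CHANNELS = (
    "AF3", "AF4", "F7", "F8", "F3", "F4", "FC5",
    "FC6", "T7", "T8", "P7", "P8", "O1", "O2",
)

#: (name, low Hz, high Hz); delta is excluded as artifact-prone.
DEFAULT_BANDS = (
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 13.0),
    ("low_beta", 14.0, 21.0),
    ("high_beta", 22.0, 29.0),
    ("gamma", 30.0, 47.0),
)

DEFAULT_FS = 128.0
WINDOW_S = 4.0
STEP_S = 0.5

MUSIC_CLASSES = ("sad", "happy")  # fitted classes, orientation sad->0, happy->1

_EVENT_LABELS = {
    "happy", "sad", "neutral", "idle", "rest", "cue",
    "action_happy", "action_sad",
}


@dataclass
class EEGRecording:
    """Annotated multichannel EEG: channels x time samples in microvolts."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    events: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows for "
                f"{len(self.channel_names)} channel names"
            )
        for onset, duration, label in self.events:
            if onset < 0 or duration < 0:
                raise ValueError("event onset/duration must be non-negative")
            if onset > self.duration + 1e-9:
                raise ValueError(
                    f"event {label!r} at {onset} s beyond recording end"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def resampled(self, fs: float) -> "EEGRecording":
        """Return a copy resampled to ``fs`` (polyphase)."""
        if fs == self.fs:
            return self
        from fractions import Fraction

        frac = Fraction(fs / self.fs).limit_denominator(1000)
        data = signal.resample_poly(
            self.samples, frac.numerator, frac.denominator, axis=1
        )
        return EEGRecording(
            samples=data,
            fs=fs,
            channel_names=self.channel_names,
            events=list(self.events),
        )


@dataclass
class Segment:
    """One fixed-length analysis window cut from a recording."""

    data: np.ndarray
    start: float
    label: str
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be channels x samples")


@dataclass(frozen=True)
class Score:
    """One decoder output: the control signal s in (0, 1) at a time point."""

    value: float
    time: float

    def __post_init__(self) -> None:
        if not (0.0 < self.value < 1.0):
            raise ValueError("score must lie strictly inside (0, 1)")


def segment_stream(
    rec: EEGRecording,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
    labels: Iterable[str] | None = None,
) -> list[Segment]:
    """Cut every labeled period into overlapping fixed-length windows.

    Window starts fall on every ``step_s`` inside a period (beginning at
    the period onset); a window belongs to the period containing its start
    and may extend beyond the period boundary, so each period contributes
    ``floor(duration / step_s)`` windows.  Windows that would run past the
    end of the recording are dropped with a warning.
    """
    if rec.duration < window_s:
        raise ValueError("recording shorter than one analysis window")
    want = set(labels) if labels is not None else None
    n_win = int(round(window_s * rec.fs))
    segments: list[Segment] = []
    for onset, duration, label in rec.events:
        if want is not None and label not in want:
            continue
        n_seg = int(np.floor(duration / step_s + 1e-9))
        if n_seg == 0:
            warnings.warn(
                f"period {label!r} at {onset} s shorter than the step "
                f"({duration} s < {step_s} s): zero segments"
            )
            continue
        dropped = 0
        for k in range(n_seg):
            start = onset + k * step_s
            i0 = int(round(start * rec.fs))
            if i0 + n_win > rec.samples.shape[1]:
                dropped += 1
                continue
            segments.append(
                Segment(
                    data=rec.samples[:, i0 : i0 + n_win],
                    start=start,
                    label=label,
                    fs=rec.fs,
                )
            )
        if dropped:
            warnings.warn(
                f"dropped {dropped} window(s) of period {label!r} at "
                f"{onset} s extending past the end of the recording"
            )
    return segments


@lru_cache(maxsize=64)
def _design_bandpass(
    lo: float, hi: float, fs: float, order: int, ripple_db: float
) -> np.ndarray:
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(
            f"band edges ({lo}, {hi}) Hz invalid for fs = {fs} Hz"
        )
    return signal.cheby1(
        order, ripple_db, [lo / nyq, hi / nyq], btype="bandpass", output="sos"
    )


def bandpass(
    seg: Segment | np.ndarray,
    lo: float,
    hi: float,
    fs: float | None = None,
    order: int = 2,
    ripple_db: float = 0.5,
):
    """Zero-phase Chebyshev type-I band-pass of one segment in isolation.

    The filter (order 2, 0.5 dB passband ripple by default) is applied
    forward and backward along the time axis, so the net phase shift is
    zero and no group delay is introduced.  Each segment is filtered
    independently of its neighbours — there is no continuous filter state.
    """
    if isinstance(seg, Segment):
        sos = _design_bandpass(lo, hi, seg.fs, order, ripple_db)
        return Segment(
            data=signal.sosfiltfilt(sos, seg.data, axis=-1),
            start=seg.start,
            label=seg.label,
            fs=seg.fs,
        )
    if fs is None:
        raise ValueError("fs required when filtering a bare array")
    sos = _design_bandpass(lo, hi, fs, order, ripple_db)
    return signal.sosfiltfilt(sos, np.asarray(seg, dtype=float), axis=-1)


def _segment_features(
    data: np.ndarray,
    fs: float,
    band_defs: Sequence[tuple[str, float, float]],
    order: int = 2,
    ripple_db: float = 0.5,
) -> np.ndarray:
    """Log band-power features of one window, channel-major ordering."""
    n_ch = data.shape[0]
    out = np.empty((n_ch, len(band_defs)))
    for j, (_name, lo, hi) in enumerate(band_defs):
        sos = _design_bandpass(lo, hi, fs, order, ripple_db)
        filt = signal.sosfiltfilt(sos, data, axis=-1)
        var = filt.var(axis=-1, ddof=1)
        if np.any(var <= 0.0):
            dead = np.where(var <= 0.0)[0]
            raise ValueError(
                f"zero variance in band {_name!r} on channel index "
                f"{dead.tolist()}: flat or dead channel"
            )
        out[:, j] = np.log(var)
    return out.ravel()  # channel-major: ch0 bands.., ch1 bands..


def extract_features(
    seg: Segment,
    band_defs: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
    order: int = 2,
    ripple_db: float = 0.5,
) -> np.ndarray:
    """Natural log of the variance of each band-filtered channel.

    Returns a vector of length ``n_channels * n_bands`` in channel-major
    order (all bands of channel 0, then channel 1, ...).  A flat channel
    (zero variance) raises, since its log band power is undefined.
    """
    return _segment_features(seg.data, seg.fs, band_defs, order, ripple_db)


def feature_index(
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    band_defs: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
) -> list[tuple[str, str]]:
    """(channel, band) pair for each position of the feature vector."""
    return [(ch, band[0]) for ch in channel_names for band in band_defs]


def compute_baseline(idle_features: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the idle-condition observations."""
    feats = np.asarray(list(idle_features), dtype=float)
    if feats.size == 0:
        raise ValueError("no idle observations to average")
    return feats.mean(axis=0)


def _auto_ridge(pooled: np.ndarray, weight: float = 1e-2) -> float:
    # scale-free Tikhonov weight; 70 features from ~80 observations keep
    # the pooled covariance severely rank-deficient, so the default
    # shrinkage must be substantial to stabilize the fold-level fits
    return weight * np.trace(pooled) / pooled.shape[0]


def fit_lda(
    X_sad: np.ndarray,
    X_happy: np.ndarray,
    ridge: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Closed-form two-class LDA on already baseline-cleared, standardized
    observations.

    ``w = (S_sad + S_happy + ridge*I)^-1 (mu_happy - mu_sad)`` with the
    class-wise sample covariances, and the bias ``b`` chosen so that the
    discriminant ``d(f) = w.f + b`` is zero at the class-mean midpoint.
    Raises when the regularized matrix is still singular.
    """
    X1 = np.atleast_2d(np.asarray(X_sad, dtype=float))
    X2 = np.atleast_2d(np.asarray(X_happy, dtype=float))
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("need at least 2 observations per class")
    mu1 = X1.mean(axis=0)
    mu2 = X2.mean(axis=0)
    S = np.cov(X1, rowvar=False, ddof=1) + np.cov(X2, rowvar=False, ddof=1)
    S = np.atleast_2d(S) + ridge * np.eye(X1.shape[1])
    try:
        w = np.linalg.solve(S, mu2 - mu1)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; increase the ridge weight"
        ) from err
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "pooled covariance is ill-conditioned; increase the ridge weight"
        )
    b = -float(w @ (mu1 + mu2) / 2.0)
    return w, b


def _sigmoid(x):
    # clamped just inside (0, 1): the score is an open-interval control
    # signal and float saturation at |x| ~ 37 would otherwise hit 0 or 1
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return np.clip(s, 1e-12, 1.0 - 1e-12)


class SigmoidLDA(BaseEstimator, ClassifierMixin):
    """Closed-form two-class LDA with a sigmoid-squashed decision value.

    A scikit-learn estimator over plain (X, y) feature matrices: ``fit``
    computes the class means and covariances and the closed-form weight
    vector; ``decision_function`` is the midpoint-centered discriminant;
    ``predict_score`` maps it through ``1 / (1 + exp(-alpha * d))`` into
    the (0, 1) control signal.

    Parameters
    ----------
    ridge : float or "auto"
        Tikhonov weight added to the pooled covariance.  ``"auto"`` uses
        ``1e-2 * trace(S1 + S2) / n_features``, a scale-free default that
        keeps the 70-feature problem well posed from ~80 observations.
    alpha : float
        Sigmoid steepness (system reactivity); default 2.
    bias_mode : {"midpoint", "as-printed"}
        ``"midpoint"`` places the decision threshold at the class-mean
        midpoint so the midpoint scores exactly 0.5.  ``"as-printed"``
        reproduces the uncentered textbook-transcription variant
        ``d(f) = w.f + w.(mu1 + mu2)`` verbatim.
    """

    def __init__(
        self,
        ridge: float | str = "auto",
        alpha: float = 2.0,
        bias_mode: str = "midpoint",
    ):
        self.ridge = ridge
        self.alpha = alpha
        self.bias_mode = bias_mode

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SigmoidLDA is strictly two-class")
        if self.bias_mode not in ("midpoint", "as-printed"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        X1 = X[y == self.classes_[0]]
        X2 = X[y == self.classes_[1]]
        if X1.shape[0] < 2 or X2.shape[0] < 2:
            raise ValueError("need at least 2 observations per class")
        mu1 = X1.mean(axis=0)
        mu2 = X2.mean(axis=0)
        S = np.cov(X1, rowvar=False, ddof=1) + np.cov(
            X2, rowvar=False, ddof=1
        )
        S = np.atleast_2d(np.asarray(S, dtype=float))
        lam = _auto_ridge(S) if self.ridge == "auto" else float(self.ridge)
        S = S + lam * np.eye(X.shape[1])
        try:
            w = np.linalg.solve(S, mu2 - mu1)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular; increase the ridge weight"
            ) from err
        self.coef_ = w
        self.means_ = np.vstack([mu1, mu2])
        self.ridge_ = lam
        if self.bias_mode == "midpoint":
            self.intercept_ = -float(w @ (mu1 + mu2) / 2.0)
        else:
            self.intercept_ = float(w @ (mu1 + mu2))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return np.where(
            self.decision_function(X) > 0, self.classes_[1], self.classes_[0]
        )

    def predict_score(self, X):
        """Continuous control signal s in (0, 1); class 1 maps toward 1."""
        return _sigmoid(self.alpha * self.decision_function(X))


@dataclass
class AffectModel:
    """The serializable product of calibration.

    Holds everything the online phase needs: the idle baseline vector, the
    feature standardization parameters, the LDA weight vector and bias
    (midpoint-centered discriminant), the sigmoid steepness, the filter
    and montage configuration, and bookkeeping counts.
    """

    baseline: np.ndarray
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    w: np.ndarray
    b: float
    alpha: float
    ridge: float
    band_defs: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = DEFAULT_FS
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    filter_order: int = 2
    ripple_db: float = 0.5
    class_orientation: tuple[str, str] = MUSIC_CLASSES  # (score->0, score->1)
    n_obs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.feat_mean = np.asarray(self.feat_mean, dtype=float)
        self.feat_sd = np.asarray(self.feat_sd, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.w)
        for name in ("baseline", "feat_mean", "feat_sd"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != weight-vector length")
        if np.any(self.feat_sd <= 0):
            raise ValueError("feat_sd must be strictly positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        self.band_defs = tuple(
            (str(nm), float(lo), float(hi)) for nm, lo, hi in self.band_defs
        )
        self.channel_names = tuple(self.channel_names)

    @property
    def n_features(self) -> int:
        return len(self.w)

    def prepare(self, f_raw: np.ndarray) -> np.ndarray:
        """Baseline-subtract and standardize a raw feature vector."""
        f_raw = np.asarray(f_raw, dtype=float)
        if f_raw.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {f_raw.shape[-1]}"
            )
        return (f_raw - self.baseline - self.feat_mean) / self.feat_sd

    def discriminant(self, f: np.ndarray) -> float:
        return float(np.asarray(f, dtype=float) @ self.w + self.b)

    def score_features(self, f_raw: np.ndarray, time: float = 0.0) -> Score:
        """Score a raw (unnormalized) feature vector."""
        d = self.discriminant(self.prepare(f_raw))
        return Score(value=float(_sigmoid(self.alpha * d)), time=time)

    def score_window(self, data: np.ndarray, time: float = 0.0) -> Score:
        """Score one channels x samples window of raw EEG."""
        f_raw = _segment_features(
            np.asarray(data, dtype=float),
            self.fs,
            self.band_defs,
            self.filter_order,
            self.ripple_db,
        )
        return self.score_features(f_raw, time=time)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "alpha": self.alpha,
            "ridge": self.ridge,
            "band_defs": [list(bd) for bd in self.band_defs],
            "channel_names": list(self.channel_names),
            "fs": self.fs,
            "window_s": self.window_s,
            "step_s": self.step_s,
            "filter_order": self.filter_order,
            "ripple_db": self.ripple_db,
            "class_orientation": list(self.class_orientation),
            "n_obs": dict(self.n_obs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffectModel":
        d = dict(d)
        d["band_defs"] = tuple(tuple(bd) for bd in d["band_defs"])
        d["channel_names"] = tuple(d["channel_names"])
        d["class_orientation"] = tuple(d["class_orientation"])
        return cls(**d)

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "AffectModel":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def score(model: AffectModel, f: np.ndarray, time: float = 0.0) -> Score:
    """Sigmoid-squashed discriminant of an already-prepared feature vector.

    ``f`` must already be baseline-subtracted and standardized with the
    model's parameters; ``s = 1 / (1 + exp(-alpha * d(f)))`` with the
    midpoint-centered discriminant ``d``.
    """
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {f.shape[-1]}"
        )
    d = model.discriminant(f)
    return Score(value=float(_sigmoid(model.alpha * d)), time=time)


class AffectDecoder(BaseEstimator):
    """Recording-level calibration pipeline as a fit-once estimator.

    ``fit`` consumes an annotated :class:`EEGRecording` (>= 2 happy and
    >= 2 sad listening periods, >= 1 idle period) and runs the full
    pipeline; fitted state lands in ``model_`` (an :class:`AffectModel`)
    plus the usual trailing-underscore attributes.  The plain-function
    surface (:func:`calibrate`, :func:`stream_scores`) wraps this class.
    """

    def __init__(
        self,
        window_s: float = WINDOW_S,
        step_s: float = STEP_S,
        bands: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
        ridge: float | str = "auto",
        alpha: float = 2.0,
        filter_order: int = 2,
        ripple_db: float = 0.5,
        bias_mode: str = "midpoint",
        target_fs: float = DEFAULT_FS,
    ):
        self.window_s = window_s
        self.step_s = step_s
        self.bands = bands
        self.ridge = ridge
        self.alpha = alpha
        self.filter_order = filter_order
        self.ripple_db = ripple_db
        self.bias_mode = bias_mode
        self.target_fs = target_fs

    def fit(self, rec: EEGRecording, y=None):
        labels = [label for _, _, label in rec.events]
        for cls_label, minimum in (("happy", 2), ("sad", 2), ("idle", 1)):
            if labels.count(cls_label) < minimum:
                raise ValueError(
                    f"calibration recording lacks {cls_label!r} periods "
                    f"(need >= {minimum}, found {labels.count(cls_label)})"
                )
        rec = rec.resampled(self.target_fs)

        segments = segment_stream(
            rec,
            window_s=self.window_s,
            step_s=self.step_s,
            labels={"happy", "sad", "idle"},
        )
        feats: dict[str, list[np.ndarray]] = {
            "happy": [], "sad": [], "idle": []
        }
        for seg in segments:
            feats[seg.label].append(
                _segment_features(
                    seg.data, rec.fs, self.bands,
                    self.filter_order, self.ripple_db,
                )
            )
        baseline = compute_baseline(feats["idle"])
        X_sad = np.asarray(feats["sad"]) - baseline
        X_happy = np.asarray(feats["happy"]) - baseline

        both = np.vstack([X_sad, X_happy])
        feat_mean = both.mean(axis=0)
        feat_sd = both.std(axis=0)
        if np.any(feat_sd <= 0):
            raise ValueError("a feature is constant across calibration data")
        Z = (both - feat_mean) / feat_sd
        y_cls = np.r_[
            np.zeros(len(X_sad), dtype=int), np.ones(len(X_happy), dtype=int)
        ]

        lda = SigmoidLDA(
            ridge=self.ridge, alpha=self.alpha, bias_mode=self.bias_mode
        ).fit(Z, y_cls)

        self.lda_ = lda
        self.baseline_ = baseline
        self.mean_ = feat_mean
        self.scale_ = feat_sd
        self.n_features_in_ = both.shape[1]
        self.model_ = AffectModel(
            baseline=baseline,
            feat_mean=feat_mean,
            feat_sd=feat_sd,
            w=lda.coef_,
            b=lda.intercept_,
            alpha=self.alpha,
            ridge=lda.ridge_,
            band_defs=tuple(self.bands),
            channel_names=rec.channel_names,
            fs=rec.fs,
            window_s=self.window_s,
            step_s=self.step_s,
            filter_order=self.filter_order,
            ripple_db=self.ripple_db,
            n_obs={k: len(v) for k, v in feats.items()},
        )
        return self

    def stream_scores(self, rec: EEGRecording) -> list[Score]:
        return stream_scores(self.model_, rec)


def calibrate(rec: EEGRecording, **kwargs) -> AffectModel:
    """Run the full calibration pipeline on an annotated recording.

    Keyword arguments are forwarded to :class:`AffectDecoder`.  Returns
    the serializable :class:`AffectModel` carrying every parameter the
    online phase needs (baseline, standardization, weights, sigmoid
    steepness, filter and montage configuration).
    """
    return AffectDecoder(**kwargs).fit(rec).model_


def stream_scores(model: AffectModel, rec: EEGRecording) -> list[Score]:
    """Score a recording exactly as the online system would.

    One score per ``step_s``, each computed from the latest full
    ``window_s`` of data; the first score lands at t = ``window_s``.
    """
    if tuple(rec.channel_names) != tuple(model.channel_names):
        raise ValueError("recording montage does not match the model")
    rec = rec.resampled(model.fs)
    if rec.duration < model.window_s:
        raise ValueError("recording shorter than one analysis window")
    n_win = int(round(model.window_s * model.fs))
    step = int(round(model.step_s * model.fs))
    out: list[Score] = []
    i0 = 0
    while i0 + n_win <= rec.samples.shape[1]:
        t_end = (i0 + n_win) / model.fs
        out.append(
            model.score_window(rec.samples[:, i0 : i0 + n_win], time=t_end)
        )
        i0 += step
    return out
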