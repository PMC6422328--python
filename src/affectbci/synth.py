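"""Synthetic EEG and a simulated responder for closed-loop testing.

Real affective EEG cannot be downloaded or re-recorded, so every other
module is exercised on generated data with controllable structure:

* a 1/f^exponent Gaussian background per channel (the canonical EEG
  spectral shape), unit variance before microvolt scaling;
* calibration recordings following the stimulus schedule, with
  class-dependent band-limited oscillatory components added on selected
  channels — amplitude-modulated narrowband noise rather than pure
  sinusoids, so log-variance features stay realistically dispersed;
* a "responder": a sample source whose internal affect state drifts
  toward the active task target during action periods (emulating a
  participant self-inducing the target emotion) and relaxes toward a
  personal bias at rest, expressed as a monotone band-amplitude gain on
  coupled channels;
* planted vector-autoregressive pairs for causality-analysis tests.

All generators are fully seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal

from .decoder import (
    DEFAULT_CHANNELS,
    DEFAULT_FS,
    AffectModel,
    EEGRecording,
    calibrate,
)
from .loop import StimulusSchedule, build_calibration_schedule

__all__ = [
    "EffectSpec",
    "ResponderConfig",
    "Responder",
    "gen_background",
    "gen_calibration_recording",
    "responder_stream",
    "make_responder_setup",
    "gen_var_pair",
]

#: default microvolt scale of the background (SD per channel)
BACKGROUND_SD_UV = 10.0

#: tail appended after the schedule so every window is full length
TAIL_S = 4.0


def gen_background(
    n_channels: int = 14,
    duration: float = 10.0,
    fs: float = DEFAULT_FS,
    exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EEGRecording:
    """Independent 1/f^exponent Gaussian noise per channel, unit variance.

    Spectral shaping is done in the frequency domain (amplitude ∝
    f^(-exponent/2), DC removed), then each channel is rescaled to unit
    sample variance.  ``exponent=0`` gives white noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration * fs))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    data = np.fft.irfft(spec * shape, n=n, axis=1)
    data /= data.std(axis=1, keepdims=True)
    names = tuple(DEFAULT_CHANNELS[:n_channels]) if n_channels <= 14 else (
        tuple(f"ch{i}" for i in range(n_channels))
    )
    return EEGRecording(samples=data, fs=fs, channel_names=names)


def _narrowband_carrier(
    n_channels: int,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(
        4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="bandpass",
        output="sos",
    )
    carrier = signal.sosfiltfilt(sos, white, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    return carrier


@dataclass(frozen=True)
class EffectSpec:
    """Planted class-dependent oscillatory effect for calibration data.

    ``class_amps`` gives the added narrowband amplitude (µV SD) on the
    designated channels for each stimulus class; ``effect_size`` scales
    all of them jointly (0 → pure background, the null condition).
    """

    channels: tuple[str, ...] = ("P7", "P8", "O1", "O2")
    band: tuple[float, float] = (8.0, 13.0)  # alpha
    class_amps: dict = field(
        default_factory=lambda: {"sad": 15.0, "neutral": 10.0, "happy": 5.0}
    )
    background_sd: float = BACKGROUND_SD_UV
    noise_exponent: float = 1.0
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.class_amps.values()):
            raise ValueError("class amplitudes must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(effect_size=0.0)

    @classmethod
    def strong(cls) -> "EffectSpec":
        return cls(effect_size=2.5)

    @classmethod
    def responder_aligned(cls, effect_size: float = 1.5) -> "EffectSpec":
        """Gamma effect on fronto-central channels, happy = more gamma —
        the same coupling the default responder uses, so a model
        calibrated on this data decodes the responder's state."""
        return cls(
            channels=("FC5", "FC6"),
            band=(30.0, 47.0),
            class_amps={"sad": 5.0, "neutral": 10.0, "happy": 15.0},
            effect_size=effect_size,
        )


def gen_calibration_recording(
    effect: EffectSpec,
    seed: int,
    schedule: StimulusSchedule | None = None,
    fs: float = DEFAULT_FS,
) -> EEGRecording:
    """Synthetic calibration recording following the stimulus schedule.

    180 s of scheduled periods (six 20-s excerpts, six 10-s idles) plus a
    4-s background tail so that windows labeled by their start time are
    always full length.  During happy/sad/neutral periods the class's
    narrowband component is added on the effect channels; idle periods
    are background only.  Event annotations are embedded.
    """
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_calibration_schedule(
            int(rng.integers(0, 2**31 - 1))
        )
    total = schedule.total_duration + TAIL_S
    bg = gen_background(
        n_channels=14,
        duration=total,
        fs=fs,
        exponent=effect.noise_exponent,
        seed=rng,
    )
    data = bg.samples * effect.background_sd
    names = bg.channel_names

    idx = [names.index(ch) for ch in effect.channels]
    n = data.shape[1]
    carrier = _narrowband_carrier(len(idx), n, fs, effect.band, rng)
    for onset, duration, label in schedule.to_events():
        if label not in effect.class_amps:
            continue
        amp = effect.effect_size * effect.class_amps[label]
        if amp == 0.0:
            continue
        i0 = int(round(onset * fs))
        i1 = int(round((onset + duration) * fs))
        data[idx, i0:i1] += amp * carrier[:, i0:i1]
    return EEGRecording(
        samples=data,
        fs=fs,
        channel_names=names,
        events=schedule.to_events(),
    )


@dataclass(frozen=True)
class ResponderConfig:
    """Simulated participant coupled to the feedback loop.

    The internal affect state s* in [0, 1] follows first-order dynamics:
    during action periods it tracks the task target (1 for ``to_happy``,
    0 for ``to_sad``) at ``tracking_rate`` per second; otherwise it
    relaxes toward the personal ``bias`` at ``relax_rate``.  The state is
    expressed in the EEG as a coupled-band narrowband component on the
    coupled channels whose amplitude is ``gain_map(s*)`` (monotone; the
    default interpolates linearly between ``amp_sad`` and ``amp_happy``
    µV).  A zero tracking rate or flat gain decouples the responder.
    """

    coupled_channels: tuple[str, ...] = ("FC5", "FC6")
    coupled_band: tuple[float, float] = (30.0, 47.0)  # gamma
    amp_sad: float = 5.0
    amp_happy: float = 15.0
    gain_map: Callable[[float], float] | None = None
    tracking_rate: float = 0.5  # 1/s toward the task target during action
    relax_rate: float = 0.3  # 1/s toward the bias otherwise
    # resting set-point slightly below neutral: resting EEG tends toward
    # the low-arousal side, which makes the happy-directed task the more
    # frequent assignment
    bias: float = 0.45
    state_noise_sd: float = 0.08  # per-sqrt(s) OU fluctuation of the state
    noise_exponent: float = 1.0
    background_sd: float = BACKGROUND_SD_UV
    buffer_s: float = 1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracking_rate < 0 or self.relax_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.bias <= 1.0):
            raise ValueError("bias must lie in [0, 1]")

    def amplitude(self, state: float, bg_var: float = 0.0) -> float:
        """Coupled-band amplitude (µV SD) expressed by an affect state.

        The default map is monotone and linear in *log band power* on
        top of the background: the total in-band variance interpolates
        geometrically between the sad and happy levels, so the decoder's
        log-variance feature moves linearly with the state and state 0.5
        sits at the feature-space midpoint of the two extremes.
        """
        if self.gain_map is not None:
            return float(self.gain_map(state))
        lo = bg_var + self.amp_sad**2
        hi = bg_var + self.amp_happy**2
        total = lo ** (1.0 - state) * hi**state
        return float(np.sqrt(max(total - bg_var, 0.0)))


_TASK_TARGET = {"to_happy": 1.0, "to_sad": 0.0}


class Responder:
    """Streaming EEG source driven by the responder's internal state.

    Pre-generates a long background and coupled-band carrier at
    construction (fully seeded); ``next_block`` advances the state
    dynamics and returns background + state-scaled carrier.  The buffer
    is tiled if a session outruns it.
    """

    def __init__(
        self,
        cfg: ResponderConfig,
        channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
        fs: float = DEFAULT_FS,
    ):
        missing = [c for c in cfg.coupled_channels if c not in channel_names]
        if missing:
            raise ValueError(
                f"coupled channels {missing} absent from the montage"
            )
        self.cfg = cfg
        self.channel_names = tuple(channel_names)
        self.fs = fs
        rng = np.random.default_rng(cfg.seed)
        n = int(round(cfg.buffer_s * fs))
        bg = gen_background(
            n_channels=len(channel_names),
            duration=cfg.buffer_s,
            fs=fs,
            exponent=cfg.noise_exponent,
            seed=rng,
        )
        self._bg = bg.samples * cfg.background_sd
        self._idx = [channel_names.index(c) for c in cfg.coupled_channels]
        self._carrier = _narrowband_carrier(
            len(self._idx), n, fs, cfg.coupled_band, rng
        )
        # background variance inside the coupled band, for the log-linear
        # default gain map
        sos = signal.butter(
            4,
            [cfg.coupled_band[0] / (fs / 2), cfg.coupled_band[1] / (fs / 2)],
            btype="bandpass",
            output="sos",
        )
        probe = signal.sosfiltfilt(
            sos, self._bg[self._idx, : min(n, int(60 * fs))], axis=1
        )
        self._bg_band_var = float(probe.var(axis=1).mean())
        self._state_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1])
        )
        self._pos = 0
        self.state = cfg.bias
        self.state_trace: list[tuple[float, float]] = []
        self._time = 0.0

    def next_block(
        self, n_samples: int, phase: str, task: str | None
    ) -> np.ndarray:
        cfg = self.cfg
        dt = n_samples / self.fs
        if phase == "action" and task in _TASK_TARGET:
            target, rate = _TASK_TARGET[task], cfg.tracking_rate
        else:
            target, rate = cfg.bias, cfg.relax_rate
        self.state += min(rate * dt, 1.0) * (target - self.state)
        self.state += cfg.state_noise_sd * np.sqrt(dt) * (
            self._state_rng.standard_normal()
        )
        self.state = min(max(self.state, 0.0), 1.0)
        self._time += dt
        self.state_trace.append((self._time, self.state))

        n_buf = self._bg.shape[1]
        i0 = self._pos % n_buf
        if i0 + n_samples <= n_buf:
            bg = self._bg[:, i0 : i0 + n_samples]
            car = self._carrier[:, i0 : i0 + n_samples]
        else:  # wrap
            k = n_buf - i0
            bg = np.concatenate(
                [self._bg[:, i0:], self._bg[:, : n_samples - k]], axis=1
            )
            car = np.concatenate(
                [self._carrier[:, i0:], self._carrier[:, : n_samples - k]],
                axis=1,
            )
        self._pos += n_samples
        block = bg.copy()
        amp = cfg.amplitude(self.state, bg_var=self._bg_band_var)
        block[self._idx] += amp * car
        return block


def responder_stream(
    cfg: ResponderConfig,
    model: AffectModel,
    protocol=None,
) -> Responder:
    """Build a streaming source matched to a calibrated model's montage.

    The phase/task protocol is supplied block-by-block by the session
    runner, so ``protocol`` is accepted for interface symmetry only.
    """
    return Responder(cfg, channel_names=model.channel_names, fs=model.fs)


def make_responder_setup(
    seed: int,
    effect_size: float = 1.5,
    cfg: ResponderConfig | None = None,
    **calibrate_kwargs,
) -> tuple[AffectModel, Responder]:
    """Calibrated model + aligned responder for closed-loop simulation.

    Generates a calibration recording whose class effect lives in the
    same band/channels the responder couples through (gamma on FC5/FC6,
    happy = larger amplitude), calibrates a model on it, and builds the
    responder.  All randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    effect = EffectSpec.responder_aligned(effect_size=effect_size)
    rec = gen_calibration_recording(
        effect, seed=int(rng.integers(0, 2**31 - 1))
    )
    model = calibrate(rec, **calibrate_kwargs)
    if cfg is None:
        # gain range mirrors the calibration amplitudes, so the decoder's
        # class midpoint corresponds to the responder's mid state
        cfg = ResponderConfig(
            amp_sad=effect.effect_size * effect.class_amps["sad"],
            amp_happy=effect.effect_size * effect.class_amps["happy"],
            coupled_channels=effect.channels,
            coupled_band=effect.band,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    responder = Responder(cfg, model.channel_names, model.fs)
    return model, responder


def gen_var_pair(
    coef: float,
    lag: int = 1,
    n: int = 600,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted unidirectional pair: x white noise, y(t) = coef·x(t-lag) + e.

    With ``coef=0`` the two series are independent.
    """
    if abs(coef) >= 1:
        raise ValueError("|coef| must be < 1")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = e.copy()
    y[lag:] += coef * x[:-lag]
    return x, y
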