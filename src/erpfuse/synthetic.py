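"""Synthetic oddball-EEG cohorts with feature-selective condition effects.

The simulator emulates the geometry of a typical visual-oddball ERP study
(many participants, 32 channels at 150 Hz, epochs of [-1000, +2000] ms with
24 rare and 135 frequent trials) and realizes three archetypes of brain
response on top of 1/f background noise:

* **additive transient** — a phase-locked monophasic bump (Gaussian
  envelope) with trial-to-trial latency jitter and log-normal amplitude
  variability; visible to the average ERP.
* **oscillation power change** — an ongoing sinusoid with free (uniform)
  phase whose amplitude is multiplied post-stimulus by a smooth gain
  envelope (< 1 suppression, > 1 enhancement); invisible to the ERP,
  visible to time-frequency amplitude.
* **phase reset** — an ongoing sinusoid whose phase slides smoothly after
  stimulus onset to a reset value, with *bimodal* resets (fair coin between
  phi and phi + pi) keeping the trial-average near zero and the amplitude
  envelope exactly unchanged; visible only to cross-trial phase statistics.

Condition effects are introduced by giving the rare and frequent trials of
a source different parameters, so each scenario places the effect in
exactly the feature family it should be visible to (see
:func:`make_scenario`).

Everything is a pure function of ``(config, seed)``: per-participant and
per-source random streams are derived with ``numpy.random.SeedSequence`` so
cohorts reproduce bit-exactly and adding a source never perturbs the draws
of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import EpochedRecording, n_samples_for_window, time_axis

SCENARIOS = ("erp_only", "tfpower_only", "phase_only", "combined", "null")

SOURCE_KINDS = ("transient", "ongoing_oscillation")
PHASE_MODES = ("free", "reset_unimodal", "reset_bimodal")

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SourceSpec:
    """One neural source, for one condition.

    Transient sources use ``peak_latency_ms`` / ``width_fwhm_ms`` /
    ``amplitude_uv`` / ``sign``; ongoing sources use ``center_freq`` /
    ``amplitude_uv`` plus the phase and gain fields.  ``topography`` is the
    per-channel gain vector.  ``latency_jitter_sd_ms`` (Normal) and
    ``amplitude_cv`` (log-normal, mean 1) set trial-to-trial variability.

    ``phase_mode`` governs the phase of an ongoing source at stimulus
    onset: ``free`` leaves the uniform pre-stimulus phase untouched;
    ``reset_unimodal`` slides it to ``reset_phase``; ``reset_bimodal``
    slides it to ``reset_phase`` or ``reset_phase + pi`` on a fair coin.
    The slide is a smooth (raised-cosine) phase interpolation over
    ``reset_ramp_ms``, so the amplitude envelope of the source is constant
    by construction.  ``post_stimulus_gain`` multiplies the amplitude after
    onset, reached through a raised-cosine ramp of ``gain_ramp_ms``.
    """

    kind: str
    topography: tuple[float, ...]
    amplitude_uv: float = 1.0
    center_freq: float | None = None
    peak_latency_ms: float = 300.0
    width_fwhm_ms: float = 250.0
    sign: float = 1.0
    latency_jitter_sd_ms: float = 0.0
    amplitude_cv: float = 0.0
    phase_mode: str = "free"
    reset_phase: float = 0.0
    post_stimulus_gain: float = 1.0
    gain_ramp_ms: float = 200.0
    reset_ramp_ms: float = 700.0

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.phase_mode not in PHASE_MODES:
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if self.amplitude_cv < 0 or self.latency_jitter_sd_ms < 0:
            raise ValueError("variability parameters must be non-negative")
        if self.kind == "ongoing_oscillation" and not (self.center_freq or 0) > 0:
            raise ValueError("ongoing sources need center_freq > 0")
        object.__setattr__(self, "topography", tuple(float(g) for g in self.topography))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort; output is a pure function of it."""

    n_participants: int = 200
    n_rare: int = 24
    n_frequent: int = 135
    srate: float = 150.0
    window: tuple[float, float] = (-1000.0, 2000.0)
    n_channels: int = 32
    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    sources: tuple[tuple[SourceSpec, SourceSpec], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rare < 1 or self.n_frequent < 1:
            raise ValueError("need at least one trial per condition")
        for rare_spec, freq_spec in self.sources:
            for s in (rare_spec, freq_spec):
                if len(s.topography) != self.n_channels:
                    raise ValueError("source topography length must equal n_channels")

    @property
    def n_trials(self) -> int:
        return self.n_rare + self.n_frequent


def _rng(cfg: SimulationConfig, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(cfg.seed) & 0x7FFFFFFF, spawn_key=(participant, stream))
    )


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, exponent: float, rms: float
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^exponent, expected RMS ``rms``.

    Shaped in the frequency domain (zero DC), independent across the
    leading axes.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    w = np.zeros_like(f)
    w[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * w, n=n_samples, axis=-1)
    # variance of filtering unit white noise: mean |w|^2 over the full spectrum
    full_sq = w**2
    total = full_sq[0] + 2.0 * full_sq[1:-1].sum() + (
        full_sq[-1] if n_samples % 2 == 0 else 2.0 * full_sq[-1]
    )
    expected_sd = np.sqrt(total / n_samples)
    return shaped * (rms / expected_sd)


def _smooth_step(t_ms: np.ndarray, ramp_ms: float) -> np.ndarray:
    """0 before onset, raised-cosine rise over [0, ramp_ms], 1 after."""
    if ramp_ms <= 0:
        return (t_ms >= 0).astype(float)
    r = np.clip(t_ms / ramp_ms, 0.0, 1.0)
    return np.where(t_ms < 0, 0.0, 0.5 * (1.0 - np.cos(np.pi * r)))


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def _lognormal_factor(z: np.ndarray, cv: float) -> np.ndarray:
    """Mean-1 log-normal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones_like(z)
    s2 = np.log1p(cv**2)
    return np.exp(np.sqrt(s2) * z - s2 / 2.0)


def _source_trial_waveforms(
    cfg: SimulationConfig,
    pair: tuple[SourceSpec, SourceSpec],
    labels: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial (n_trials, n_channels, n_samples) contribution of one source.

    All per-trial random quantities are drawn once, up front, in a fixed
    order, so the draws do not depend on the condition assignment or on the
    presence of other sources.
    """
    n_trials = cfg.n_trials
    n_samples = n_samples_for_window(cfg.window, cfg.srate)
    t_ms = time_axis(cfg.window, cfg.srate)
    t_s = t_ms / 1000.0

    amp_z = rng.standard_normal(n_trials)
    jit_z = rng.standard_normal(n_trials)
    phase_pre = rng.uniform(-np.pi, np.pi, n_trials)
    coin = rng.integers(0, 2, n_trials)

    out = np.zeros((n_trials, cfg.n_channels, n_samples))
    for i, label in enumerate(labels):
        s = pair[0] if label == "rare" else pair[1]
        amp = s.amplitude_uv * _lognormal_factor(amp_z[i : i + 1], s.amplitude_cv)[0]
        if s.kind == "transient":
            lat = s.peak_latency_ms + s.latency_jitter_sd_ms * jit_z[i]
            sd = s.width_fwhm_ms * _FWHM_TO_SD
            wave = s.sign * amp * np.exp(-((t_ms - lat) ** 2) / (2.0 * sd**2))
        else:
            if s.phase_mode == "free":
                target = phase_pre[i]
            elif s.phase_mode == "reset_unimodal":
                target = s.reset_phase
            else:  # reset_bimodal
                target = s.reset_phase + np.pi * coin[i]
            delta = _wrap_phase(target - phase_pre[i])
            phi = phase_pre[i] + delta * _smooth_step(t_ms, s.reset_ramp_ms)
            gain = 1.0 + (s.post_stimulus_gain - 1.0) * _smooth_step(t_ms, s.gain_ramp_ms)
            wave = amp * gain * np.cos(2.0 * np.pi * s.center_freq * t_s + phi)
        out[i] = np.asarray(s.topography)[:, None] * wave[None, :]
    return out


def simulate_participant_components(
    cfg: SimulationConfig, participant_index: int
) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Background, per-source contributions, and labels for one participant.

    The summed data of :func:`simulate_participant` equals
    ``background + sum(source_contributions)`` exactly; exposing the parts
    makes superposition and noiseless-source properties directly testable.
    """
    n_samples = n_samples_for_window(cfg.window, cfg.srate)
    labels = ["rare"] * cfg.n_rare + ["frequent"] * cfg.n_frequent
    bg_rng = _rng(cfg, participant_index, 0)
    background = one_over_f_noise(
        bg_rng,
        (cfg.n_trials, cfg.n_channels),
        n_samples,
        cfg.background_exponent,
        cfg.background_rms_uv,
    )
    contributions = [
        _source_trial_waveforms(cfg, pair, labels, _rng(cfg, participant_index, k + 1))
        for k, pair in enumerate(cfg.sources)
    ]
    return background, contributions, labels


def simulate_participant(cfg: SimulationConfig, participant_index: int) -> EpochedRecording:
    """Simulate one participant's epoched recording (deterministic in
    ``(cfg.seed, participant_index)``)."""
    background, contributions, labels = simulate_participant_components(cfg, participant_index)
    data = background
    for c in contributions:
        data = data + c
    return EpochedRecording(
        data=data,
        srate=cfg.srate,
        window=cfg.window,
        labels=labels,
        participant_id=f"sim{participant_index:04d}",
    )


def simulate_cohort(cfg: SimulationConfig) -> list[EpochedRecording]:
    """Simulate all participants (independent random streams per participant)."""
    return [simulate_participant(cfg, p) for p in range(cfg.n_participants)]


# ---------------------------------------------------------------------------
# Scenario presets


def gaussian_topography(n_channels: int, center: float, width: float) -> tuple[float, ...]:
    """Smooth unimodal channel-gain profile; ``center``/``width`` are
    fractions of the channel axis."""
    pos = np.linspace(0.0, 1.0, n_channels)
    return tuple(np.exp(-((pos - center) ** 2) / (2.0 * width**2)))


def _transient_pair(n_channels: int, rare_amp: float, freq_amp: float) -> tuple[SourceSpec, SourceSpec]:
    topo = gaussian_topography(n_channels, center=0.55, width=0.18)
    common = dict(
        kind="transient",
        topography=topo,
        peak_latency_ms=300.0,
        width_fwhm_ms=250.0,
        latency_jitter_sd_ms=40.0,
        amplitude_cv=0.3,
    )
    return (
        SourceSpec(amplitude_uv=rare_amp, **common),
        SourceSpec(amplitude_uv=freq_amp, **common),
    )


def _power_pair(n_channels: int, rare_gain: float, freq_gain: float) -> tuple[SourceSpec, SourceSpec]:
    topo = gaussian_topography(n_channels, center=0.85, width=0.15)
    # posterior alpha stands well above the 1/f floor at 10 Hz in real EEG
    common = dict(
        kind="ongoing_oscillation",
        topography=topo,
        center_freq=10.0,
        amplitude_uv=12.0,
        amplitude_cv=0.3,
        phase_mode="free",
        gain_ramp_ms=200.0,
    )
    return (
        SourceSpec(post_stimulus_gain=rare_gain, **common),
        SourceSpec(post_stimulus_gain=freq_gain, **common),
    )


def _phase_pair(
    n_channels: int, rare_mode: str, freq_mode: str, center_freq: float = 8.0
) -> tuple[SourceSpec, SourceSpec]:
    topo = gaussian_topography(n_channels, center=0.2, width=0.15)
    common = dict(
        kind="ongoing_oscillation",
        topography=topo,
        center_freq=center_freq,
        amplitude_uv=10.0,
        amplitude_cv=0.3,
        reset_phase=0.0,
        reset_ramp_ms=700.0,
    )
    return (
        SourceSpec(phase_mode=rare_mode, **common),
        SourceSpec(phase_mode=freq_mode, **common),
    )


def make_scenario(
    name: str,
    n_participants: int = 200,
    n_channels: int = 32,
    seed: int = 0,
    srate: float = 150.0,
    window: tuple[float, float] = (-1000.0, 2000.0),
    n_rare: int = 24,
    n_frequent: int = 135,
) -> SimulationConfig:
    """Build a cohort config whose condition effect sits in chosen features.

    * ``erp_only`` — rare and frequent differ only in the amplitude of an
      additive transient (10 vs 4 microvolts, typical target-vs-standard
      P3 magnitudes).
    * ``tfpower_only`` — differ only in the post-stimulus gain of a
      free-phase 10 Hz oscillation (0.4 vs 0.8, i.e. stronger alpha
      suppression for rare); invisible to the ERP by phase averaging.
    * ``phase_only`` — differ only in the phase mode of an 8 Hz oscillation
      (bimodal reset vs free) with an unchanged amplitude envelope;
      invisible to the ERP by symmetry and to TF amplitude by construction.
    * ``combined`` — all three effects at once, on distinct topographies.
    * ``null`` — rare and frequent statistically identical.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if name == "erp_only":
        sources = (_transient_pair(n_channels, 10.0, 4.0),)
    elif name == "tfpower_only":
        sources = (_power_pair(n_channels, 0.4, 0.8),)
    elif name == "phase_only":
        sources = (_phase_pair(n_channels, "reset_bimodal", "free"),)
    elif name == "combined":
        sources = (
            _transient_pair(n_channels, 10.0, 4.0),
            _power_pair(n_channels, 0.4, 0.8),
            _phase_pair(n_channels, "reset_bimodal", "free"),
        )
    else:  # null
        sources = (
            _transient_pair(n_channels, 3.0, 3.0),
            _power_pair(n_channels, 0.6, 0.6),
        )
    return SimulationConfig(
        n_participants=n_participants,
        n_rare=n_rare,
        n_frequent=n_frequent,
        srate=srate,
        window=window,
        n_channels=n_channels,
        sources=sources,
        seed=seed,
    )


def scaled_scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Fast preset for tests and desk-scale runs: 12 participants, 8 channels."""
    return make_scenario(name, n_participants=12, n_channels=8, seed=seed)


# ---------------------------------------------------------------------------
# YAML round-trip


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["window"] = list(cfg.window)
    d["sources"] = [
        [
            {**asdict(s), "topography": list(s.topography)}
            for s in pair
        ]
        for pair in cfg.sources
    ]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["window"] = tuple(d["window"])
    d["sources"] = tuple(
        (SourceSpec(**pair[0]), SourceSpec(**pair[1])) for pair in d.get("sources", [])
    )
    return SimulationConfig(**d)


def save_config(cfg: SimulationConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
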