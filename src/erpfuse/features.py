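"""The three brain-response feature families: ERP, time-frequency amplitude,
and phase dynamics.

* **ERP** — the arithmetic average of epochs within a condition; keeps
  phase-locked transients, cancels non-phase-locked oscillations.
* **TF power** — the modulus (amplitude, deliberately *not* squared) of
  complex Morlet wavelet coefficients per trial, optionally averaged.
* **Phase dynamics** — either the raw single-trial wavelet phase angle, or
  the cross-trial *phase synchronization* statistic: at each
  (channel, frequency, time) point the trial phases are histogrammed into
  10 equal bins on (-pi, pi] and the statistic is the standard deviation of
  the bin probabilities, ``sqrt(sum_i (p_i - 0.1)^2 / 10)``.  It is 0 for a
  perfectly uniform histogram and 0.3 when every phase falls in one bin.

All features are baseline-corrected to a pre-stimulus window (per channel
for the ERP; per channel and frequency for TF amplitude and phase sync);
raw phase angles are not baselined, since angles are not additive offsets.

Wavelet convention
------------------
The mother wavelet is ``psi(t) = (pi*fb)^(-1/2) exp(-t^2/fb) exp(i 2 pi fc t)``
with centre frequency ``fc = 1`` Hz and time-decay (bandwidth) parameter
``fb`` in s^2 (default 0.5); analysis frequency ``f`` uses scale
``a = fc / f``, so ``1/a`` is proportional to ``f``.  Coefficients
``W(a, b) = a^(-1/2) * integral S(t) psi*((t - b)/a) dt`` are evaluated by
FFT convolution and scaled by ``2 / sqrt(a)`` so that a unit-amplitude
sinusoid at ``f`` yields modulus 1 in the epoch interior (only baselined
differences matter downstream, so the absolute calibration is a
convenience, not a claim about physical units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .data_model import BaselineSpec, EpochedRecording, baseline_correct, time_axis

FEATURE_KINDS = ("erp", "tf_power", "phase_sync", "tf_phase")

N_PHASE_BINS = 10
PHASE_SYNC_MAX = 0.3  # sqrt((0.9^2 + 9 * 0.1^2) / 10): all phases in one bin

_ENVELOPE_CUTOFF = 1e-5  # truncate the kernel where the envelope falls below this


@dataclass(frozen=True)
class WaveletSpec:
    """Complex Morlet analysis grid.

    Parameters
    ----------
    decay
        Time-decay (bandwidth) parameter ``fb`` of the mother wavelet, in
        s^2.  Larger values trade time resolution for frequency resolution.
    freqs
        Analysis frequencies in Hz, each in (0, srate/2).
    srate
        Sampling rate of the signal, Hz.
    """

    decay: float = 0.5
    freqs: tuple[float, ...] = tuple(float(f) for f in range(2, 31))
    srate: float = 150.0

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        for f in self.freqs:
            if not 0.0 < f < self.srate / 2.0:
                raise ValueError(f"frequency {f} Hz outside (0, Nyquist={self.srate / 2} Hz)")

    def scale(self, f: float) -> float:
        """Wavelet scale for analysis frequency ``f`` (mother fc = 1 Hz)."""
        return 1.0 / float(f)


def morlet_kernel(f: float, spec: WaveletSpec) -> np.ndarray:
    """Sampled, scale-dilated complex Morlet wavelet for frequency ``f``.

    Returns ``psi(t_m / a)`` on a symmetric grid ``t_m = m / srate``,
    truncated where the Gaussian envelope drops below 1e-5 of its peak.
    Prefactors (``a^(-1/2)``, dt, amplitude calibration) are applied in
    :func:`cwt`, not here.
    """
    if f >= spec.srate / 2.0:
        raise ValueError(f"frequency {f} Hz is at or above Nyquist ({spec.srate / 2} Hz)")
    fb = spec.decay
    a = spec.scale(f)
    # envelope exp(-(t/a)^2 / fb) < cutoff  <=>  |t| > a * sqrt(fb * ln(1/cutoff))
    t_max = a * np.sqrt(fb * np.log(1.0 / _ENVELOPE_CUTOFF))
    m = int(np.ceil(t_max * spec.srate))
    t = np.arange(-m, m + 1) / spec.srate
    u = t / a
    return (np.pi * fb) ** -0.5 * np.exp(-(u**2) / fb) * np.exp(2j * np.pi * u)


@dataclass
class SpectralDecomposition:
    """Complex CWT coefficients ``(n_trials, n_channels, n_freqs, n_samples)``.

    The modulus of ``coeffs`` estimates oscillation amplitude and the angle
    estimates phase.  ``edge_halfwidth[j]`` is the kernel half-length (in
    samples) at frequency ``freqs[j]``: coefficients closer than that to an
    epoch edge were computed with zero-padding and should be treated as
    contaminated (see :meth:`valid_mask`).
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    srate: float
    window: tuple[float, float]
    edge_halfwidth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[2] != self.freqs.size:
            raise ValueError("coeffs must be (n_trials, n_channels, n_freqs, n_samples)")
        if self.edge_halfwidth is None:
            self.edge_halfwidth = np.zeros(self.freqs.size, dtype=int)

    @property
    def times(self) -> np.ndarray:
        return time_axis(self.window, self.srate)

    def valid_mask(self) -> np.ndarray:
        """Boolean ``(n_freqs, n_samples)``: True where coefficients are
        unaffected by epoch-edge zero-padding."""
        n = self.coeffs.shape[3]
        idx = np.arange(n)
        return (idx[None, :] >= self.edge_halfwidth[:, None]) & (
            idx[None, :] <= n - 1 - self.edge_halfwidth[:, None]
        )


@dataclass
class FeatureSample:
    """One labeled classifier input.

    ``kind`` is one of ``erp`` (channels x time), ``tf_power``,
    ``phase_sync`` or ``tf_phase`` (channels x freqs x time).  ``trial_ids``
    records which trials of the source recording produced the tensor.
    """

    kind: str
    tensor: np.ndarray
    label: str
    participant_id: str = ""
    trial_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.tensor = np.asarray(self.tensor)
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("feature tensor contains non-finite values")

    def flatten(self) -> np.ndarray:
        return self.tensor.reshape(-1)


def compute_erp(
    rec: EpochedRecording,
    trial_subset,
    baseline: BaselineSpec = BaselineSpec(),
    label: str | None = None,
) -> FeatureSample:
    """Average the selected epochs and baseline-correct per channel."""
    idx = np.asarray(trial_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("trial subset must be non-empty")
    erp = rec.data[idx].mean(axis=0)
    erp = baseline_correct(erp, rec.times, baseline)
    if label is None:
        labs = {rec.labels[i] for i in idx}
        label = labs.pop() if len(labs) == 1 else "frequent"
    return FeatureSample(
        kind="erp",
        tensor=erp,
        label=label,
        participant_id=rec.participant_id,
        trial_ids=tuple(int(i) for i in idx),
    )


def cwt(rec: EpochedRecording, spec: WaveletSpec) -> SpectralDecomposition:
    """Continuous wavelet transform of every trial and channel.

    Evaluates ``W(a, b) = a^(-1/2) * sum_t S(t) psi*((t - b)/a) dt`` by FFT
    convolution (the Morlet kernel's conjugate time-reverse equals itself),
    then multiplies by ``2 / sqrt(a)`` so a unit-amplitude sinusoid at the
    analysis frequency has modulus ~1 away from the epoch edges.
    """
    if spec.srate != rec.srate:
        raise ValueError(f"wavelet srate {spec.srate} != recording srate {rec.srate}")
    n = rec.n_samples
    dt = 1.0 / rec.srate
    out = np.empty((rec.n_trials, rec.n_channels, len(spec.freqs), n), dtype=np.complex128)
    halfwidths = np.empty(len(spec.freqs), dtype=int)
    for j, f in enumerate(spec.freqs):
        kernel = morlet_kernel(f, spec)
        half = (kernel.size - 1) // 2
        if kernel.size > n:
            raise ValueError(
                f"epoch of {n} samples is shorter than the {kernel.size}-sample "
                f"kernel at {f} Hz"
            )
        a = spec.scale(f)
        gain = dt * a**-0.5 * 2.0 * a**-0.5  # Riemann dt, a^(-1/2), unit-sinusoid calibration
        out[:, :, j, :] = fftconvolve(rec.data, kernel[None, None, :], mode="same", axes=2) * gain
        halfwidths[j] = half
    return SpectralDecomposition(
        coeffs=out,
        freqs=np.asarray(spec.freqs),
        srate=rec.srate,
        window=rec.window,
        edge_halfwidth=halfwidths,
    )


def cwt_direct(signal: np.ndarray, spec: WaveletSpec, srate: float) -> np.ndarray:
    """Reference CWT by direct numerical integration (one channel).

    Literal Riemann-sum evaluation of the coefficient integral at every
    translation ``b``, with the same calibration as :func:`cwt`.  Quadratic
    in the epoch length — an oracle for small inputs, not a pipeline path.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    dt = 1.0 / srate
    t = np.arange(n) * dt
    out = np.empty((len(spec.freqs), n), dtype=np.complex128)
    fb = spec.decay
    for j, f in enumerate(spec.freqs):
        a = spec.scale(f)
        gain = dt * a**-0.5 * 2.0 * a**-0.5
        t_max = a * np.sqrt(fb * np.log(1.0 / _ENVELOPE_CUTOFF))
        # truncate at whole samples, like the discrete kernel
        cut = np.ceil(t_max * srate) * dt + 0.5 * dt
        for bi in range(n):
            u = (t - t[bi]) / a
            u = np.where(np.abs(t - t[bi]) <= cut, u, np.nan)
            psi = (np.pi * fb) ** -0.5 * np.exp(-(u**2) / fb) * np.exp(2j * np.pi * u)
            psi = np.nan_to_num(psi)
            out[j, bi] = np.sum(signal * np.conj(psi)) * gain
    return out


def tf_power(
    dec: SpectralDecomposition,
    trial_subset,
    baseline: BaselineSpec = BaselineSpec(),
    average: bool = True,
    label: str = "frequent",
    participant_id: str = "",
) -> FeatureSample | list[FeatureSample]:
    """Wavelet amplitude (modulus, not squared), baselined per (channel, freq).

    With ``average=True`` the per-trial moduli are averaged over the subset
    into a single sample; otherwise one baselined sample per trial is
    returned.
    """
    idx = np.asarray(trial_subset, dtype=int)
    if idx.size == 0:
        raise ValueError("trial subset must be non-empty")
    amp = np.abs(dec.coeffs[idx])
    times = dec.times
    if average:
        tensor = baseline_correct(amp.mean(axis=0), times, baseline)
        return FeatureSample(
            kind="tf_power",
            tensor=tensor,
            label=label,
            participant_id=participant_id,
            trial_ids=tuple(int(i) for i in idx),
        )
    corrected = baseline_correct(amp, times, baseline)
    return [
        FeatureSample(
            kind="tf_power",
            tensor=corrected[k],
            label=label,
            participant_id=participant_id,
            trial_ids=(int(i),),
        )
        for k, i in enumerate(idx)
    ]


def tf_phase(
    dec: SpectralDecomposition,
    trial: int,
    label: str = "frequent",
    participant_id: str = "",
    encoding: str = "angle",
) -> FeatureSample:
    """Single-trial wavelet phase (angle of -1 is +pi).

    The default feeds classifiers the raw angle in (-pi, pi]; deliberately
    not baseline-subtracted, since phase is an angle, not an additive
    offset.  ``encoding="cos_sin"`` instead stacks (cos, sin) along a
    leading axis, trading dimensionality for continuity at the +/-pi wrap.
    """
    ang = np.angle(dec.coeffs[int(trial)])
    if encoding == "cos_sin":
        tensor = np.stack([np.cos(ang), np.sin(ang)])
    elif encoding == "angle":
        tensor = ang
    else:
        raise ValueError(f"unknown phase encoding {encoding!r}")
    return FeatureSample(
        kind="tf_phase",
        tensor=tensor,
        label=label,
        participant_id=participant_id,
        trial_ids=(int(trial),),
    )


def phase_bin_index(phases: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Map phases in [-pi, pi] to half-open bins ``(-pi + (i-1)w, -pi + i*w]``.

    Returns 0-based bin indices; a phase of exactly -pi lands in bin 0.
    """
    width = 2.0 * np.pi / n_bins
    idx = np.ceil((np.asarray(phases) + np.pi) / width).astype(np.int64) - 1
    return np.clip(idx, 0, n_bins - 1)


def phase_sync_statistic(phases: np.ndarray, axis: int = 0, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Standard deviation of 10-bin phase-histogram probabilities.

    ``phases`` holds trial phases along ``axis``; every other axis is an
    independent (channel, frequency, time) point.  The result is
    ``sqrt(sum_i (p_i - 1/n_bins)^2 / n_bins)``: 0 for an exactly uniform
    histogram, 0.3 (for 10 bins) when all phases share one bin.
    """
    phases = np.moveaxis(np.asarray(phases), axis, 0)
    n = phases.shape[0]
    if n < 2:
        raise ValueError("phase synchronization needs at least 2 trials")
    idx = phase_bin_index(phases, n_bins)
    mu = 1.0 / n_bins
    acc = np.zeros(phases.shape[1:], dtype=np.float64)
    for i in range(n_bins):
        p_i = (idx == i).sum(axis=0) / n
        acc += (p_i - mu) ** 2
    return np.sqrt(acc / n_bins)


def phase_synchronization(
    dec: SpectralDecomposition,
    trial_subset,
    baseline: BaselineSpec = BaselineSpec(),
    label: str = "frequent",
    participant_id: str = "",
) -> FeatureSample:
    """Cross-trial phase-synchronization map, baselined per (channel, freq).

    At each (channel, frequency, time) point the phases of the selected
    trials are collected, histogrammed into 10 equal bins on (-pi, pi], and
    summarized by the standard deviation of the bin probabilities.  Values
    before baselining lie in [0, 0.3].
    """
    idx = np.asarray(trial_subset, dtype=int)
    if idx.size < 2:
        raise ValueError("phase synchronization needs at least 2 trials")
    phases = np.angle(dec.coeffs[idx])
    stat = phase_sync_statistic(phases, axis=0)
    tensor = baseline_correct(stat, dec.times, baseline)
    return FeatureSample(
        kind="phase_sync",
        tensor=tensor,
        label=label,
        participant_id=participant_id,
        trial_ids=tuple(int(i) for i in idx),
    )


def crop_tensor(tensor: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Restrict the trailing time axis to ``window`` (ms, inclusive)."""
    m = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not m.any():
        raise ValueError("crop window does not overlap the time axis")
    return tensor[..., m]
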