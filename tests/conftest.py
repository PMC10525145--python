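import numpy as np
import pytest

from erpfuse.data_model import EpochedRecording, time_axis
from erpfuse.features import WaveletSpec
from erpfuse.synthetic import SimulationConfig, SourceSpec

TEST_FREQS = (4.0, 6.0, 8.0, 10.0, 12.0, 14.0)


@pytest.fixture
def wavelet():
    return WaveletSpec(freqs=TEST_FREQS, srate=150.0)


@pytest.fixture
def sine_recording():
    """One noiseless 10 Hz unit-amplitude trial at the standard geometry."""
    t = time_axis((-1000.0, 2000.0), 150.0) / 1000.0
    sig = np.cos(2 * np.pi * 10.0 * t)
    return EpochedRecording(sig[None, None, :], 150.0, (-1000.0, 2000.0), ["rare"])


@pytest.fixture
def noisy_recording():
    """24 rare + 30 frequent trials of Gaussian noise, 3 channels."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((54, 3, 451)) * 5.0
    labels = ["rare"] * 24 + ["frequent"] * 30
    return EpochedRecording(data, 150.0, (-1000.0, 2000.0), labels,
                            participant_id="fixture")


def micro_cohort_config(scenario_sources, seed=0, n_participants=4):
    """Tiny cohort geometry for fast end-to-end tests (6 rare / 18 frequent)."""
    return SimulationConfig(
        n_participants=n_participants,
        n_rare=6,
        n_frequent=18,
        n_channels=4,
        sources=scenario_sources,
        seed=seed,
    )


def micro_transient_pair(n_channels=4, rare_amp=8.0, freq_amp=2.0):
    topo = tuple(np.linspace(1.0, 0.2, n_channels))
    common = dict(kind="transient", topography=topo, peak_latency_ms=300.0,
                  width_fwhm_ms=250.0)
    return (SourceSpec(amplitude_uv=rare_amp, **common),
            SourceSpec(amplitude_uv=freq_amp, **common))


def write_minimal_edf(path, signals, srate, ch_names, phys_range=200.0,
                      corrupt_ns=False):
    """Write a minimal one-record EDF file (test helper, synthetic data).

    ``signals``: (n_channels, n_samples) in microvolts, all channels one
    data record.  ``corrupt_ns=True`` mangles the signal-count field to
    produce an unparseable file.
    """
    signals = np.asarray(signals, dtype=float)
    ns, n_samp = signals.shape

    def fw(text, width):
        return f"{text:<{width}}"[:width].encode("ascii")

    header = b"".join([
        fw("0", 8), fw("X X X X", 80), fw("Startdate 01-JAN-2000 X X X", 80),
        fw("01.01.00", 8), fw("00.00.00", 8),
        fw(str(256 * (ns + 1)), 8), fw("EDF", 44), fw("1", 8),
        fw(f"{n_samp / srate:g}", 8),
        fw("XY" if corrupt_ns else str(ns), 4),
    ])
    per_field = [
        [fw(name, 16) for name in ch_names],
        [fw("AgAgCl electrode", 80)] * ns,
        [fw("uV", 8)] * ns,
        [fw(str(-phys_range), 8)] * ns,
        [fw(str(phys_range), 8)] * ns,
        [fw("-32768", 8)] * ns,
        [fw("32767", 8)] * ns,
        [fw("", 80)] * ns,
        [fw(str(n_samp), 8)] * ns,
        [fw("", 32)] * ns,
    ]
    body = b"".join(b"".join(fields) for fields in per_field)
    digital = np.round(signals / phys_range * 32767.0).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + body + digital.tobytes())
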