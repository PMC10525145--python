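"""Compute the three brain-response feature families for one participant.

Shows the average ERP, baselined wavelet amplitude ("TF power"), and the
10-bin cross-trial phase-synchronization statistic side by side on the
`phase_only` scenario, where only the phase feature should separate the
conditions.
"""

import numpy as np

from erpfuse import (
    BaselineSpec,
    WaveletSpec,
    compute_erp,
    cwt,
    make_scenario,
    phase_synchronization,
    simulate_participant,
    tf_power,
)

cfg = make_scenario("phase_only", n_participants=1, n_channels=8, seed=0)
rec = simulate_participant(cfg, 0)
wavelet = WaveletSpec(freqs=(4.0, 6.0, 8.0, 10.0, 12.0, 14.0), srate=rec.srate)
base = BaselineSpec()

dec = cwt(rec, wavelet)
rare = rec.trial_indices("rare")
freq = rec.trial_indices("frequent")[: len(rare)]

post = (rec.times > 700) & (rec.times < 1500)
j8 = list(wavelet.freqs).index(8.0)  # the reset oscillation's frequency

for label, ids in (("rare", rare), ("frequent", freq)):
    erp = compute_erp(rec, ids, base).tensor
    power = tf_power(dec, ids, base).tensor
    sync = phase_synchronization(dec, ids, base).tensor
    print(f"{label:9s} | ERP rms {np.sqrt((erp[:, post] ** 2).mean()):5.2f} uV"
          f" | TF power @8Hz {power[1, j8, post].mean():+6.2f} uV"
          f" | phase sync @8Hz {sync[1, j8, post].mean():+6.3f}")

print("\nThe bimodal phase reset leaves the ERP and the TF amplitude of the")
print("rare condition unchanged, but raises its post-stimulus cross-trial")
print("phase synchronization well above the frequent condition's.")
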