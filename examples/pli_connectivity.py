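"""Phase-lag-index connectivity from simulated coupled oscillators.

Two channels share a 10-Hz source with a rigid pi/2 phase lag; a third
carries only noise.  A zero-lag component is added identically to every
channel to mimic volume conduction -- PLI must ignore it, because
exactly-zero phase differences contribute sign(0) = 0.  (A zero-lag
component much stronger than the lagged source would *dilute* genuine
coupling by dragging every phase toward its own; immunity means common
signals create no spurious connectivity, not that they carry none away.)
"""

import numpy as np

from avconn import band_pli, global_connectivity, trim_epochs
from avconn.synthetic import EEGGenSpec, OscillatorSource, generate_eeg_dataset

lagged = OscillatorSource(freq_hz=10.0, channel_lags={0: 0.0, 1: np.pi / 2}, kappa=1e6)
spec = EEGGenSpec(
    n_channels=3,
    n_trials=60,
    sources=(lagged,),
    noise_sd=0.3,
    common_zero_lag_amplitude=0.4,  # volume-conduction stand-in
    seed=7,
)
(epochs,) = generate_eeg_dataset(spec, n_subjects=1)

tensor = trim_epochs(band_pli(epochs, "alpha"))
print("alpha-band PLI, mean over the -200...+600 ms analysis window:")
print(f"  coupled pair (0,1)   : {tensor.pli[0, 1].mean():.3f}   <- rigid pi/2 lag")
print(f"  uncoupled pair (0,2) : {tensor.pli[0, 2].mean():.3f}   <- noise only")
print(f"  uncoupled pair (1,2) : {tensor.pli[1, 2].mean():.3f}")

series = global_connectivity(tensor)
print(f"  global connectivity  : {series.mean_pli.mean():.3f}   (mean over all pairs)")

print(
    "\nThe coupled pair sits near 1 despite the common zero-lag signal, while\n"
    "the noise-only pairs stay near the 1/sqrt(N_trials) floor: PLI counts\n"
    "only consistently signed, nonzero phase lags."
)
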