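"""Localizing a group difference in global connectivity.

The elderly group receives theta-band coupling (von Mises kappa = 6)
between 100 and 300 ms; the younger group receives the same source with no
phase coupling (kappa = 0).  Background coupling in the other bands is
identical for both groups.  A pointwise one-tailed t-test on the global
connectivity time series should recover the injected window, and the
window-averaged PLI feeds a group comparison.
"""

import numpy as np

from avconn import band_pli, global_connectivity, pointwise_ttest, trim_epochs, window_mean
from avconn.groupstats import DEFAULT_WINDOWS_MS
from avconn.synthetic import EEGGenSpec, OscillatorSource, generate_eeg_dataset
from scipy import stats


def simulate_group(kappa_theta: float, seed: int, n_subjects: int = 8):
    theta = OscillatorSource(
        freq_hz=5.5, channel_lags={0: 0.0, 2: np.pi / 2, 4: 2.2},
        kappa=kappa_theta, onset_ms=100.0, offset_ms=300.0, amplitude=1.2,
    )
    background = [
        OscillatorSource(
            freq_hz=f, channel_lags={0: 0.0, 2: 1.2, 4: 2.4}, kappa=1e6, amplitude=2.0,
        )
        for f in (10.5, 22.0, 40.0)
    ]
    spec = EEGGenSpec(
        n_channels=6, n_trials=25, sources=(theta, *background), noise_sd=1.0, seed=seed,
    )
    return generate_eeg_dataset(spec, n_subjects)


elderly = simulate_group(kappa_theta=6.0, seed=1)
younger = simulate_group(kappa_theta=0.0, seed=2)

series = {}
for label, subjects in (("elderly", elderly), ("younger", younger)):
    rows = [
        global_connectivity(trim_epochs(band_pli(ep, "theta"))).mean_pli
        for ep in subjects
    ]
    series[label] = np.vstack(rows)
times = trim_epochs(band_pli(elderly[0], "theta")).times_ms

cmp_ = pointwise_ttest(series["elderly"], series["younger"], times, tail="greater")
print(f"theta-band significant window(s): {cmp_.windows_ms} ms")
print("  (coupling was injected at 100-300 ms; the ~±100 ms spread comes")
print("   from the 200-ms analysis window)")

window = DEFAULT_WINDOWS_MS["theta"]
m_e = window_mean(series["elderly"], times, window)
m_y = window_mean(series["younger"], times, window)
t, p = stats.ttest_ind(m_e, m_y, alternative="greater")
print(f"\nwindow-averaged PLI over {window} ms:")
print(f"  elderly {m_e.mean():.3f}  vs  younger {m_y.mean():.3f}  (t={t:.2f}, p={p:.2g})")
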