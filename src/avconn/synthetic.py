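"""Ground-truth generators for reaction-time and EEG datasets.

Both generators emulate the structure the downstream analyses assume, with
every parameter recorded so that recovery can be tested:

* **Reaction times** -- ex-Gaussian unimodal distributions (Gaussian mu,
  sigma plus exponential tau), an additive slowing for the elderly group,
  and audio-visual responses produced by a race between fresh unimodal
  draws, optionally sped up by a proportional coactivation gain.  With
  ``coactivation_gain = 0`` the AV response is exactly ``min(A', V')``:
  pure statistical facilitation, which satisfies the race-model bound in
  expectation at every time bin.
* **EEG epochs** -- band-limited oscillatory sources with a uniform random
  phase per trial, trial-consistent cross-channel lags jittered by a von
  Mises distribution whose concentration ``kappa`` sets the coupling
  strength (0 = no coupling, >= 1e6 = rigid lag), additive white noise,
  and an optional zero-lag component added identically to every channel to
  mimic volume conduction.

All randomness flows from the single ``seed`` in each spec through
``numpy.random.SeedSequence`` spawning (one child stream per subject), so a
fixed seed yields bit-identical datasets regardless of how many subjects
are requested downstream of any given one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ANALYSIS_CHANNELS_28, EpochArray

__all__ = [
    "RTGenSpec",
    "OscillatorSource",
    "EEGGenSpec",
    "generate_rt_dataset",
    "generate_eeg_dataset",
]

GROUPS = ("elderly", "younger")
INTENSITIES = ("high", "low")
STIM_TYPES = ("A", "V", "AV")


@dataclass(frozen=True)
class RTGenSpec:
    """Parameters of the behavioral generator.

    Defaults describe a plausible go/no-go tool-recognition task: unimodal
    means around 450-500 ms with auditory slower than visual, a 100-150 ms
    exponential tail, an 80-ms additive slowing for the elderly group, and
    a 5% miss rate.  ``subject_sd`` adds a per-subject mean shift (drawn
    once per subject, applied to every modality) so that between-subject
    statistics have realistic variance; ``intensity_slowing`` is added to
    all modalities under the low-intensity label.
    """

    mu_a: float = 500.0
    sigma_a: float = 60.0
    tau_a: float = 120.0
    mu_v: float = 450.0
    sigma_v: float = 60.0
    tau_v: float = 120.0
    coactivation_gain: float = 0.0
    group_slowing: float = 80.0
    miss_rate: float = 0.05
    n_trials_per_type: int = 30
    subject_sd: float = 40.0
    intensity_slowing: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma_a", "sigma_v", "tau_a", "tau_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.coactivation_gain < 1:
            raise ValueError("coactivation_gain must lie in [0, 1)")
        if not 0 <= self.miss_rate < 1:
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.n_trials_per_type <= 0:
            raise ValueError("n_trials_per_type must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


def _exgauss(rng: np.random.Generator, n: int, mu: float, sigma: float, tau: float) -> np.ndarray:
    rt = rng.normal(mu, sigma, n) + rng.exponential(tau, n)
    return np.maximum(rt, 1.0)  # RTs are strictly positive


def generate_rt_dataset(
    spec: RTGenSpec,
    n_subjects_per_group: int,
    *,
    groups: Sequence[str] = GROUPS,
    intensities: Sequence[str] = INTENSITIES,
    n_nontarget_per_type: int = 8,
) -> pd.DataFrame:
    """Simulate a behavioral trial table.

    One row per trial with columns ``subject, group, intensity, stim_type,
    is_target, rt_ms, correct``.  Target trials: ``n_trials_per_type`` per
    (subject, intensity, stimulus type); AV reaction times are
    ``(1 - coactivation_gain) * min(A', V')`` over fresh unimodal draws.
    A fraction ``miss_rate`` of target trials is a miss (empty ``rt_ms``,
    ``correct`` False).  Nontarget trials carry no response and count as
    correct rejections.  The generating parameters are stored in
    ``DataFrame.attrs['ground_truth']``.
    """
    spec.validate()
    if n_subjects_per_group <= 0:
        raise ValueError("n_subjects_per_group must be positive")

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(groups) * n_subjects_per_group)
    rows: list[dict] = []
    nt = spec.n_trials_per_type

    for gi, group in enumerate(groups):
        slow_g = spec.group_slowing if group == "elderly" else 0.0
        for si in range(n_subjects_per_group):
            rng = np.random.default_rng(children[gi * n_subjects_per_group + si])
            subject = f"{group[0].upper()}{si + 1:02d}"
            subj_shift = rng.normal(0.0, spec.subject_sd) if spec.subject_sd else 0.0
            for intensity in intensities:
                slow = slow_g + subj_shift + (
                    spec.intensity_slowing if intensity == "low" else 0.0
                )
                draws = {
                    "A": _exgauss(rng, nt, spec.mu_a + slow, spec.sigma_a, spec.tau_a),
                    "V": _exgauss(rng, nt, spec.mu_v + slow, spec.sigma_v, spec.tau_v),
                    "AV": (1.0 - spec.coactivation_gain) * np.minimum(
                        _exgauss(rng, nt, spec.mu_a + slow, spec.sigma_a, spec.tau_a),
                        _exgauss(rng, nt, spec.mu_v + slow, spec.sigma_v, spec.tau_v),
                    ),
                }
                for stim_type in STIM_TYPES:
                    missed = rng.random(nt) < spec.miss_rate
                    for t in range(nt):
                        rows.append({
                            "subject": subject,
                            "group": group,
                            "intensity": intensity,
                            "stim_type": stim_type,
                            "is_target": True,
                            "rt_ms": np.nan if missed[t] else draws[stim_type][t],
                            "correct": not missed[t],
                        })
                    for _ in range(n_nontarget_per_type):
                        rows.append({
                            "subject": subject,
                            "group": group,
                            "intensity": intensity,
                            "stim_type": stim_type,
                            "is_target": False,
                            "rt_ms": np.nan,
                            "correct": True,
                        })

    table = pd.DataFrame(rows)
    table.attrs["ground_truth"] = {
        **asdict(spec),
        "n_subjects_per_group": n_subjects_per_group,
        "groups": list(groups),
        "intensities": list(intensities),
    }
    return table


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatorSource:
    """One band-limited oscillatory source.

    ``channel_lags`` maps channel index -> lag in radians; the first listed
    channel is the phase reference (uniform random phase per trial), and
    every other listed channel oscillates at the reference phase plus its
    lag plus von Mises jitter of concentration ``kappa``.  ``kappa = 0``
    gives uniform jitter (no coupling); ``kappa >= 1e6`` is treated as a
    rigid, jitter-free lag.  The source is active between ``onset_ms`` and
    ``offset_ms`` with 20-ms cosine ramps.
    """

    freq_hz: float
    band: str = ""
    channel_lags: dict[int, float] = field(default_factory=dict)
    kappa: float = 1e6
    onset_ms: float = -800.0
    offset_ms: float = 2000.0
    amplitude: float = 1.0

    def validate(self) -> None:
        if not 1.0 <= self.freq_hz <= 50.0:
            raise ValueError("source frequency must lie within 1-50 Hz (analysis band)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not self.channel_lags:
            raise ValueError("source must involve at least one channel")
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset_ms must exceed onset_ms")


_RIGID_KAPPA = 1e6
_RAMP_MS = 20.0


@dataclass(frozen=True)
class EEGGenSpec:
    """Parameters of the EEG epoch generator (28 channels, 250 Hz,
    -800...+2000 ms => 700 samples, at the defaults)."""

    n_channels: int = 28
    fs: float = 250.0
    epoch_span_ms: tuple[float, float] = (-800.0, 2000.0)
    n_trials: int = 40
    sources: tuple[OscillatorSource, ...] = ()
    noise_sd: float = 1.0
    common_zero_lag_amplitude: float = 0.0
    common_zero_lag_freq_hz: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels <= 0 or self.n_trials <= 0:
            raise ValueError("n_channels and n_trials must be positive")
        t0, t1 = self.epoch_span_ms
        if t1 <= t0:
            raise ValueError("epoch span must be increasing")
        for src in self.sources:
            src.validate()
            for ch in src.channel_lags:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"source references channel {ch} out of range")
        if self.noise_sd < 0 or self.common_zero_lag_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_span_ms
        return int(round((t1 - t0) * self.fs / 1000.0))


def _envelope(times_ms: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """Rectangular activation with raised-cosine ramps, to keep source
    on/offsets from splattering broadband energy."""
    env = np.zeros_like(times_ms)
    core = (times_ms >= onset) & (times_ms <= offset)
    env[core] = 1.0
    for edge, rising in ((onset, True), (offset, False)):
        ramp = (times_ms >= edge - _RAMP_MS) & (times_ms < edge) if rising else (
            (times_ms > edge) & (times_ms <= edge + _RAMP_MS)
        )
        x = (times_ms[ramp] - edge) / _RAMP_MS
        env[ramp] = 0.5 * (1.0 + np.cos(np.pi * x))
    return env


def _wrap(a: np.ndarray | float) -> np.ndarray:
    return np.angle(np.exp(1j * np.asarray(a)))


def generate_eeg_dataset(
    spec: EEGGenSpec,
    n_subjects: int,
    *,
    condition: tuple | None = None,
    channel_names: Sequence[str] | None = None,
) -> list[EpochArray]:
    """Simulate one :class:`~avconn.connectivity.EpochArray` per subject.

    Each trial superimposes the specified oscillatory sources (per-trial
    uniform phase, von Mises-jittered cross-channel lags), i.i.d. Gaussian
    noise per sample, and the zero-lag common component added identically
    to all channels.  All lags are wrapped to (-pi, pi].
    """
    spec.validate()
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if channel_names is None:
        if spec.n_channels == len(ANALYSIS_CHANNELS_28):
            channel_names = ANALYSIS_CHANNELS_28
        else:
            channel_names = tuple(f"ch{i:02d}" for i in range(spec.n_channels))

    t0, _ = spec.epoch_span_ms
    n_samp = spec.n_samples
    times_ms = t0 + np.arange(n_samp) * 1000.0 / spec.fs
    times_s = times_ms / 1000.0

    subjects = []
    for child in np.random.SeedSequence(spec.seed).spawn(n_subjects):
        rng = np.random.default_rng(child)
        data = rng.normal(0.0, spec.noise_sd, (spec.n_channels, n_samp, spec.n_trials)) \
            if spec.noise_sd > 0 else np.zeros((spec.n_channels, n_samp, spec.n_trials))

        for src in spec.sources:
            env = _envelope(times_ms, src.onset_ms, src.offset_ms)
            carrier = 2.0 * np.pi * src.freq_hz * times_s
            theta = rng.uniform(-np.pi, np.pi, spec.n_trials)
            for rank, (ch, lag) in enumerate(src.channel_lags.items()):
                if rank == 0 or src.kappa >= _RIGID_KAPPA:
                    jitter = np.zeros(spec.n_trials)
                elif src.kappa == 0:
                    jitter = rng.uniform(-np.pi, np.pi, spec.n_trials)
                else:
                    jitter = rng.vonmises(0.0, src.kappa, spec.n_trials)
                ph = _wrap(theta + lag + jitter)  # (trials,)
                data[ch] += src.amplitude * env[:, None] * np.cos(carrier[:, None] + ph[None, :])

        if spec.common_zero_lag_amplitude > 0:
            theta_c = rng.uniform(-np.pi, np.pi, spec.n_trials)
            common = spec.common_zero_lag_amplitude * np.cos(
                2.0 * np.pi * spec.common_zero_lag_freq_hz * times_s[:, None] + theta_c[None, :]
            )
            data += common[None, :, :]

        subjects.append(EpochArray(
            data=data,
            fs=spec.fs,
            t0_ms=t0,
            channel_names=tuple(channel_names),
            condition=condition,
        ))
    return subjects
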