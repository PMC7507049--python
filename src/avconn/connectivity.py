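"""Phase extraction and phase-lag-index (PLI) connectivity from EEG epochs.

The connectivity chain is::

    preprocess -> wft_phase -> pli / pli_matrix -> band_average
               -> trim_epochs -> global_connectivity

or, streaming frequency-by-frequency for full-size data, :func:`band_pli`,
which fuses the phase, PLI and band-average steps without materializing the
channels x samples x freqs x trials phase tensor.

Conventions
-----------
* Epochs are channels x samples x trials at ``fs`` Hz, first sample at
  ``t0_ms`` relative to stimulus onset (default -800 ms, 700 samples at
  250 Hz spanning -800...+2000 ms).
* Instantaneous phase comes from a sliding 200-ms Hamming-windowed Fourier
  transform evaluated at integer frequencies 1...50 Hz.  The window is a
  direct complex inner product at each requested frequency rather than an
  FFT bin: a 50-sample window has 5-Hz FFT resolution, while the direct
  product honors 1-Hz steps.
* PLI between channels i and j is ``| mean over trials of sign(dphi) |``
  with ``dphi`` the phase difference wrapped to (-pi, pi] and
  ``sign(0) = 0``, so exactly zero-lag (volume-conducted) components
  contribute nothing.  Values lie in [0, 1].
* The first 150 and last 350 samples of a 700-sample epoch are trimmed
  before aggregation, leaving 200 samples covering -200...+600 ms, which
  keeps every analyzed sample more than a window half-width away from the
  epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "BANDS",
    "ANALYSIS_CHANNELS_28",
    "RAW_CHANNELS_32",
    "EpochArray",
    "SpectralPhase",
    "PLITensor",
    "ConnectivityTimeSeries",
    "preprocess",
    "wft_coefficients",
    "wft_phase",
    "pli",
    "pli_matrix",
    "band_average",
    "band_pli",
    "trim_epochs",
    "global_connectivity",
]

#: Canonical frequency bands (Hz, inclusive integer ranges).
BANDS: dict[str, tuple[int, int]] = {
    "theta": (4, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "gamma": (31, 50),
}

#: Scalp montage retained for connectivity analysis (10/20 system, 28
#: channels after dropping the two EOG channels and the two mastoids).
ANALYSIS_CHANNELS_28: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Full 32-channel acquisition montage (analysis channels + mastoid
#: references + EOG).
RAW_CHANNELS_32: tuple[str, ...] = ANALYSIS_CHANNELS_28 + ("TP9", "TP10", "HEOG", "VEOG")

_FREQ_MIN, _FREQ_MAX = 1.0, 50.0
_TRIM_HEAD = 150   # samples removed at epoch start (600 ms at 250 Hz)
_TRIM_TAIL = 350   # samples removed at epoch end (1400 ms at 250 Hz)
_FULL_EPOCH = 700  # samples in an untrimmed epoch


@dataclass
class EpochArray:
    """Stimulus-locked multichannel epochs.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples, n_trials)``.
    fs
        Sampling rate in Hz.
    t0_ms
        Time of the first sample relative to stimulus onset, in ms.
    channel_names
        One label per channel.
    condition
        Optional ``(group, intensity, stim_type)`` labels.
    """

    data: np.ndarray
    fs: float = 250.0
    t0_ms: float = -800.0
    channel_names: tuple[str, ...] = ANALYSIS_CHANNELS_28
    condition: tuple | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class SpectralPhase:
    """Instantaneous phase per (channel, sample, frequency, trial), radians
    wrapped to (-pi, pi]."""

    phase: np.ndarray  # (channels, samples, freqs, trials)
    freqs: np.ndarray  # Hz
    fs: float
    times_ms: np.ndarray
    window_ms: float = 200.0
    window_shape: str = "hamming"

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]


@dataclass
class PLITensor:
    """Channel x channel x time PLI adjacency series for one band (or one
    frequency).  Symmetric in the channel axes with a zero diagonal."""

    pli: np.ndarray  # (channels, channels, samples)
    band: str
    band_hz: tuple[float, float]
    times_ms: np.ndarray
    channel_names: tuple[str, ...]
    trimmed: bool = False

    @property
    def n_channels(self) -> int:
        return self.pli.shape[0]


@dataclass
class ConnectivityTimeSeries:
    """Global functional connectivity: mean PLI over all unordered
    off-diagonal channel pairs, as a time series."""

    mean_pli: np.ndarray
    times_ms: np.ndarray
    band: str = ""


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    raw: EpochArray,
    *,
    eog: Sequence[str] = ("HEOG", "VEOG"),
    mastoids: Sequence[str] | None = ("TP9", "TP10"),
    band: tuple[float, float] = (1.0, 50.0),
    baseline: bool = True,
    ica_hook: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EpochArray:
    """Drop EOG channels, re-reference to the bilateral mastoids, band-pass
    filter and baseline-correct.

    Steps, in order: (1) EOG channels named in ``eog`` are removed;
    (2) the mean of the two mastoid channels is subtracted from every
    remaining channel and the mastoids are dropped (skipped when
    ``mastoids`` is None, for data that is already referenced);
    (3) zero-phase (forward-backward) Butterworth band-pass ``band`` Hz --
    zero-phase because phase is the analyte downstream; (4) the optional
    artifact-removal hook is applied (identity when None); (5) the
    prestimulus mean is subtracted per channel and trial.

    Raises
    ------
    KeyError
        If ``mastoids`` is requested but a mastoid label is missing.
    """
    names = list(raw.channel_names)
    data = raw.data

    keep = [i for i, n in enumerate(names) if n not in set(eog)]
    data = data[keep]
    names = [names[i] for i in keep]

    if mastoids is not None:
        try:
            m_idx = [names.index(m) for m in mastoids]
        except ValueError as exc:
            raise KeyError(f"mastoid channel missing from montage: {exc}") from exc
        ref = data[m_idx].mean(axis=0, keepdims=True)
        data = data - ref
        keep = [i for i in range(len(names)) if i not in m_idx]
        data = data[keep]
        names = [names[i] for i in keep]

    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=raw.fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)

    if ica_hook is not None:
        data = ica_hook(data)

    if baseline:
        times = raw.t0_ms + np.arange(data.shape[1]) * 1000.0 / raw.fs
        pre = times < 0
        if pre.any():
            data = data - data[:, pre, :].mean(axis=1, keepdims=True)

    return EpochArray(
        data=np.ascontiguousarray(data),
        fs=raw.fs,
        t0_ms=raw.t0_ms,
        channel_names=tuple(names),
        condition=raw.condition,
    )


# ---------------------------------------------------------------------------
# Windowed Fourier phase
# ---------------------------------------------------------------------------

def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if (freqs < _FREQ_MIN).any() or (freqs > _FREQ_MAX).any():
        raise ValueError(f"frequencies must lie within [{_FREQ_MIN:g}, {_FREQ_MAX:g}] Hz")
    return freqs


def _wft_kernel(freq: float, fs: float, window: np.ndarray) -> np.ndarray:
    # Convolution kernel g such that (x * g)[t] equals the windowed inner
    # product sum_k x[t + k - c] w[k] exp(-i 2 pi f (k - c) / fs) with the
    # window centered at c = W // 2.  Demodulating relative to the window
    # center makes the coefficient's argument track the signal phase at
    # sample t itself.
    w = len(window)
    c = w // 2
    k = np.arange(w)
    corr = window * np.exp(-2j * np.pi * freq * (k - c) / fs)
    return corr[::-1]  # correlation -> convolution


def wft_coefficients(
    data: np.ndarray,
    fs: float,
    freqs: Iterable[float],
    *,
    window_ms: float = 200.0,
) -> np.ndarray:
    """Complex sliding-window Fourier coefficients.

    Parameters
    ----------
    data
        ``(..., n_samples)`` real signals; the transform runs along the
        last axis.
    fs
        Sampling rate in Hz.
    freqs
        Frequencies in Hz; each must lie in [1, 50].
    window_ms
        Hamming window length in ms (50 samples at the 250-Hz default).

    Returns
    -------
    ndarray
        Complex array ``(..., n_samples, n_freqs)``.  Samples closer than
        half a window to the epoch edge use the zero-padded window portion;
        downstream trimming discards them.
    """
    freqs = _check_freqs(np.asarray(list(freqs), dtype=float))
    w = int(round(window_ms * fs / 1000.0))
    if data.shape[-1] < w:
        raise ValueError(f"need >= {w} samples for a {window_ms:g}-ms window")
    window = np.hamming(w)
    out = np.empty(data.shape + (len(freqs),), dtype=complex)
    for fi, f in enumerate(freqs):
        kern = _wft_kernel(f, fs, window)
        shape = [1] * (data.ndim - 1) + [w]
        out[..., fi] = signal.oaconvolve(data, kern.reshape(shape), mode="same", axes=-1)
    return out


def wft_phase(
    epochs: EpochArray,
    freqs: Iterable[float] | None = None,
    *,
    window_ms: float = 200.0,
) -> SpectralPhase:
    """Instantaneous phase via the sliding Hamming-windowed Fourier
    transform at 1-Hz steps (default 1...50 Hz).

    The returned phases are wrapped to (-pi, pi].  For full-size data
    prefer :func:`band_pli`, which streams one frequency at a time.
    """
    if freqs is None:
        freqs = np.arange(1, 51, dtype=float)
    freqs = _check_freqs(np.asarray(list(freqs), dtype=float))
    # data is (ch, samples, trials); transform along samples
    coeffs = wft_coefficients(
        np.moveaxis(epochs.data, 1, -1), epochs.fs, freqs, window_ms=window_ms
    )  # (ch, trials, samples, freqs)
    phase = np.angle(np.moveaxis(coeffs, 1, -1))  # (ch, samples, freqs, trials)
    return SpectralPhase(
        phase=phase,
        freqs=freqs,
        fs=epochs.fs,
        times_ms=epochs.times_ms,
        window_ms=window_ms,
    )


# ---------------------------------------------------------------------------
# PLI
# ---------------------------------------------------------------------------

def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * angles))


def _sign_mean(dphi: np.ndarray, axis: int = -1) -> np.ndarray:
    """|mean over trials of sign(wrapped phase difference)|, sign(0) = 0."""
    return np.abs(np.mean(np.sign(_wrap(dphi)), axis=axis))


def pli(phase: SpectralPhase, i: int, j: int) -> np.ndarray:
    """PLI between channels ``i`` and ``j`` per (sample, frequency).

    ``PLI = | (1/N) sum_n sign(dphi_n) |`` with ``dphi_n = phi_i - phi_j``
    wrapped to (-pi, pi] on trial n.  ``i == j`` returns zeros (the
    diagonal is excluded from every aggregate).
    """
    if i == j:
        return np.zeros(phase.phase.shape[1:3])
    return _sign_mean(phase.phase[i] - phase.phase[j], axis=-1)


def pli_matrix(phase: SpectralPhase) -> np.ndarray:
    """Full symmetric PLI array ``(channels, channels, samples, freqs)``
    with a zero diagonal.  Intended for modest channel counts; the band
    pipeline uses :func:`band_pli` instead."""
    n = phase.n_channels
    out = np.zeros((n, n) + phase.phase.shape[1:3])
    for i in range(n):
        for j in range(i + 1, n):
            v = _sign_mean(phase.phase[i] - phase.phase[j], axis=-1)
            out[i, j] = v
            out[j, i] = v
    return out


def band_average(pli_tf: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Mean PLI over the band's frequencies, inclusive range, along the last
    axis of ``pli_tf`` (which must match ``freqs``)."""
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequencies inside band {band}")
    return np.asarray(pli_tf)[..., sel].mean(axis=-1)


def band_pli(
    epochs: EpochArray,
    band: str | tuple[float, float],
    *,
    window_ms: float = 200.0,
) -> PLITensor:
    """Band-averaged PLI adjacency time series, streamed per frequency.

    For each integer frequency in the band (inclusive), extract phases with
    the windowed Fourier transform, form the trial-wise sign of the wrapped
    pairwise phase difference, average over trials, take the magnitude, and
    finally average the per-frequency PLI over the band.  Equivalent to
    ``band_average`` over ``pli_matrix(wft_phase(...))`` but bounded in
    memory, since the (channels, samples, freqs, trials) phase tensor is
    never materialized.
    """
    if isinstance(band, str):
        name, (lo, hi) = band, BANDS[band]
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    freqs = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1, dtype=float)
    _check_freqs(freqs)

    n = epochs.n_channels
    iu, ju = np.triu_indices(n, k=1)
    acc = np.zeros((len(iu), epochs.n_samples))
    data = np.moveaxis(epochs.data, 1, -1)  # (ch, trials, samples)
    for f in freqs:
        coef = wft_coefficients(data, epochs.fs, [f], window_ms=window_ms)[..., 0]
        phi = np.angle(coef)  # (ch, trials, samples)
        dphi = phi[iu] - phi[ju]  # (pairs, trials, samples)
        acc += np.abs(np.mean(np.sign(_wrap(dphi)), axis=1))
    acc /= len(freqs)

    mat = np.zeros((n, n, epochs.n_samples))
    mat[iu, ju] = acc
    mat[ju, iu] = acc
    return PLITensor(
        pli=mat,
        band=name,
        band_hz=(float(lo), float(hi)),
        times_ms=epochs.times_ms,
        channel_names=epochs.channel_names,
        trimmed=False,
    )


# ---------------------------------------------------------------------------
# Trimming and aggregation
# ---------------------------------------------------------------------------

def trim_epochs(tensor: PLITensor) -> PLITensor:
    """Cut the 150 leading and 350 trailing samples of a 700-sample epoch
    axis, leaving 200 samples that cover -200...+600 ms.

    The removed margins (600 ms leading, 1400 ms trailing) exceed the
    analysis window half-width, so every retained sample is free of
    zero-padding edge effects.
    """
    if tensor.trimmed:
        raise ValueError("tensor is already trimmed")
    if tensor.pli.shape[-1] != _FULL_EPOCH:
        raise ValueError(
            f"expected an untrimmed {_FULL_EPOCH}-sample axis, got {tensor.pli.shape[-1]}"
        )
    sl = slice(_TRIM_HEAD, _FULL_EPOCH - _TRIM_TAIL)
    return replace(
        tensor,
        pli=tensor.pli[..., sl],
        times_ms=tensor.times_ms[sl],
        trimmed=True,
    )


def global_connectivity(tensor: PLITensor) -> ConnectivityTimeSeries:
    """Mean network weight: average PLI over all unordered off-diagonal
    channel pairs at each time point (378 pairs for 28 channels)."""
    n = tensor.n_channels
    iu, ju = np.triu_indices(n, k=1)
    return ConnectivityTimeSeries(
        mean_pli=tensor.pli[iu, ju].mean(axis=0),
        times_ms=tensor.times_ms,
        band=tensor.band,
    )
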