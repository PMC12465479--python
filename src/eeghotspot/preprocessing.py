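"""The five-level signal-processing ladder producing CNN model inputs.

Levels, applied cumulatively to a recording (all levels are downsampled to a
common 200 Hz so tensor widths are comparable):

1. raw channel x time epochs
2. + common average reference (CAR)
3. + zero-phase 3rd-order Butterworth band-pass, 1-55 Hz
4. + ICA artifact removal (extended Infomax; blink-correlation and kurtosis
   auto-flagging)
5. + gamma-band (30-50 Hz) power spectral density at 1 Hz resolution
   (magnitude-squared FFT), channel x 21 bins
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io import EEGRecording
from .montage import ChannelSet

logger = logging.getLogger(__name__)

TARGET_FS = 200.0

#: epoch window (s, relative to the event) per cohort
EPOCH_WINDOWS = {"healthy": (-0.5, 0.5), "stroke": (-0.5, 1.0)}
EPOCH_EVENT = {"healthy": "keypress", "stroke": "cue"}

GAMMA_BAND = (30.0, 50.0)


@dataclass
class EpochArray:
    """Trials x channels x samples, cut around events."""

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    labels: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at {self.fs} Hz implies {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("need at least one trial")

    @property
    def n_trials(self):
        return self.data.shape[0]


@dataclass
class ModelInput:
    """A trials x channels x width tensor ready for the CNN."""

    level: int
    tensor: np.ndarray
    width_kind: str  # "time" | "psd"
    labels: tuple[str, ...]
    freq_bins: tuple[float, ...] | None = None
    stages: tuple[str, ...] = ()

    def __post_init__(self):
        if self.level not in range(1, 6):
            raise ValueError("level must be 1..5")
        if self.level <= 4 and self.width_kind != "time":
            raise ValueError("levels 1-4 are time-domain inputs")
        if self.level == 5 and (self.width_kind != "psd" or self.freq_bins is None):
            raise ValueError("level 5 must carry PSD bins")

    @property
    def shape(self):
        return self.tensor.shape


# ---------------------------------------------------------------------------
# stages


def downsample(rec: EEGRecording, target_fs: float = TARGET_FS) -> EEGRecording:
    """Polyphase anti-aliased resampling; event indices are rescaled."""
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signal, up, down, axis=1)
    ratio = target_fs / rec.fs
    events = [(int(round(s * ratio)), t) for s, t in rec.events]
    events = [(min(s, out.shape[1] - 1), t) for s, t in events]
    return rec.copy_with(signal=out, fs=float(target_fs), events=tuple(events))


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the across-channel mean potential at every sample."""
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    return rec.copy_with(signal=rec.signal - rec.signal.mean(axis=0, keepdims=True))


def bandpass(
    rec: EEGRecording, low: float = 1.0, high: float = 55.0, order: int = 3
) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    # pad by ~6 time-constants of the low cutoff so edge transients settle
    padlen = min(rec.n_samples - 1, int(round(6 * rec.fs / low)))
    return rec.copy_with(
        signal=sps.sosfiltfilt(sos, rec.signal, axis=1, padlen=padlen)
    )


@dataclass
class ICAReport:
    n_components: int
    flagged: tuple[int, ...]
    reasons: dict[int, str] = field(default_factory=dict)
    blink_proxy_channels: tuple[str, ...] = ()


def remove_artifact_components(
    rec: EEGRecording,
    corr_threshold: float = 0.7,
    kurt_threshold: float = 8.0,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[EEGRecording, ICAReport]:
    """Extended-Infomax ICA with automatic artifact flagging.

    Components are flagged when the absolute correlation of their time course
    with a frontal blink proxy (mean of Fp1/Fp2, or the two most anterior
    channels) exceeds ``corr_threshold``, or when their excess kurtosis
    exceeds ``kurt_threshold``.  Flagged components are zeroed before
    reconstruction.
    """
    from mne.preprocessing import infomax

    x = rec.signal
    n_ch, n_samp = x.shape
    if n_samp <= n_ch:
        raise ValueError("ICA needs more samples than channels")
    if n_samp < 20 * n_ch:
        warnings.warn(
            "fewer than 20 samples per channel; ICA may be unstable", stacklevel=2
        )

    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean

    # PCA whitening; rank-deficient data (e.g. after CAR) keep n-1 components
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max() * max(n_ch, n_samp) * np.finfo(float).eps * 1e3
    rank = int(np.sum(s > tol))
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    whitened = vt * np.sqrt(n_samp)  # rank x samples, unit variance

    unmixing = infomax(
        whitened.T, extended=True, max_iter=max_iter, rng=np.random.default_rng(seed),
        verbose="error",
    )
    sources = unmixing @ whitened  # rank x samples
    if not np.all(np.isfinite(sources)):
        raise RuntimeError(
            "ICA did not converge to finite sources; provide more data or "
            "reduce the number of components"
        )

    # blink proxy: frontopolar channels; montages list anterior rows first,
    # so fall back to the first two channels when Fp1/Fp2 are absent
    frontal = [lab for lab in ("Fp1", "Fp2") if lab in rec.labels]
    if not frontal:
        frontal = list(rec.labels[:2])
    idx = [rec.labels.index(lab) for lab in frontal]
    proxy = x[idx].mean(axis=0)
    proxy = proxy - proxy.mean()

    flagged, reasons = [], {}
    proxy_norm = np.linalg.norm(proxy)
    for k in range(rank):
        src = sources[k] - sources[k].mean()
        denom = np.linalg.norm(src) * proxy_norm
        r = float(src @ proxy / denom) if denom > 0 else 0.0
        kurt = float(stats.kurtosis(sources[k], fisher=True))
        if abs(r) > corr_threshold:
            flagged.append(k)
            reasons[k] = f"blink correlation |r|={abs(r):.2f}"
        elif kurt > kurt_threshold:
            flagged.append(k)
            reasons[k] = f"kurtosis {kurt:.1f}"

    keep = sources.copy()
    keep[flagged] = 0.0
    # invert: whitened = inv(unmixing) @ sources; xc = (u * s / sqrt(n)) @ whitened
    whitened_clean = np.linalg.solve(unmixing, keep)
    back = (u * s) @ (whitened_clean / np.sqrt(n_samp))
    cleaned = back + mean

    report = ICAReport(
        n_components=rank,
        flagged=tuple(flagged),
        reasons=reasons,
        blink_proxy_channels=tuple(frontal),
    )
    logger.info("ICA flagged %d/%d components: %s", len(flagged), rank, reasons)
    return rec.copy_with(signal=cleaned), report


def epoch(rec: EEGRecording, cohort: str | None = None) -> EpochArray:
    """Cut trials around events: (-0.5, 0.5) s for key presses (healthy),
    (-0.5, 1.0) s for cues (stroke).  Out-of-bounds trials are dropped."""
    cohort = cohort or rec.cohort
    if cohort not in EPOCH_WINDOWS:
        raise ValueError(f"unknown cohort {cohort!r}")
    t0, t1 = EPOCH_WINDOWS[cohort]
    ev_type = EPOCH_EVENT[cohort]
    n_samp = int(round((t1 - t0) * rec.fs))
    offset = int(round(t0 * rec.fs))
    trials = []
    for s in rec.event_samples(ev_type):
        start = s + offset
        if start < 0 or start + n_samp > rec.n_samples:
            logger.warning(
                "dropping trial at sample %d: window outside recording", s
            )
            continue
        trials.append(rec.signal[:, start:start + n_samp])
    if not trials:
        raise ValueError("no usable trials: all event windows fall outside the recording")
    return EpochArray(
        data=np.stack(trials), fs=rec.fs, window=(t0, t1), labels=rec.labels
    )


def compute_psd(
    ep: EpochArray,
    band: tuple[float, float] = GAMMA_BAND,
    resolution: float = 1.0,
) -> ModelInput:
    """Magnitude-squared FFT PSD at integer-Hz bins within ``band``.

    Epochs are zero-padded to the next multiple of fs/resolution samples so
    that every multiple of ``resolution`` Hz is an exact FFT bin.
    """
    if band[1] > ep.fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist {ep.fs / 2} Hz")
    n0 = ep.data.shape[2]
    if n0 / ep.fs < 1.0 / resolution:
        raise ValueError(
            f"epoch of {n0 / ep.fs:.3f} s cannot support {resolution} Hz resolution"
        )
    block = int(round(ep.fs / resolution))
    n_fft = block * int(np.ceil(n0 / block))
    spec = np.fft.rfft(ep.data, n=n_fft, axis=2)
    psd = np.abs(spec) ** 2 / n_fft
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / ep.fs)
    wanted = np.arange(band[0], band[1] + 0.5 * resolution, resolution)
    idx = np.round(wanted * n_fft / ep.fs).astype(int)
    if not np.allclose(freqs[idx], wanted):
        raise RuntimeError("frequency grid misaligned")  # guarded by padding
    return ModelInput(
        level=5,
        tensor=psd[:, :, idx],
        width_kind="psd",
        labels=ep.labels,
        freq_bins=tuple(float(f) for f in wanted),
    )


# ---------------------------------------------------------------------------
# the ladder


def build_input(
    rec: EEGRecording,
    level: int,
    channel_set: ChannelSet | None = None,
    cohort: str | None = None,
    ica_seed: int = 0,
) -> ModelInput:
    """Apply the cumulative ladder up to ``level`` and epoch the result.

    Channel-set restriction is applied after epoching, so CAR and ICA always
    operate on the full montage.
    """
    if level not in range(1, 6):
        raise ValueError("level must be in 1..5")
    cohort = cohort or rec.cohort
    stages = []
    r = downsample(rec)
    stages.append(f"downsample->{int(r.fs)}Hz")
    if level >= 2:
        r = common_average_reference(r)
        stages.append("CAR")
    if level >= 3:
        r = bandpass(r)
        stages.append("bandpass(1-55Hz,order3,zero-phase)")
    if level >= 4:
        r, report = remove_artifact_components(r, seed=ica_seed)
        stages.append(f"ICA(removed={list(report.flagged)})")
    ep = epoch(r, cohort)
    stages.append(f"epoch{EPOCH_WINDOWS[cohort]}")

    if channel_set is not None:
        idx = [ep.labels.index(lab) for lab in channel_set.labels]
        ep = EpochArray(
            data=ep.data[:, idx, :], fs=ep.fs, window=ep.window,
            labels=channel_set.labels,
        )
        stages.append(f"channels({channel_set.set_id},n={len(idx)})")

    if level == 5:
        mi = compute_psd(ep)
        stages.append("PSD(30-50Hz,1Hz)")
        return ModelInput(
            level=5, tensor=mi.tensor, width_kind="psd", labels=mi.labels,
            freq_bins=mi.freq_bins, stages=tuple(stages),
        )
    return ModelInput(
        level=level, tensor=ep.data, width_kind="time", labels=ep.labels,
        stages=tuple(stages),
    )
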