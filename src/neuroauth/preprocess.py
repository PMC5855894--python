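"""EEG and EOG preprocessing.

EEG path: Chebyshev low-pass (40 Hz passband / 49 Hz stopband), downsampling
2400 -> 600 Hz by averaging four consecutive samples, epoching to -200..1000
ms around stimulus onset with the -200..0 ms interval as baseline.

EOG path: Chebyshev band-pass (1-40 Hz), the same averaging downsampler,
threshold-based blink detection (positive peak > 100 uV followed by a
negative peak < -50 uV, boundaries found by scanning to the first zero
crossing), and global normalization of the segmented blinks to [-1, 1].

Conventions: indices are 0-based, windows half-open [start, end) except the
blink segment which stores inclusive ``end_idx``; time is in ms relative to
stimulus onset; amplitudes in microvolts until blink normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger("neuroauth")

# Filter design defaults (Chebyshev type I, forward-backward for zero phase).
PASSBAND_RIPPLE_DB = 0.5
STOPBAND_ATTEN_DB = 40.0
EEG_PASSBAND_HZ = 40.0
EEG_STOPBAND_HZ = 49.0
BLINK_BAND_HZ = (1.0, 40.0)
BLINK_STOP_HZ = (0.25, 49.0)
BLINK_POS_THRESH_UV = 100.0
BLINK_NEG_THRESH_UV = -50.0


@dataclass
class MultichannelRecording:
    """A channels x time voltage matrix in microvolts."""

    samples: np.ndarray
    rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel label count must equal row count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class SingleChannelRecording:
    """One-channel trace (the frontal Fp1 electrode for blinks)."""

    samples: np.ndarray
    rate: float
    label: str = "Fp1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class EventList:
    """Stimulus onsets (sample indices at the recording's current rate)."""

    onsets: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if len(self.labels) != self.onsets.size:
            raise ValueError("labels and onsets must have equal length")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.labels) - {"self", "nonself"}
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def downsampled(self, factor: int) -> "EventList":
        return EventList(onsets=self.onsets // factor, labels=list(self.labels))

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class EpochSet:
    """Baseline-corrected epochs: trials x channels x samples.

    The window is -200..+1000 ms around onset; at 600 Hz that is 720 samples
    (120 baseline + 600 post-stimulus). ``labels`` holds "self"/"nonself"
    per trial; N1/N2 are the class trial counts.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    baseline_samples: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def N1(self) -> int:
        return sum(1 for l in self.labels if l == "self")

    @property
    def N2(self) -> int:
        return sum(1 for l in self.labels if l == "nonself")

    @property
    def post_stimulus(self) -> np.ndarray:
        """Post-onset part of the epochs (the n = 1..600 sample points)."""
        return self.data[:, :, self.baseline_samples:]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        labels = [l for l, m in zip(self.labels, mask) if m]
        return EpochSet(self.data[mask], self.rate, labels,
                        self.baseline_samples)


@dataclass
class BlinkWaveform:
    """One segmented blink: a positive pulse followed by a negative pulse.

    ``samples`` are normalized (dimensionless) after :func:`normalize_blinks`;
    raw peak voltages are kept for traceability. Indices refer to the source
    recording; ``end_idx`` is inclusive.
    """

    samples: np.ndarray
    rate: float
    start_idx: int
    end_idx: int
    pos_peak_idx: int
    neg_peak_idx: int
    raw_pos_peak: float
    raw_neg_peak: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        ok = (self.start_idx <= self.pos_peak_idx < self.neg_peak_idx
              <= self.end_idx)
        if not ok:
            raise ValueError("blink indices must satisfy "
                             "start <= pos_peak < neg_peak <= end")


def _cheby_sos(rate: float, wp, ws) -> np.ndarray:
    nyq = rate / 2.0
    ws_hi = ws if np.isscalar(ws) else ws[1]
    if ws_hi >= nyq:
        raise ValueError(
            f"stopband edge {ws_hi} Hz is not below the Nyquist frequency "
            f"{nyq} Hz (rate {rate} Hz too low)")
    order, wn = signal.cheb1ord(wp, ws, PASSBAND_RIPPLE_DB,
                                STOPBAND_ATTEN_DB, fs=rate)
    btype = "lowpass" if np.isscalar(wp) else "bandpass"
    if btype == "lowpass" and order % 2 == 0:
        order += 1  # odd order puts a ripple peak (unit gain) at DC
    return signal.cheby1(order, PASSBAND_RIPPLE_DB, wn, btype=btype,
                         output="sos", fs=rate)


def lowpass_eeg(rec: MultichannelRecording) -> MultichannelRecording:
    """Chebyshev low-pass (40 Hz pass / 49 Hz stop), zero-phase."""
    sos = _cheby_sos(rec.rate, EEG_PASSBAND_HZ, EEG_STOPBAND_HZ)
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return MultichannelRecording(out, rec.rate, list(rec.channel_labels))


def bandpass_blink(rec: SingleChannelRecording) -> SingleChannelRecording:
    """Chebyshev band-pass (1-40 Hz), zero-phase; removes DC."""
    sos = _cheby_sos(rec.rate, list(BLINK_BAND_HZ), list(BLINK_STOP_HZ))
    out = signal.sosfiltfilt(sos, rec.samples)
    return SingleChannelRecording(out, rec.rate, rec.label)


def downsample_by_averaging(rec, factor: int = 4):
    """Average each run of ``factor`` consecutive samples (2400 -> 600 Hz).

    A trailing remainder shorter than ``factor`` is dropped and logged.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = rec.samples
    n = x.shape[-1]
    keep = (n // factor) * factor
    if keep != n:
        logger.info("downsample: dropping %d trailing samples", n - keep)
    if isinstance(rec, MultichannelRecording):
        out = x[:, :keep].reshape(x.shape[0], -1, factor).mean(axis=2)
        return MultichannelRecording(out, rec.rate / factor,
                                     list(rec.channel_labels))
    out = x[:keep].reshape(-1, factor).mean(axis=1)
    return SingleChannelRecording(out, rec.rate / factor, rec.label)


def epoch_and_baseline(rec: MultichannelRecording, events: EventList,
                       window_ms: tuple[float, float] = (-200.0, 1000.0),
                       baseline_ms: tuple[float, float] = (-200.0, 0.0),
                       ) -> EpochSet:
    """Cut [window) epochs around each onset and subtract the baseline mean.

    The baseline interval (default -200..0 ms) mean is removed per trial and
    channel. Raises when an epoch would fall outside the recording, naming
    the offending event.
    """
    rate = rec.rate
    start_off = int(round(window_ms[0] / 1000.0 * rate))
    stop_off = int(round(window_ms[1] / 1000.0 * rate))
    b0 = int(round(baseline_ms[0] / 1000.0 * rate)) - start_off
    b1 = int(round(baseline_ms[1] / 1000.0 * rate)) - start_off
    n_len = stop_off - start_off

    epochs = np.empty((len(events), rec.n_channels, n_len))
    for k, onset in enumerate(events.onsets):
        lo, hi = onset + start_off, onset + stop_off
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"epoch for event {k} (onset {onset}) spans [{lo}, {hi}) "
                f"outside the recording of {rec.n_samples} samples")
        epochs[k] = rec.samples[:, lo:hi]

    base = epochs[:, :, b0:b1].mean(axis=2, keepdims=True)
    epochs -= base
    return EpochSet(epochs, rate, list(events.labels),
                    baseline_samples=b1)


def _scan_to_zero(x: np.ndarray, idx: int, direction: int,
                  positive: bool) -> int:
    """Walk from a peak until the first sample of opposite (or zero) sign."""
    i = idx
    while 0 <= i + direction < x.size:
        i += direction
        if (x[i] <= 0) if positive else (x[i] >= 0):
            return i
    return i


def detect_blinks(rec: SingleChannelRecording,
                  pos_thresh: float = BLINK_POS_THRESH_UV,
                  neg_thresh: float = BLINK_NEG_THRESH_UV,
                  ) -> list[BlinkWaveform]:
    """Segment blinks from a filtered Fp1 trace.

    A blink is a positive excursion above ``pos_thresh`` followed by a
    negative excursion below ``neg_thresh``. The start is found by scanning
    backward from the positive peak to the first zero crossing, the end by
    scanning forward from the negative peak likewise. When several
    supra-threshold positive peaks precede one negative peak, the largest
    (earliest on ties) is kept. Returns blinks in temporal order; an empty
    list when none qualify.
    """
    x = rec.samples
    pos_peaks, _ = signal.find_peaks(x, height=pos_thresh)
    neg_peaks, _ = signal.find_peaks(-x, height=-neg_thresh)
    blinks: list[BlinkWaveform] = []
    prev_end = -1
    for npk in neg_peaks:
        if npk <= prev_end:
            continue
        cands = pos_peaks[(pos_peaks < npk) & (pos_peaks > prev_end)]
        if cands.size == 0:
            continue
        ppk = int(cands[np.argmax(x[cands])])  # argmax keeps earliest on ties
        start = _scan_to_zero(x, ppk, -1, positive=True)
        end = _scan_to_zero(x, npk, +1, positive=False)
        seg = x[start:end + 1].copy()
        blinks.append(BlinkWaveform(
            samples=seg, rate=rec.rate, start_idx=int(start),
            end_idx=int(end), pos_peak_idx=ppk, neg_peak_idx=int(npk),
            raw_pos_peak=float(x[ppk]), raw_neg_peak=float(x[npk])))
        prev_end = end
    return blinks


def normalize_blinks(blinks: list[BlinkWaveform]) -> list[BlinkWaveform]:
    """Divide every blink by the single largest absolute peak in the list.

    After normalization the global maximum absolute amplitude over all
    blinks is exactly 1. Idempotent. Raises on an empty list or all-zero
    peaks.
    """
    if not blinks:
        raise ValueError("no blinks to normalize")
    cur = max(float(np.max(np.abs(b.samples))) for b in blinks)
    if cur == 0:
        raise ValueError("all-zero blink amplitudes cannot be normalized")
    out = []
    for b in blinks:
        out.append(BlinkWaveform(
            samples=b.samples / cur, rate=b.rate, start_idx=b.start_idx,
            end_idx=b.end_idx, pos_peak_idx=b.pos_peak_idx,
            neg_peak_idx=b.neg_peak_idx, raw_pos_peak=b.raw_pos_peak,
            raw_neg_peak=b.raw_neg_peak))
    return out
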