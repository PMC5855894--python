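"""Time-domain morphological features of a normalized eye-blink waveform.

Twenty features per blink, in four groups:

* energy     — Ap, An (signed peak amplitudes), Ep, En (areas under the
               positive / negative pulse; En is the area magnitude)
* position   — Pp, Pn (peak times from blink start, s), Dp, Dn (pulse
               durations, s)
* slope      — S1..S4 (onset/offset slopes, amplitude per second, i.e.
               tan(theta) on an amplitude-vs-seconds plot), S5, S6
               (dispersion sigma/mean within each pulse)
* derivative — D1..D4 (extreme values/positions of the first derivative),
               D5, D6 (zero-crossing counts of the first/second derivative)

The positive pulse runs from the blink start to the positive-to-negative
zero crossing; the negative pulse is the remainder. Times are in seconds so
every feature is sampling-rate independent; a blink's position inside the
source recording affects nothing (all times are relative to its start).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BlinkWaveform

FEATURE_NAMES: tuple[str, ...] = (
    "Ap", "An", "Ep", "En", "Pp", "Pn", "Dp", "Dn",
    "S1", "S2", "S3", "S4", "S5", "S6",
    "D1", "D2", "D3", "D4", "D5", "D6",
)


@dataclass
class BlinkFeatureVector:
    """The 20 morphological features of one blink."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError("a blink feature vector has exactly 20 entries")

    def __getattr__(self, name: str):
        if name in FEATURE_NAMES:
            return float(self.values[FEATURE_NAMES.index(name)])
        raise AttributeError(name)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def _sign_changes(x: np.ndarray) -> int:
    """Strict sign changes; zero samples inherit the preceding sign."""
    s = np.sign(x)
    last = 0.0
    changes = 0
    for v in s:
        if v == 0:
            continue
        if last != 0 and v != last:
            changes += 1
        last = v
    return changes


def extract_blink_features(blink: BlinkWaveform) -> BlinkFeatureVector:
    """Compute the 20-feature vector from one normalized blink."""
    x = blink.samples
    rate = blink.rate
    n = x.size
    p = int(np.argmax(x))
    q = int(np.argmin(x))
    if not 0 < p < q < n:
        raise ValueError("blink lacks a positive pulse followed by a "
                         "negative pulse")
    # positive -> negative zero crossing splits the pulses
    after = np.nonzero(x[p:] <= 0)[0]
    if after.size == 0:
        raise ValueError("no zero crossing after the positive peak")
    mid = p + int(after[0])

    pos = x[:mid]
    neg = x[mid:]
    if pos.size < 2:
        raise ValueError("degenerate positive pulse (duration 0)")
    if neg.size < 2:
        raise ValueError("degenerate negative pulse (duration 0)")

    dt = 1.0 / rate
    ap = float(x[p])
    an = float(x[q])
    ep = float(np.trapezoid(pos, dx=dt))
    en = float(abs(np.trapezoid(neg, dx=dt)))
    pp = p * dt
    pn = q * dt
    dp = mid * dt                  # start .. zero crossing
    dn = (n - 1 - mid) * dt        # zero crossing .. end

    t_mid = mid * dt
    t_end = (n - 1) * dt
    s1 = ap / pp
    s3 = ap / (t_mid - pp) if t_mid > pp else np.inf
    s2 = an / (pn - t_mid) if pn > t_mid else -np.inf
    s4 = an / (t_end - pn) if t_end > pn else -np.inf

    s5 = float(np.std(pos) / np.mean(pos))
    s6 = float(np.std(neg) / np.mean(np.abs(neg)))

    d = np.diff(x) * rate
    d1 = float(d.max())
    d2 = float(d.min())
    d3 = int(np.argmax(d)) * dt
    d4 = int(np.argmin(d)) * dt
    d5 = _sign_changes(d)
    d6 = _sign_changes(np.diff(d) * rate)

    return BlinkFeatureVector(np.array([
        ap, an, ep, en, pp, pn, dp, dn,
        s1, s2, s3, s4, s5, s6,
        d1, d2, d3, d4, float(d5), float(d6),
    ]))


def features_for_session(blinks: list[BlinkWaveform],
                         target_count: int | None = None,
                         seed: int = 0) -> list[BlinkFeatureVector]:
    """One feature vector per blink, order preserved.

    With ``target_count`` a seeded random subset (or with-replacement
    upsample) of that size is taken first, emulating the random pick of a
    fixed number of blinks per subject.
    """
    if not blinks:
        raise ValueError("empty blink list")
    if target_count is not None:
        rng = np.random.default_rng(seed)
        replace = target_count > len(blinks)
        pick = np.sort(rng.choice(len(blinks), size=target_count,
                                  replace=replace))
        blinks = [blinks[i] for i in pick]
    return [extract_blink_features(b) for b in blinks]


def feature_matrix(vectors: list[BlinkFeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n, 20) array."""
    return np.vstack([v.values for v in vectors])
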