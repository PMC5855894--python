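"""Synthetic subjects, EEG sessions, and eye-blink sessions.

The generator emulates the statistical structure a face-RSVP authentication
pipeline assumes: each subject carries an N250-like event-related deflection
with subject-specific latency, amplitude and scalp topography, a contrast
between self-face and non-self-face stimuli, 1/f ("pink") background noise,
and a biphasic eye-blink waveform (positive lobe above 100 uV followed by a
negative undershoot below -50 uV) with subject-specific segment durations.

All randomness flows from explicit integer seeds; there is no global RNG
state anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# 16-electrode montage used throughout (frontal, central, parietal, occipital).
CHANNEL_LABELS: tuple[str, ...] = (
    "Fz", "Cz", "P3", "Pz", "P4", "Po7", "Oz", "Po8",
    "C3", "C4", "F3", "F4", "Af7", "Af8", "Cp5", "Cp6",
)
N_CHANNELS = len(CHANNEL_LABELS)

# Documented generator ranges (uniform draws per subject). The face-sensitive
# component is a negative deflection peaking 200-350 ms post-stimulus, largest
# over parieto-occipital sites; across-subject variability of real ERPs is not
# quantified anywhere authoritative, so these ranges are package choices.
ERP_LATENCY_RANGE_MS = (200.0, 350.0)
ERP_WIDTH_RANGE_MS = (40.0, 80.0)
ERP_AMP_SELF_RANGE_UV = (5.0, 9.0)      # peak magnitude, self-face response
ERP_AMP_NONSELF_RANGE_UV = (1.0, 3.0)   # peak magnitude, non-self response
BLINK_POS_AMP_RANGE_UV = (150.0, 300.0)
BLINK_NEG_AMP_RANGE_UV = (-120.0, -60.0)
BLINK_RISE_RANGE_MS = (60.0, 110.0)
BLINK_FALL_RANGE_MS = (60.0, 110.0)
BLINK_UNDERSHOOT_RANGE_MS = (100.0, 170.0)

# Channels where the face-sensitive component is concentrated.
_POSTERIOR = np.array([2, 3, 4, 5, 6, 7])  # P3, Pz, P4, Po7, Oz, Po8


@dataclass(frozen=True)
class SubjectProfile:
    """Latent parameters of one synthetic subject.

    ERP amplitudes are signed per-channel peak values in microvolts (the
    component is a negative deflection, so amplitudes are negative on the
    carrying channels). Blink parameters describe a biphasic pulse: a
    raised-cosine positive lobe (rise + fall segments) followed by a
    raised-cosine negative undershoot.
    """

    subject_id: str
    erp_amp_self: np.ndarray      # (16,) uV
    erp_amp_nonself: np.ndarray   # (16,) uV
    erp_latency: float            # ms post-stimulus
    erp_width: float              # ms (FWHM of the Gaussian deflection)
    blink_pos_amp: float          # uV, > 100
    blink_neg_amp: float          # uV, < -50
    blink_rise_ms: float
    blink_fall_ms: float
    blink_undershoot_ms: float
    seed: int

    def __post_init__(self) -> None:
        if not self.blink_pos_amp > 100.0:
            raise ValueError("blink_pos_amp must exceed 100 uV")
        if not self.blink_neg_amp < -50.0:
            raise ValueError("blink_neg_amp must be below -50 uV")
        if not 0.0 < self.erp_latency < 1000.0:
            raise ValueError("erp_latency must lie in (0, 1000) ms")
        for name in ("erp_width", "blink_rise_ms", "blink_fall_ms",
                     "blink_undershoot_ms"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """Stimulus/recording layout of one EEG acquisition session.

    ``n_trials`` counts stimulus presentations (face images); a fraction
    ``self_ratio`` of them are self-face images, mirroring the 1-in-10
    self/non-self RSVP composition. ``soa_ms`` is the stimulus-onset
    asynchrony (300 ms in the RSVP paradigm; epochs of neighbouring stimuli
    therefore overlap, as they do in real RSVP data).
    """

    n_trials: int
    self_ratio: float = 0.1
    noise_sd: float = 2.0          # uV
    noise_spectrum: str = "pink"   # "pink" | "white"
    sample_rate: float = 2400.0    # Hz
    soa_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.self_ratio < 1.0:
            raise ValueError("self_ratio must lie strictly between 0 and 1")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.noise_spectrum not in ("pink", "white"):
            raise ValueError("noise_spectrum must be 'pink' or 'white'")


def make_subject(subject_id: str, seed: int) -> SubjectProfile:
    """Draw a deterministic subject profile from the documented ranges."""
    rng = np.random.default_rng(seed)
    latency = rng.uniform(*ERP_LATENCY_RANGE_MS)
    width = rng.uniform(*ERP_WIDTH_RANGE_MS)

    # Topography: smooth random weights in [0, 1], boosted over posterior
    # sites so the component is face-sensitive; peak channel weight is 1.
    topo = rng.uniform(0.1, 0.5, size=N_CHANNELS)
    topo[_POSTERIOR] += rng.uniform(0.4, 0.8, size=_POSTERIOR.size)
    topo /= topo.max()
    amp_self = -rng.uniform(*ERP_AMP_SELF_RANGE_UV) * topo

    topo_ns = rng.uniform(0.1, 0.5, size=N_CHANNELS)
    topo_ns[_POSTERIOR] += rng.uniform(0.2, 0.5, size=_POSTERIOR.size)
    topo_ns /= topo_ns.max()
    amp_nonself = -rng.uniform(*ERP_AMP_NONSELF_RANGE_UV) * topo_ns

    return SubjectProfile(
        subject_id=subject_id,
        erp_amp_self=amp_self,
        erp_amp_nonself=amp_nonself,
        erp_latency=float(latency),
        erp_width=float(width),
        blink_pos_amp=float(rng.uniform(*BLINK_POS_AMP_RANGE_UV)),
        blink_neg_amp=float(rng.uniform(*BLINK_NEG_AMP_RANGE_UV)),
        blink_rise_ms=float(rng.uniform(*BLINK_RISE_RANGE_MS)),
        blink_fall_ms=float(rng.uniform(*BLINK_FALL_RANGE_MS)),
        blink_undershoot_ms=float(rng.uniform(*BLINK_UNDERSHOOT_RANGE_MS)),
        seed=int(seed),
    )


def drift_subject(profile: SubjectProfile, amp_scale: float,
                  latency_shift_ms: float, seed: int) -> SubjectProfile:
    """Perturb a profile to emulate a later acquisition session.

    ``amp_scale`` is the SD of a multiplicative jitter applied to the ERP
    amplitudes, ``latency_shift_ms`` the SD of an additive latency jitter.
    """
    rng = np.random.default_rng(seed)
    factor = float(np.exp(rng.normal(0.0, amp_scale)))
    shift = float(rng.normal(0.0, latency_shift_ms))
    new_lat = float(np.clip(profile.erp_latency + shift, 1.0, 999.0))
    return replace(
        profile,
        erp_amp_self=profile.erp_amp_self * factor,
        erp_amp_nonself=profile.erp_amp_nonself * factor,
        erp_latency=new_lat,
    )


def erp_template(profile: SubjectProfile, which: str, rate: float,
                 duration_ms: float = 1000.0) -> np.ndarray:
    """Per-channel ERP template on [0, duration) ms post-stimulus.

    A Gaussian-windowed deflection: amplitude * exp(-(t - latency)^2 / 2s^2)
    with s = FWHM / 2.355, truncated to the post-stimulus window (exactly
    zero outside it, which makes zero-noise epochs reproduce the template
    bit-for-bit).
    """
    amp = profile.erp_amp_self if which == "self" else profile.erp_amp_nonself
    n = int(round(duration_ms / 1000.0 * rate))
    t_ms = np.arange(n) / rate * 1000.0
    s = profile.erp_width / 2.355
    shape = np.exp(-0.5 * ((t_ms - profile.erp_latency) / s) ** 2)
    return amp[:, None] * shape[None, :]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                sd: float) -> np.ndarray:
    """1/f-amplitude noise, unit-variance per channel, scaled to ``sd``."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    std = out.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return out / std * sd


def gen_eeg_session(profile: SubjectProfile, spec: SessionSpec,
                    viewer: SubjectProfile | None = None):
    """Generate one 16-channel RSVP session.

    Returns ``(MultichannelRecording, EventList)``. ``n_trials`` stimuli are
    presented every ``soa_ms``; a fraction ``self_ratio`` (exact count,
    seeded order) are self-face images. Self-face stimuli evoke the *self*
    template, non-self stimuli the *non-self* template.

    ``viewer``: when a different subject watches this user's stimulus stream
    (an imposter attempt), pass their profile here — every image is then a
    non-self face for them and evokes the viewer's non-self template.
    """
    from .preprocess import EventList, MultichannelRecording

    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    soa = int(round(spec.soa_ms / 1000.0 * rate))
    pre_pad = int(round(0.3 * rate))
    post_pad = int(round(1.2 * rate))
    n_samp = pre_pad + max(spec.n_trials - 1, 0) * soa + post_pad
    if spec.n_trials == 0:
        n_samp = pre_pad + post_pad

    data = np.zeros((N_CHANNELS, n_samp))
    if spec.noise_sd > 0:
        if spec.noise_spectrum == "pink":
            data += _pink_noise(rng, data.shape, spec.noise_sd)
        else:
            data += rng.standard_normal(data.shape) * spec.noise_sd

    n_self = int(round(spec.n_trials * spec.self_ratio))
    labels = np.array(["nonself"] * spec.n_trials, dtype=object)
    if spec.n_trials:
        self_pos = rng.choice(spec.n_trials, size=n_self, replace=False)
        labels[np.sort(self_pos)] = "self"
    onsets = pre_pad + np.arange(spec.n_trials) * soa

    responder = viewer if viewer is not None else profile
    tmpl_self = erp_template(responder, "self", rate)
    tmpl_nonself = erp_template(responder, "nonself", rate)
    for onset, lab in zip(onsets, labels):
        if viewer is None and lab == "self":
            tmpl = tmpl_self
        else:
            tmpl = tmpl_nonself
        data[:, onset:onset + tmpl.shape[1]] += tmpl

    rec = MultichannelRecording(samples=data, rate=rate,
                                channel_labels=list(CHANNEL_LABELS))
    events = EventList(onsets=onsets.astype(int), labels=list(labels))
    return rec, events


def blink_template(profile: SubjectProfile, rate: float) -> np.ndarray:
    """One noise-free biphasic blink pulse sampled at ``rate``.

    Piecewise raised-cosine: rise segment 0 -> pos_amp over ``blink_rise_ms``,
    fall segment pos_amp -> 0 over ``blink_fall_ms``, then a full
    raised-cosine negative lobe reaching ``blink_neg_amp`` over
    ``blink_undershoot_ms``. Closed-form areas: the positive pulse integrates
    to pos_amp*(rise+fall)/2, the undershoot to neg_amp*undershoot/2.
    """
    n_rise = int(round(profile.blink_rise_ms / 1000.0 * rate))
    n_fall = int(round(profile.blink_fall_ms / 1000.0 * rate))
    n_und = int(round(profile.blink_undershoot_ms / 1000.0 * rate))
    t_r = np.arange(n_rise) / max(n_rise, 1)
    t_f = np.arange(n_fall) / max(n_fall, 1)
    t_u = np.arange(n_und) / max(n_und, 1)
    rise = profile.blink_pos_amp * 0.5 * (1.0 - np.cos(np.pi * t_r))
    fall = profile.blink_pos_amp * 0.5 * (1.0 + np.cos(np.pi * t_f))
    under = profile.blink_neg_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t_u))
    return np.concatenate([rise, fall, under])


def gen_blink_session(profile: SubjectProfile, n_blinks: int,
                      noise_sd: float, seed: int,
                      rate: float = 2400.0,
                      duration_s: float | None = None):
    """Generate an Fp1-like single-channel trace containing ``n_blinks``
    biphasic pulses at jittered, non-overlapping positions plus noise.

    When ``duration_s`` is given the blinks are packed into that span and a
    ``ValueError`` is raised if the density would force pulses to overlap;
    otherwise the trace is sized for roughly one blink every 1.5 s (10-12
    natural blinks fit a 15-20 s trial).
    """
    from .preprocess import SingleChannelRecording

    if n_blinks < 0:
        raise ValueError("n_blinks must be non-negative")
    rng = np.random.default_rng(seed)
    tmpl = blink_template(profile, rate)
    margin = int(round(0.5 * rate))
    if duration_s is None:
        gap = int(round(0.8 * rate))       # >= 0.8 s between blinks
        slot = tmpl.size + gap
        n_samp = margin * 2 + max(n_blinks, 1) * slot
    else:
        n_samp = int(round(duration_s * rate))
        if n_blinks > 0:
            slot = (n_samp - 2 * margin) // n_blinks
            if slot < tmpl.size:
                raise ValueError(
                    "blinks would overlap at the requested density: "
                    f"slot {slot} samples < pulse {tmpl.size} samples")
            gap = slot - tmpl.size

    data = np.zeros(n_samp)
    if noise_sd > 0:
        data += _pink_noise(rng, (1, n_samp), noise_sd)[0]

    onsets = []
    for k in range(n_blinks):
        jitter = rng.integers(0, max(gap // 2, 0) + 1)
        onset = margin + k * slot + int(jitter)
        data[onset:onset + tmpl.size] += tmpl
        onsets.append(onset)

    rec = SingleChannelRecording(samples=data, rate=rate, label="Fp1")
    rec.blink_onsets = np.asarray(onsets, dtype=int)  # ground truth for tests
    return rec
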