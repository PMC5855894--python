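"""Session and model persistence plus the registration/login pipeline.

Session bundles travel in a plain-text "matrix + JSON" dialect designed for
lossless round trips: ``<stem>.meta.json`` holds the metadata (subject id,
rates, channel labels, 0-based event onsets and labels), ``<stem>.eeg.tsv``
the time x channels EEG matrix in microvolts, and ``<stem>.blink.tsv`` the
single-channel Fp1 trace. Values are written with 17 significant digits so
text round trips are bit-identical.

EDF files are read through MNE (optional dependency); channels are mapped
by label onto the fixed 16-electrode montage, and a blink file must contain
an Fp1 channel.

Trained user models (selection mask, CNN, NN, fusion coefficients) are
stored as a single JSON container carrying the architecture specs and seeds
alongside the weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .erp_features import SelectionMask
from .evaluate import UserModel, derive_seed, train_user_system
from .fusion import FusionModel, decide, fuse
from .preprocess import (EventList, MultichannelRecording,
                         SingleChannelRecording, bandpass_blink,
                         detect_blinks, downsample_by_averaging,
                         epoch_and_baseline, lowpass_eeg, normalize_blinks)
from .blink_features import feature_matrix, features_for_session
from .scoring import CnnScorer, CnnSpec, NnScorer, NnSpec
from .synthgen import CHANNEL_LABELS

logger = logging.getLogger("neuroauth")

_FLOAT_FMT = "%.17g"


@dataclass
class SessionBundle:
    """One subject's acquisition: EEG + events + blink trace + metadata."""

    eeg: MultichannelRecording
    events: EventList
    blink: SingleChannelRecording
    subject_id: str
    session_id: str = "s1"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")


def write_session(bundle: SessionBundle, stem: str | Path) -> Path:
    """Write a bundle in the matrix+JSON dialect; returns the meta path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(stem.with_suffix(".eeg.tsv"), bundle.eeg.samples.T,
               fmt=_FLOAT_FMT, delimiter="\t",
               header="\t".join(bundle.eeg.channel_labels), comments="")
    np.savetxt(stem.with_suffix(".blink.tsv"), bundle.blink.samples,
               fmt=_FLOAT_FMT, header=bundle.blink.label, comments="")
    meta = {
        "subject_id": bundle.subject_id,
        "session_id": bundle.session_id,
        "eeg_rate_hz": bundle.eeg.rate,
        "blink_rate_hz": bundle.blink.rate,
        "channel_labels": list(bundle.eeg.channel_labels),
        "units": "uV",
        "events": {"onsets": bundle.events.onsets.tolist(),
                   "labels": list(bundle.events.labels)},
    }
    path = stem.with_suffix(".meta.json")
    path.write_text(json.dumps(meta, indent=1))
    return path


def order_channels(samples: np.ndarray, labels: list[str],
                   montage: tuple[str, ...] = CHANNEL_LABELS) -> np.ndarray:
    """Reorder a channels x time matrix into the fixed montage order."""
    lut = {l.lower(): i for i, l in enumerate(labels)}
    unknown = [l for l in labels if l.lower() not in
               {m.lower() for m in montage}]
    missing = [m for m in montage if m.lower() not in lut]
    if missing:
        raise ValueError(f"missing montage channels: {missing}; "
                         f"unmapped labels: {unknown}")
    return samples[[lut[m.lower()] for m in montage]]


def read_session(stem: str | Path, fmt: str = "matrix-json") -> SessionBundle:
    """Read a session bundle (``matrix-json`` or ``edf``)."""
    stem = Path(stem)
    if fmt == "matrix-json":
        meta_path = stem.with_suffix(".meta.json")
        try:
            meta = json.loads(meta_path.read_text())
        except json.JSONDecodeError as e:
            raise ValueError(
                f"malformed sidecar {meta_path}: line {e.lineno}, "
                f"column {e.colno}: {e.msg}") from e
        for key in ("subject_id", "eeg_rate_hz", "channel_labels", "events"):
            if key not in meta:
                raise ValueError(f"sidecar {meta_path} lacks field '{key}'")
        eeg = np.loadtxt(stem.with_suffix(".eeg.tsv"), skiprows=1, ndmin=2).T
        blink = np.loadtxt(stem.with_suffix(".blink.tsv"), skiprows=1)
        return SessionBundle(
            eeg=MultichannelRecording(eeg, meta["eeg_rate_hz"],
                                      meta["channel_labels"]),
            events=EventList(np.asarray(meta["events"]["onsets"]),
                             list(meta["events"]["labels"])),
            blink=SingleChannelRecording(blink, meta["blink_rate_hz"]),
            subject_id=meta["subject_id"],
            session_id=meta.get("session_id", "s1"))
    if fmt == "edf":
        return _read_session_edf(stem)
    raise ValueError(f"unknown session format: {fmt!r}")


def _read_session_edf(path: Path) -> SessionBundle:
    import mne  # optional, used only for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # MNE returns volts
    low = [l.lower() for l in labels]
    if "fp1" not in low:
        raise ValueError("blink channel Fp1 missing from EDF")
    blink = SingleChannelRecording(data[low.index("fp1")], raw.info["sfreq"])
    eeg_rows = [i for i, l in enumerate(low) if l != "fp1"]
    eeg = order_channels(data[eeg_rows],
                         [labels[i] for i in eeg_rows])
    onsets, evt_labels = [], []
    for ann in raw.annotations:
        onsets.append(int(round(ann["onset"] * raw.info["sfreq"])))
        evt_labels.append(str(ann["description"]))
    return SessionBundle(
        eeg=MultichannelRecording(eeg, raw.info["sfreq"],
                                  list(CHANNEL_LABELS)),
        events=EventList(np.asarray(onsets, dtype=int), evt_labels),
        blink=blink, subject_id=path.stem)


# ------------------------------------------------------------ model store


def _mask_to_json(mask: SelectionMask) -> dict:
    return {"channels": mask.channels.tolist(),
            "time_indices": mask.time_indices.tolist(),
            "channel_scores": mask.channel_scores.tolist()}


def _mask_from_json(d: dict) -> SelectionMask:
    return SelectionMask(channels=np.asarray(d["channels"]),
                         time_indices=np.asarray(d["time_indices"]),
                         channel_scores=np.asarray(d["channel_scores"]))


def save_user_model(model: UserModel, path: str | Path) -> Path:
    """Serialize a trained user model (weights, specs, seeds) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cnn, nn, fu = model.cnn, model.nn, model.fusion
    payload = {
        "user_id": model.user_id,
        "mask": _mask_to_json(model.mask),
        "cnn": {
            "spec": asdict(cnn.spec),
            "weights": {k: getattr(cnn, k).tolist()
                        for k in ("W1", "b1", "W2", "b2", "W3", "b3")},
            "mu": cnn.mu, "sigma": cnn.sigma,
        },
        "nn": {
            "spec": {**asdict(nn.spec), "hidden": list(nn.spec.hidden)},
            "weights": [w.tolist() for w in nn.weights],
            "biases": [b.tolist() for b in nn.biases],
            "mu": nn.mu.tolist(), "sigma": nn.sigma.tolist(),
        },
        "fusion": {"lam": fu.lam.tolist(), "M": fu.M, "N": fu.N,
                   "threshold": fu.threshold},
    }
    path.write_text(json.dumps(payload))
    return path


def load_user_model(path: str | Path) -> UserModel:
    d = json.loads(Path(path).read_text())
    cnn = CnnScorer(CnnSpec(**d["cnn"]["spec"]))
    for k, v in d["cnn"]["weights"].items():
        setattr(cnn, k, np.asarray(v, dtype=float))
    cnn.mu, cnn.sigma = d["cnn"]["mu"], d["cnn"]["sigma"]
    nn_spec = dict(d["nn"]["spec"])
    nn_spec["hidden"] = tuple(nn_spec["hidden"])
    nn = NnScorer(NnSpec(**nn_spec))
    nn.weights = [np.asarray(w, dtype=float) for w in d["nn"]["weights"]]
    nn.biases = [np.asarray(b, dtype=float) for b in d["nn"]["biases"]]
    nn.mu = np.asarray(d["nn"]["mu"], dtype=float)
    nn.sigma = np.asarray(d["nn"]["sigma"], dtype=float)
    fu = FusionModel(lam=np.asarray(d["fusion"]["lam"]), M=d["fusion"]["M"],
                     N=d["fusion"]["N"], threshold=d["fusion"]["threshold"])
    return UserModel(user_id=d["user_id"], profile=None, mask=_mask_from_json(
        d["mask"]), cnn=cnn, nn=nn, fusion=fu)


# -------------------------------------------------------------- pipeline


def _bundle_to_epochs(bundle: SessionBundle):
    rec = lowpass_eeg(bundle.eeg)
    events = bundle.events
    factor = int(round(rec.rate / 600.0))
    if factor > 1:
        rec = downsample_by_averaging(rec, factor)
        events = events.downsampled(factor)
    return epoch_and_baseline(rec, events)


def _bundle_to_blink_vectors(bundle: SessionBundle, seed: int = 0):
    rec = bandpass_blink(bundle.blink)
    factor = int(round(rec.rate / 600.0))
    if factor > 1:
        rec = downsample_by_averaging(rec, factor)
    blinks = normalize_blinks(detect_blinks(rec))
    return feature_matrix(features_for_session(blinks, seed=seed))


def run_pipeline(config: dict) -> dict:
    """Registration or login, driven by a config mapping.

    Registration (``mode: "register"``): trains and stores one user's model
    from a user session and a list of imposter sessions::

        {"mode": "register", "user_session": STEM,
         "imposter_sessions": [STEM, ...], "model_out": PATH,
         "seed": INT, "cnn_epochs": ..., "nn_epochs": ...,
         "test_fraction": ..., "fusion_order": ..., "smote_k": ...}

    Login (``mode: "login"``): scores a session against a stored model and
    returns the fused score and accept/reject decision::

        {"mode": "login", "session": STEM, "model": PATH, "seed": INT}

    Every run writes ``<out>.manifest.json`` recording inputs, seeds and
    parameters, sufficient to reproduce the run bit-for-bit.
    """
    mode = config.get("mode")
    if mode == "register":
        seed = int(config.get("seed", 0))
        user = read_session(config["user_session"])
        imps = [read_session(p) for p in config["imposter_sessions"]]
        user_epochs = _bundle_to_epochs(user)
        imp_epochs = [_bundle_to_epochs(b) for b in imps]
        user_vecs = _bundle_to_blink_vectors(user, derive_seed(seed, 1))
        imp_vecs = np.concatenate([
            _bundle_to_blink_vectors(b, derive_seed(seed, 2, j))
            for j, b in enumerate(imps)])
        mask, cnn, nn, fu, result = train_user_system(
            user.subject_id, user_epochs, imp_epochs, user_vecs, imp_vecs,
            test_fraction=float(config.get("test_fraction", 0.1)),
            fusion_order=int(config.get("fusion_order", 2)),
            smote_k=int(config.get("smote_k", 5)),
            cnn_epochs=int(config.get("cnn_epochs", 500)),
            nn_epochs=int(config.get("nn_epochs", 2000)),
            seed=seed)
        model = UserModel(user_id=user.subject_id, profile=None, mask=mask,
                          cnn=cnn, nn=nn, fusion=fu)
        out = Path(config["model_out"])
        save_user_model(model, out)
        report = {
            "mode": "register", "user_id": user.subject_id,
            "model": str(out),
            "held_out_acc_fused": result.fused.acc,
            "held_out_acc_eeg": result.eeg.acc,
        }
        _write_manifest(out, config)
        return report

    if mode == "login":
        model = load_user_model(config["model"])
        bundle = read_session(config["session"])
        seed = int(config.get("seed", 0))
        epochs = _bundle_to_epochs(bundle)
        from .evaluate import _self_maps  # shared map construction
        maps = _self_maps(epochs, model.mask)
        vecs = _bundle_to_blink_vectors(bundle, derive_seed(seed, 3))
        rng = np.random.default_rng(derive_seed(seed, 4))
        k = min(len(maps), len(vecs))
        s1 = model.cnn.score_batch(maps)
        s2 = model.nn.score_batch(vecs)
        s1 = rng.permutation(s1)[:k]
        s2 = rng.permutation(s2)[:k]
        fused = [fuse(model.fusion, np.array([a, b]))
                 for a, b in zip(s1, s2)]
        s_f = float(np.mean(fused))
        accept = decide(model.fusion, s_f)
        report = {"mode": "login", "user_id": model.user_id,
                  "session": str(config["session"]),
                  "fused_score": s_f, "accept": accept}
        _write_manifest(Path(config["model"]).with_suffix(".login"), config)
        return report

    raise ValueError(f"unknown pipeline mode: {mode!r}")


def _write_manifest(out_stem: Path, config: dict) -> None:
    manifest = {"config": {k: (str(v) if isinstance(v, Path) else v)
                           for k, v in config.items()}}
    Path(str(out_stem) + ".manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
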