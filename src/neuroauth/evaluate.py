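"""Authentication metrics, ROC curves, and the three evaluation protocols.

Metrics follow the standard biometric definitions: ACC is the fraction of
correctly authenticated attempts, FAR the fraction of imposter attempts
accepted, FRR the fraction of genuine-user attempts rejected. The exact
count identity ACC*(n_user+n_imposter) = (1-FAR)*n_imposter + (1-FRR)*n_user
holds on every run.

Protocols (each fully seeded, per-user seeds derived from the master seed
through a counter scheme):

* closed set   — per user: generate the user's RSVP session and one session
  per enrolled imposter watching the same stimulus stream; select channels
  and time points from the user's self/non-self contrast; build sparse ERP
  maps from self-face epochs (adjacent trials averaged pairwise); balance
  the user class with SMOTE; split train/test per class; train the CNN and
  blink NN; fit the least-squares fusion on training scores; report EEG-only
  and fused metrics on the held-out scores.
* open set     — previously unseen imposters are scored against each user's
  frozen models; only FAR is meaningful.
* permanence   — a later acquisition session of each user (profile drift:
  multiplicative amplitude jitter, additive latency jitter) is scored
  against the frozen models; only FRR is meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import synthgen
from .blink_features import feature_matrix, features_for_session
from .erp_features import (SelectionMask, average_adjacent_trials,
                           feature_maps_for_epochs, pointwise_biserial,
                           select_channels_times)
from .fusion import FusionModel, build_design, decide, fit_fusion, fuse_batch
from .preprocess import (EpochSet, bandpass_blink, detect_blinks,
                         downsample_by_averaging, epoch_and_baseline,
                         lowpass_eeg, normalize_blinks)
from .scoring import (CnnScorer, CnnSpec, NnScorer, NnSpec, SmoteConfig,
                      smote_oversample, train_cnn, train_nn)

TARGET_RATE = 600.0  # Hz after the averaging downsampler


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from a master seed plus counter indices."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ----------------------------------------------------------------- metrics


@dataclass
class AuthMetrics:
    """ACC / FAR / FRR with their denominators.

    Rates with a zero denominator are reported as NaN (undefined), never 0.
    """

    acc: float
    far: float
    frr: float
    n_user_tests: int
    n_imposter_tests: int


def compute_metrics(decisions, labels) -> AuthMetrics:
    """Exact ACC/FAR/FRR ratios from accept/reject decisions.

    ``decisions``: accept = True/1; ``labels``: user = 1, imposter = 0.
    """
    d = np.asarray(decisions, dtype=bool)
    y = np.asarray(labels, dtype=int)
    if d.size != y.size:
        raise ValueError("decisions and labels must have equal length")
    n_user = int((y == 1).sum())
    n_imp = int((y == 0).sum())
    correct = int(((d == 1) == (y == 1)).sum())
    acc = correct / d.size if d.size else math.nan
    far = float(d[y == 0].sum() / n_imp) if n_imp else math.nan
    frr = float((~d[y == 1]).sum() / n_user) if n_user else math.nan
    return AuthMetrics(acc=acc, far=far, frr=frr,
                       n_user_tests=n_user, n_imposter_tests=n_imp)


def roc(scores, labels, n_thresholds: int | None = None) -> np.ndarray:
    """Threshold-sweep ROC: rows of (FAR, TPR), FAR non-decreasing,
    endpoints (0,0) and (1,1). Accept iff score >= threshold.

    With ``n_thresholds`` the sweep uses that many evenly spaced cutoffs
    over the score range instead of every unique score.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    if n_thresholds is None:
        thr = np.unique(s)[::-1]
    else:
        thr = np.linspace(s.max(), s.min(), n_thresholds)
    pts = [(0.0, 0.0)]
    n_imp = (y == 0).sum()
    n_user = (y == 1).sum()
    for t in thr:
        acc = s >= t
        pts.append((float(acc[y == 0].sum() / n_imp),
                    float(acc[y == 1].sum() / n_user)))
    pts.append((1.0, 1.0))
    arr = np.array(pts)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def auc(scores, labels) -> float:
    """Area under the threshold-sweep ROC (trapezoidal)."""
    curve = roc(scores, labels)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


# ------------------------------------------------------------ cohort spec


@dataclass(frozen=True)
class CohortSpec:
    """Sizes, noise levels and seeds of a synthetic evaluation cohort.

    Defaults mirror the full acquisition protocol (15 enrolled imposters and
    10 unseen imposters per user, 2000 stimuli -> 200 self-face epochs ->
    100 averaged trials, 100 blinks, SMOTE to the imposter count, a 10%
    held-out split, 50 login attempts in the permanence session).
    ``small()`` returns the scaled-down cohort used for desk-scale checks.
    """

    n_users: int = 15
    n_imposters_per_user: int = 15
    n_open_imposters: int = 10
    n_trials: int = 2000           # stimulus presentations per EEG session
    self_ratio: float = 0.1
    n_blinks: int = 100
    sample_rate: float = 2400.0
    noise_sd: float = 2.0          # uV, EEG background
    blink_noise_sd: float = 5.0    # uV, Fp1 background
    noise_spectrum: str = "pink"
    test_fraction: float = 0.1
    fusion_order: int = 2
    smote_k: int = 5
    cnn_epochs: int = 500
    nn_epochs: int = 2000
    n_login: int = 50              # permanence login attempts per user
    drift_amp: float = 0.1         # SD of log amplitude jitter
    drift_latency_ms: float = 10.0
    null_effect: bool = False      # identical templates for every subject
    seed: int = 0

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """Scaled-down cohort: 5 users, 2 enrolled + 2 unseen imposters,
        300 stimuli (30 self-face epochs -> 15 averaged trials), 12 blinks,
        600 Hz acquisition, shorter training schedules."""
        base = dict(
            n_users=5, n_imposters_per_user=2, n_open_imposters=2,
            n_trials=300, n_blinks=12, sample_rate=600.0,
            noise_sd=2.0, blink_noise_sd=5.0, test_fraction=0.2,
            smote_k=3, cnn_epochs=150, nn_epochs=600, n_login=10,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class UserModel:
    """Everything frozen at enrolment time for one user."""

    user_id: str
    profile: synthgen.SubjectProfile
    mask: SelectionMask
    cnn: CnnScorer
    nn: NnScorer
    fusion: FusionModel


@dataclass
class UserResult:
    user_id: str
    eeg: AuthMetrics
    fused: AuthMetrics
    auc_eeg: float
    auc_fused: float


# -------------------------------------------------------- pipeline pieces


def _session_epochs(stim_profile: synthgen.SubjectProfile,
                    cohort: CohortSpec, seed: int,
                    viewer: synthgen.SubjectProfile | None = None,
                    n_trials: int | None = None) -> EpochSet:
    """Generate, filter, downsample and epoch one RSVP session."""
    spec = synthgen.SessionSpec(
        n_trials=n_trials if n_trials is not None else cohort.n_trials,
        self_ratio=cohort.self_ratio, noise_sd=cohort.noise_sd,
        noise_spectrum=cohort.noise_spectrum,
        sample_rate=cohort.sample_rate, seed=seed)
    rec, events = synthgen.gen_eeg_session(stim_profile, spec, viewer=viewer)
    rec = lowpass_eeg(rec)
    factor = int(round(rec.rate / TARGET_RATE))
    if factor > 1:
        rec = downsample_by_averaging(rec, factor)
        events = events.downsampled(factor)
    return epoch_and_baseline(rec, events)


def _self_maps(epochs: EpochSet, mask: SelectionMask) -> np.ndarray:
    """Averaged self-face epochs -> stacked expanded 20 x 20 maps."""
    sel = epochs.subset(np.array([l == "self" for l in epochs.labels]))
    avg = average_adjacent_trials(sel, group=2)
    maps = feature_maps_for_epochs(avg, mask)
    return np.stack([m.expanded for m in maps])


def _blink_vectors(profile: synthgen.SubjectProfile, cohort: CohortSpec,
                   n_blinks: int, seed: int) -> np.ndarray:
    """Generate, filter, segment, normalize and featurize one blink run."""
    rec = synthgen.gen_blink_session(profile, n_blinks,
                                     cohort.blink_noise_sd, seed,
                                     rate=cohort.sample_rate)
    rec = bandpass_blink(rec)
    factor = int(round(rec.rate / TARGET_RATE))
    if factor > 1:
        rec = downsample_by_averaging(rec, factor)
    blinks = normalize_blinks(detect_blinks(rec))
    vecs = features_for_session(blinks, target_count=n_blinks, seed=seed)
    return feature_matrix(vecs)


def _split(n: int, test_fraction: float, rng: np.random.Generator):
    n_test = max(1, int(round(n * test_fraction)))
    order = rng.permutation(n)
    return order[n_test:], order[:n_test]


def _paired(eeg_scores: np.ndarray, blink_scores: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Pair the i-th (shuffled) EEG score with the i-th blink score."""
    k = min(eeg_scores.size, blink_scores.size)
    return np.column_stack([rng.permutation(eeg_scores)[:k],
                            rng.permutation(blink_scores)[:k]])


def _cohort_profiles(cohort: CohortSpec):
    """User profiles plus per-user enrolled-imposter profiles."""
    users, imposters = [], []
    if cohort.null_effect:
        base = synthgen.make_subject("null-base", derive_seed(cohort.seed, 99))
        flat = replace(base, erp_amp_self=base.erp_amp_nonself.copy())
        for u in range(cohort.n_users):
            users.append(replace(flat, subject_id=f"user{u}"))
            imposters.append([replace(flat, subject_id=f"imp{u}.{j}")
                              for j in range(cohort.n_imposters_per_user)])
        return users, imposters
    for u in range(cohort.n_users):
        users.append(synthgen.make_subject(
            f"user{u}", derive_seed(cohort.seed, 1, u)))
        imposters.append([
            synthgen.make_subject(f"imp{u}.{j}", derive_seed(cohort.seed, 2, u, j))
            for j in range(cohort.n_imposters_per_user)])
    return users, imposters


def train_user_system(user_id: str,
                      user_epochs: EpochSet,
                      imposter_epochs: list[EpochSet],
                      user_blink_vectors: np.ndarray,
                      imposter_blink_vectors: np.ndarray,
                      *,
                      test_fraction: float = 0.1,
                      fusion_order: int = 2,
                      smote_k: int = 5,
                      cnn_epochs: int = 500,
                      nn_epochs: int = 2000,
                      seed: int = 0):
    """Closed-set enrolment from preprocessed data.

    Selects channels/times from the user's self vs. non-self contrast,
    builds sparse ERP maps (user self-face epochs and each imposter's
    epochs at the same self-face onsets, adjacent trials averaged), balances
    the user class with SMOTE to the pooled imposter count, splits per
    class, trains both scorers, fits the fusion on training scores and
    evaluates the held-out scores. Returns ``(mask, cnn, nn, fusion,
    UserResult)``.
    """
    rng = np.random.default_rng(derive_seed(seed, 3))

    user_vecs = np.asarray(user_blink_vectors)
    imp_vecs = np.asarray(imposter_blink_vectors)

    # Per-class train/test splits on *original* samples, drawn before any
    # fitting. Held-out user trials are excluded from the discriminability
    # map as well: electrode/time selection is part of the trained system,
    # and letting it see the test trials' noise biases the evaluation. The
    # minority (user) training portion is then SMOTE-balanced up to the
    # pooled imposter training count; held-out samples are never synthetic.
    # With 100 user originals, 15 imposters and a 10% split this reproduces
    # the canonical 1350-train / 150-test arithmetic exactly (90*15 = 1350).
    is_self = np.array([l == "self" for l in user_epochs.labels])
    self_idx = np.nonzero(is_self)[0]
    n_avg = self_idx.size // 2
    um_tr, um_te = _split(n_avg, test_fraction, rng)
    held_out = np.zeros(user_epochs.n_trials, dtype=bool)
    for k in um_te:
        held_out[self_idx[2 * k]] = True
        held_out[self_idx[2 * k + 1]] = True
    mask = select_channels_times(
        pointwise_biserial(user_epochs.subset(~held_out)))

    user_maps = _self_maps(user_epochs, mask)
    imp_maps = np.concatenate([_self_maps(ep, mask)
                               for ep in imposter_epochs])

    mag = max(len(imposter_epochs) - 1, 0)
    im_tr, im_te = _split(len(imp_maps), test_fraction, rng)
    uv_tr, uv_te = _split(len(user_vecs), test_fraction, rng)
    iv_tr, iv_te = _split(len(imp_vecs), test_fraction, rng)

    flat = user_maps[um_tr].reshape(um_tr.size, -1)
    train_maps_user = smote_oversample(flat, SmoteConfig(
        k_neighbors=smote_k, magnification=mag,
        seed=derive_seed(seed, 6))).reshape(-1, *user_maps.shape[1:])
    train_vecs_user = smote_oversample(user_vecs[uv_tr], SmoteConfig(
        k_neighbors=smote_k, magnification=mag, seed=derive_seed(seed, 9)))

    cnn = train_cnn(
        np.concatenate([train_maps_user, imp_maps[im_tr]]),
        np.r_[np.ones(len(train_maps_user)), np.zeros(im_tr.size)],
        CnnSpec(epochs=cnn_epochs, seed=derive_seed(seed, 10)))
    nn = train_nn(
        np.concatenate([train_vecs_user, imp_vecs[iv_tr]]),
        np.r_[np.ones(len(train_vecs_user)), np.zeros(iv_tr.size)],
        NnSpec(epochs=nn_epochs, seed=derive_seed(seed, 11)))

    # fusion fitted on training scores
    tr_user = _paired(cnn.score_batch(train_maps_user),
                      nn.score_batch(train_vecs_user), rng)
    tr_imp = _paired(cnn.score_batch(imp_maps[im_tr]),
                     nn.score_batch(imp_vecs[iv_tr]), rng)
    design = build_design(np.vstack([tr_user, tr_imp]),
                          M=fusion_order,
                          labels=np.r_[np.ones(len(tr_user)),
                                       np.zeros(len(tr_imp))])
    fusion = fit_fusion(design)

    # held-out evaluation; both classes trimmed to equal attempt counts so
    # accuracy is interpretable against the 50% chance level
    te_user = _paired(cnn.score_batch(user_maps[um_te]),
                      nn.score_batch(user_vecs[uv_te]), rng)
    te_imp = _paired(cnn.score_batch(imp_maps[im_te]),
                     nn.score_batch(imp_vecs[iv_te]), rng)
    k = min(len(te_user), len(te_imp))
    te_user, te_imp = te_user[:k], te_imp[:k]
    s = np.vstack([te_user, te_imp])
    y = np.r_[np.ones(len(te_user)), np.zeros(len(te_imp))]
    fused_scores = fuse_batch(fusion, s)
    eeg_scores = s[:, 0]

    result = UserResult(
        user_id=user_id,
        eeg=compute_metrics(eeg_scores >= 0.5, y),
        fused=compute_metrics([decide(fusion, v) for v in fused_scores], y),
        auc_eeg=auc(eeg_scores, y),
        auc_fused=auc(fused_scores, y))
    return mask, cnn, nn, fusion, result


def _enroll_user(user: synthgen.SubjectProfile,
                 imposters: list[synthgen.SubjectProfile],
                 cohort: CohortSpec, u: int) -> tuple[UserModel, UserResult]:
    """Generate one user's cohort data and run the enrolment pipeline."""
    user_epochs = _session_epochs(user, cohort, derive_seed(cohort.seed, 4, u))
    imp_epochs = [
        _session_epochs(user, cohort, derive_seed(cohort.seed, 5, u, j),
                        viewer=imp)
        for j, imp in enumerate(imposters)]
    user_vecs = _blink_vectors(user, cohort, cohort.n_blinks,
                               derive_seed(cohort.seed, 7, u))
    imp_vecs = np.concatenate([
        _blink_vectors(imp, cohort, cohort.n_blinks,
                       derive_seed(cohort.seed, 8, u, j))
        for j, imp in enumerate(imposters)])

    mask, cnn, nn, fusion, result = train_user_system(
        user.subject_id, user_epochs, imp_epochs, user_vecs, imp_vecs,
        test_fraction=cohort.test_fraction,
        fusion_order=cohort.fusion_order, smote_k=cohort.smote_k,
        cnn_epochs=cohort.cnn_epochs, nn_epochs=cohort.nn_epochs,
        seed=derive_seed(cohort.seed, 12, u))
    model = UserModel(user_id=user.subject_id, profile=user, mask=mask,
                      cnn=cnn, nn=nn, fusion=fusion)
    return model, result


# --------------------------------------------------------------- protocols


def run_closed_set(cohort: CohortSpec):
    """Enrol and evaluate every user; returns (results, models)."""
    users, imposters = _cohort_profiles(cohort)
    results, models = [], {}
    for u, (user, imps) in enumerate(zip(users, imposters)):
        model, res = _enroll_user(user, imps, cohort, u)
        results.append(res)
        models[user.subject_id] = model
    return results, models


def _login_scores(model: UserModel, maps: np.ndarray, vecs: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    s = _paired(model.cnn.score_batch(maps), model.nn.score_batch(vecs), rng)
    return fuse_batch(model.fusion, s), s[:, 0]


def run_open_set(cohort: CohortSpec, models: dict[str, UserModel]):
    """Score unseen imposters against each user's frozen models (FAR only).

    Returns per-user dicts with fused and EEG-only metrics.
    """
    if not models:
        raise ValueError("no trained models")
    if cohort.n_open_imposters < 1:
        raise ValueError("need at least one unseen imposter")
    results = []
    for u, (uid, model) in enumerate(models.items()):
        rng = np.random.default_rng(derive_seed(cohort.seed, 20, u))
        fused_all, eeg_all = [], []
        for j in range(cohort.n_open_imposters):
            intruder = synthgen.make_subject(
                f"open{u}.{j}", derive_seed(cohort.seed, 21, u, j))
            if cohort.null_effect:
                intruder = replace(
                    model.profile, subject_id=f"open{u}.{j}",
                    erp_amp_self=model.profile.erp_amp_nonself.copy())
            ep = _session_epochs(model.profile, cohort,
                                 derive_seed(cohort.seed, 22, u, j),
                                 viewer=intruder)
            maps = _self_maps(ep, model.mask)
            vecs = _blink_vectors(intruder, cohort, cohort.n_blinks,
                                  derive_seed(cohort.seed, 23, u, j))
            fused, eeg = _login_scores(model, maps, vecs, rng)
            fused_all.append(fused)
            eeg_all.append(eeg)
        fused_all = np.concatenate(fused_all)
        eeg_all = np.concatenate(eeg_all)
        y = np.zeros(fused_all.size)
        results.append({
            "user_id": uid,
            "fused": compute_metrics(
                fused_all >= model.fusion.threshold, y),
            "eeg": compute_metrics(eeg_all >= 0.5, y)})
    return results


def run_permanence(cohort: CohortSpec, models: dict[str, UserModel],
                   drift_amp: float | None = None,
                   drift_latency_ms: float | None = None):
    """Score each user's later-session logins against the frozen models
    (FRR only). Drift magnitudes default to the cohort's settings."""
    if not models:
        raise ValueError("no trained models")
    amp = cohort.drift_amp if drift_amp is None else drift_amp
    lat = cohort.drift_latency_ms if drift_latency_ms is None else \
        drift_latency_ms
    n_self_needed = 2 * cohort.n_login
    n_trials = int(math.ceil(n_self_needed / cohort.self_ratio))
    results = []
    for u, (uid, model) in enumerate(models.items()):
        rng = np.random.default_rng(derive_seed(cohort.seed, 30, u))
        drifted = synthgen.drift_subject(
            model.profile, amp, lat, derive_seed(cohort.seed, 31, u))
        ep = _session_epochs(drifted, cohort,
                             derive_seed(cohort.seed, 32, u),
                             n_trials=n_trials)
        maps = _self_maps(ep, model.mask)[:cohort.n_login]
        vecs = _blink_vectors(drifted, cohort, cohort.n_login,
                              derive_seed(cohort.seed, 33, u))
        fused, eeg = _login_scores(model, maps, vecs, rng)
        y = np.ones(fused.size)
        results.append({
            "user_id": uid,
            "fused": compute_metrics(fused >= model.fusion.threshold, y),
            "eeg": compute_metrics(eeg >= 0.5, y)})
    return results


# ----------------------------------------------------------------- tables


def closed_set_table(results: list[UserResult]) -> pd.DataFrame:
    """Per-user ACC/FAR/FRR (percent) for both systems, plus mean and std."""
    rows = []
    for r in results:
        rows.append({
            "user": r.user_id,
            "acc_eeg": 100 * r.eeg.acc, "acc_fused": 100 * r.fused.acc,
            "far_eeg": 100 * r.eeg.far, "far_fused": 100 * r.fused.far,
            "frr_eeg": 100 * r.eeg.frr, "frr_fused": 100 * r.fused.frr,
            "auc_eeg": r.auc_eeg, "auc_fused": r.auc_fused})
    df = pd.DataFrame(rows).set_index("user")
    df.loc["mean"] = df.mean()
    df.loc["std"] = df.iloc[:-1].std()
    return df


def rate_table(results: list[dict], which: str) -> pd.DataFrame:
    """Open-set FAR or permanence FRR table (percent) per user."""
    rows = [{"user": r["user_id"],
             f"{which}_eeg": 100 * getattr(r["eeg"], which),
             f"{which}_fused": 100 * getattr(r["fused"], which)}
            for r in results]
    df = pd.DataFrame(rows).set_index("user")
    df.loc["mean"] = df.mean()
    df.loc["std"] = df.iloc[:-1].std()
    return df
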