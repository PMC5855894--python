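"""ERP discriminability map, channel/time selection, and sparse feature maps.

The discriminability of each electrode i and post-stimulus sample point n is
the point-biserial correlation between single-trial voltage and the
self/non-self stimulus label:

    P_i(n) = sqrt(N1*N2) / (N1 + N2) * (M_i^SF(n) - M_i^NSF(n)) / S(n)

where M_i^SF and M_i^NSF are the class means, S(n) the pooled (population)
standard deviation over all trials of both classes, and N1, N2 the class
trial counts. With this prefactor P_i(n) equals the Pearson correlation
between voltage and a 0/1 class indicator.

Per channel, the 200 sample points with the largest |P| are kept; channels
are ranked by the mean square of their selected P values and the top five
retained. Features are then built from self-face epochs only: the selected
samples of each selected channel are averaged in 20 non-overlapping windows
of 10 points, giving a 5 x 20 matrix per trial, expanded to a sparse 20 x 20
map (compact row c placed at expanded row 4c, zeros elsewhere) for the CNN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

logger = logging.getLogger("neuroauth")

N_SELECTED_CHANNELS = 5
N_SELECTED_POINTS = 200
N_WINDOWS = 20
WINDOW_WIDTH = 10


@dataclass
class DiscriminabilityMap:
    """Pointwise biserial coefficients plus the statistics behind them."""

    P: np.ndarray             # channels x post-stimulus points
    mean_self: np.ndarray     # same shape, uV
    mean_nonself: np.ndarray  # uV
    pooled_sd: np.ndarray     # uV


@dataclass
class SelectionMask:
    """Selected channels and, per channel, their selected time indices."""

    channels: np.ndarray        # (top_channels,) channel indices
    time_indices: np.ndarray    # (top_channels, top_points), ascending
    channel_scores: np.ndarray  # mean square of selected P per channel

    def __post_init__(self) -> None:
        for row in self.time_indices:
            if len(set(row.tolist())) != row.size:
                raise ValueError("selected time indices must be unique")


@dataclass
class ERPFeatureMap:
    """Window-averaged voltages: compact 5 x 20 and sparse 20 x 20 layouts."""

    compact: np.ndarray
    expanded: np.ndarray
    trial_id: int = 0


def pointwise_biserial(epochs: EpochSet) -> DiscriminabilityMap:
    """Compute P_i(n) on the post-stimulus samples of an epoch set.

    Requires at least two trials of each class. Points where the pooled SD
    is zero get P = 0 with a logged warning.
    """
    labels = np.array([l == "self" for l in epochs.labels])
    n1, n2 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two trials per class "
                         f"(got N1={n1}, N2={n2})")
    x = epochs.post_stimulus  # trials x channels x points
    m_self = x[labels].mean(axis=0)
    m_nonself = x[~labels].mean(axis=0)
    sd = x.std(axis=0)        # population SD over all trials, both classes
    pref = np.sqrt(n1 * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = pref * (m_self - m_nonself) / sd
    zero = sd == 0
    if zero.any():
        logger.warning("pointwise_biserial: %d points with zero pooled SD "
                       "set to 0", int(zero.sum()))
        P[zero] = 0.0
    return DiscriminabilityMap(P=P, mean_self=m_self, mean_nonself=m_nonself,
                               pooled_sd=sd)


def select_channels_times(dmap: DiscriminabilityMap,
                          top_points: int = N_SELECTED_POINTS,
                          top_channels: int = N_SELECTED_CHANNELS,
                          ) -> SelectionMask:
    """Rank points by |P| within channel, channels by mean selected P^2.

    Ties break toward the lower index in both rankings; selected indices are
    returned in ascending time order per channel.
    """
    P = dmap.P
    n_ch, n_pts = P.shape
    if top_points > n_pts or top_channels > n_ch:
        raise ValueError("selection sizes exceed map dimensions")
    # stable sort on (-|P|, index): lexsort's last key dominates
    idx = np.empty((n_ch, top_points), dtype=int)
    scores = np.empty(n_ch)
    for i in range(n_ch):
        order = np.lexsort((np.arange(n_pts), -np.abs(P[i])))
        chosen = np.sort(order[:top_points])
        idx[i] = chosen
        scores[i] = float(np.mean(P[i, chosen] ** 2))
    ch_order = np.lexsort((np.arange(n_ch), -scores))
    channels = np.sort(ch_order[:top_channels])
    return SelectionMask(channels=channels, time_indices=idx[channels],
                         channel_scores=scores[channels])


def average_adjacent_trials(epochs: EpochSet, group: int = 2) -> EpochSet:
    """Average non-overlapping runs of ``group`` consecutive trials.

    Intended for the self-face epochs of one subject in chronological order
    (200 single trials -> 100 averaged trials). An odd remainder is dropped
    and logged. All input trials must share one label.
    """
    if epochs.n_trials < group:
        raise ValueError(f"need at least {group} trials to average")
    if len(set(epochs.labels)) > 1:
        raise ValueError("adjacent-trial averaging expects a single class")
    n = (epochs.n_trials // group) * group
    if n != epochs.n_trials:
        logger.info("average_adjacent_trials: dropping %d trailing trials",
                    epochs.n_trials - n)
    x = epochs.data[:n]
    out = x.reshape(n // group, group, *x.shape[1:]).mean(axis=1)
    labels = [epochs.labels[0]] * (n // group)
    return EpochSet(out, epochs.rate, labels, epochs.baseline_samples)


def expand_sparse(compact: np.ndarray, size: int = 20) -> np.ndarray:
    """Place compact row c at expanded row ``size // rows * c``, zero-fill.

    For 5 x 20 input the rows land at 0, 4, 8, 12, 16 of a 20 x 20 map.
    """
    rows, cols = compact.shape
    if cols != size or size % rows:
        raise ValueError("compact shape incompatible with sparse expansion")
    out = np.zeros((size, size))
    out[np.arange(rows) * (size // rows)] = compact
    return out


def build_feature_map(epoch: np.ndarray, mask: SelectionMask,
                      n_windows: int = N_WINDOWS,
                      window_width: int = WINDOW_WIDTH,
                      baseline_samples: int = 120,
                      trial_id: int = 0) -> ERPFeatureMap:
    """Window-average one epoch's selected samples into a sparse 20 x 20 map.

    ``epoch`` is one trial (channels x samples including baseline). Per
    selected channel its selected post-stimulus samples, in ascending time
    order, are partitioned into ``n_windows`` consecutive blocks of
    ``window_width`` and averaged.
    """
    if mask.time_indices.shape[1] != n_windows * window_width:
        raise ValueError("mask size does not match n_windows * window_width")
    post = epoch[:, baseline_samples:]
    compact = np.empty((mask.channels.size, n_windows))
    for r, (ch, tidx) in enumerate(zip(mask.channels, mask.time_indices)):
        vals = post[ch, tidx]
        compact[r] = vals.reshape(n_windows, window_width).mean(axis=1)
    return ERPFeatureMap(compact=compact, expanded=expand_sparse(compact),
                         trial_id=trial_id)


def feature_maps_for_epochs(epochs: EpochSet, mask: SelectionMask,
                            ) -> list[ERPFeatureMap]:
    """Build one feature map per trial (self-face or averaged epochs)."""
    return [build_feature_map(epochs.data[k], mask,
                              baseline_samples=epochs.baseline_samples,
                              trial_id=k)
            for k in range(epochs.n_trials)]
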