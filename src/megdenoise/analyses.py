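"""Evoked-response validation analyses for original and denoised MEG.

Three classical reading-related phenomena serve as yardsticks for whether a
denoising transformation preserved stimulus-driven signal:

* **Word-length power gradation** -- early visual power (squared signal over
  occipital gradiometers) grows with the number of letters on screen, so the
  per-length mean power profiles should stack in length order.
* **N400m vs surprisal** -- the N400m, the MEG counterpart of the N400
  event-related response, is a 300-500 ms post-onset deflection in temporal /
  parietal sensors whose magnitude grows with word surprisal
  (-log p(word | context)).  Its correlation with surprisal should survive --
  and sharpen -- after denoising.
* **Encoding models** -- ridge regressions predicting each sensor-time value
  from word length, log word frequency and surprisal; held-out prediction
  correlation should be at least as high on denoised data, and the drop from
  removing surprisal isolates the variance uniquely explained by surprisal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats

from ._ridge import DEFAULT_LAMBDAS, _stats
from .data_model import MultiSubjectDataset
from .folds import FoldScheme, inner_splits, train_test_split

logger = logging.getLogger("megdenoise")


# ---------------------------------------------------------------------------
# Word-length power gradation
# ---------------------------------------------------------------------------

@dataclass
class PowerProfile:
    """Mean squared signal per word-length group over time."""

    lengths: np.ndarray  # sorted distinct word lengths
    profiles: np.ndarray  # len(lengths) x n_time
    group_sizes: np.ndarray


def power_by_word_length(
    tensors: np.ndarray | Sequence[np.ndarray],
    word_lengths: Sequence[int],
    sensor_subset: Sequence[int] | None = None,
    event_mask: np.ndarray | None = None,
) -> PowerProfile:
    """Signal power over time, grouped by word length.

    The data is squared, averaged over the selected sensors, averaged over
    the events of each word-length group, and (when several subject tensors
    are given) averaged over subjects.  ``event_mask`` restricts to e.g.
    test-usable events of a denoised dataset.
    """
    if isinstance(tensors, np.ndarray):
        tensors = [tensors]
    word_lengths = np.asarray(word_lengths, int)
    n_events, n_sensors, n_time = tensors[0].shape
    if len(word_lengths) != n_events:
        raise ValueError("word_lengths must have one entry per event")
    sensor_subset = (
        np.arange(n_sensors) if sensor_subset is None else np.asarray(sensor_subset, int)
    )
    if sensor_subset.size == 0:
        raise ValueError("empty sensor selection")
    mask = np.ones(n_events, bool) if event_mask is None else np.asarray(event_mask, bool)
    # square -> mean over sensors -> mean over subjects; grouping afterwards
    power = np.mean(
        [np.square(t[:, sensor_subset, :]).mean(axis=1) for t in tensors], axis=0
    )
    lengths = np.unique(word_lengths[mask])
    profiles = np.empty((len(lengths), n_time))
    sizes = np.empty(len(lengths), int)
    for i, ln in enumerate(lengths):
        grp = mask & (word_lengths == ln)
        sizes[i] = grp.sum()
        profiles[i] = power[grp].mean(axis=0)
    return PowerProfile(lengths, profiles, sizes)


# ---------------------------------------------------------------------------
# N400m estimation and surprisal correlation
# ---------------------------------------------------------------------------

@dataclass
class N400mSeries:
    """Per-event scalar N400m magnitude for one subject and region."""

    values: np.ndarray
    region: str | Sequence[int]
    window_ms: tuple[float, float]
    use_abs: bool = False


def estimate_n400m(
    dataset: MultiSubjectDataset,
    subject: str,
    region: str | Sequence[int],
    window_ms: tuple[float, float] = (300.0, 500.0),
    use_abs: bool = False,
) -> N400mSeries:
    """Per-event N400m magnitude: window mean per region sensor, max across them.

    ``region`` is a region label (resolved through the sensor table) or an
    explicit sequence of sensor indices.  The temporal mean is taken over the
    bins inside ``window_ms`` (bin-start convention, half-open window), then
    the maximum across the region's sensors is taken on signed values by
    default; ``use_abs`` pools absolute values instead, since field polarity
    is sensor-dependent.
    """
    if isinstance(region, str):
        sensor_idx = dataset.sensors.indices(region=region)
    else:
        sensor_idx = np.asarray(region, int)
    if sensor_idx.size == 0:
        raise ValueError(f"region {region!r} contains no sensors")
    bins = dataset.time_window(*window_ms)
    if bins.size == 0:
        raise ValueError(f"window {window_ms} ms contains no complete time bin")
    windowed = dataset.data[subject][:, sensor_idx][:, :, bins].mean(axis=2)
    if use_abs:
        windowed = np.abs(windowed)
    return N400mSeries(windowed.max(axis=1), region, tuple(window_ms), use_abs)


def surprisal_correlation(
    series: N400mSeries | np.ndarray,
    surprisal: np.ndarray,
    n_perms: int = 1000,
    seed: int = 0,
    event_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of the N400m series with word surprisal.

    Returns ``(r, p)`` where ``p`` is a one-sided (greater) permutation
    p-value with the add-one estimator: surprisal rows are permuted, which is
    exchangeable under the null of no event-level association.  Events where
    the series is NaN (edge-dropped events of denoised data) are excluded.
    """
    values = series.values if isinstance(series, N400mSeries) else np.asarray(series, float)
    surprisal = np.asarray(surprisal, float)
    keep = ~np.isnan(values)
    if event_mask is not None:
        keep &= np.asarray(event_mask, bool)
    x, y = values[keep], surprisal[keep]
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined: zero variance in series or surprisal")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    count = 0
    for _ in range(n_perms):
        rp = float(xc @ yc[rng.permutation(n)]) / n
        if rp >= r:
            count += 1
    return r, (1 + count) / (1 + n_perms)


# ---------------------------------------------------------------------------
# Encoding models
# ---------------------------------------------------------------------------

@dataclass
class EncodingResult:
    """Held-out encoding performance per (sensor, time bin).

    ``r`` is the held-out Pearson correlation per (sensor, bin), computed
    within each test fold and averaged over folds (within-fold evaluation
    keeps per-fold mean offsets from contaminating the correlation);
    ``r_per_fold`` keeps the per-fold values for fold-level inference.
    """

    r: np.ndarray  # (n_sensors, n_time)
    r_per_fold: np.ndarray  # (k, n_sensors, n_time)
    feature_names: list[str]
    penalties: np.ndarray | None = None

    def by_time(self) -> np.ndarray:
        """Correlation profile over time, averaged across sensors."""
        return self.r.mean(axis=0)


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    denom = np.sqrt((am**2).sum(axis=0) * (bm**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (am * bm).sum(axis=0) / denom, 0.0)


def fit_encoding(
    features: np.ndarray,
    tensor: np.ndarray,
    scheme: FoldScheme,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDAS,
    n_inner: int = 3,
    feature_names: Sequence[str] = ("word_length", "log_frequency", "surprisal"),
    event_mask: np.ndarray | None = None,
) -> EncodingResult:
    """Per-(sensor, bin) ridge from stimulus features to the MEG signal.

    One ridge map per response column, penalty chosen per column by inner
    contiguous-block CV; reported as held-out Pearson correlation per column.
    ``event_mask`` restricts training/evaluation to defined events (denoised
    data is NaN at edge-dropped events).
    """
    features = np.asarray(features, float)
    n_events, n_sensors, n_time = tensor.shape
    Y = tensor.reshape(n_events, n_sensors * n_time)
    if len(features) != n_events:
        raise ValueError("features must have one row per event")
    if np.isnan(features).any():
        raise ValueError("NaNs in features")
    usable = ~np.isnan(Y).any(axis=1)
    if event_mask is not None:
        usable &= np.asarray(event_mask, bool)
    lambdas = np.sort(np.asarray(lambda_grid, float))
    preds = np.full_like(Y, np.nan)
    r_per_fold = np.full((scheme.k, Y.shape[1]), np.nan)
    lams = np.empty(Y.shape[1])
    for j in range(scheme.k):
        train, test = train_test_split(scheme, j)
        train = train[usable[train]]
        test = test[usable[test]]
        if len(train) == 0 or len(test) == 0:
            raise ValueError(f"fold {j}: no usable events")
        # per-column penalty via accumulated inner-CV MSE (features are tiny)
        mse = np.zeros((len(lambdas), Y.shape[1]))
        for tr, val in inner_splits(train, n_inner):
            tr, val = tr[usable[tr]], val[usable[val]]
            xm, xs = _stats(features[tr])
            ym, ys = _stats(Y[tr])
            Xtr = (features[tr] - xm) / xs
            w, V = np.linalg.eigh(Xtr.T @ Xtr)
            A = V.T @ (Xtr.T @ ((Y[tr] - ym) / ys))
            XvalV = ((features[val] - xm) / xs) @ V
            Yval = (Y[val] - ym) / ys
            for li, lam in enumerate(lambdas):
                mse[li] += (((XvalV / (w + lam)) @ A - Yval) ** 2).mean(axis=0)
        pick = len(lambdas) - 1 - np.argmin(mse[::-1], axis=0)  # ties -> largest penalty
        lams = lambdas[pick]
        xm, xs = _stats(features[train])
        ym, ys = _stats(Y[train])
        Xtr = (features[train] - xm) / xs
        w, V = np.linalg.eigh(Xtr.T @ Xtr)
        A = V.T @ (Xtr.T @ ((Y[train] - ym) / ys))
        XtestV = ((features[test] - xm) / xs) @ V
        P = np.empty((len(test), Y.shape[1]))
        for li, lam in enumerate(lambdas):
            cols = pick == li
            if cols.any():
                P[:, cols] = (XtestV / (w + lam)) @ A[:, cols]
        P = P * ys + ym
        preds[test] = P
        r_per_fold[j] = _corr_columns(P, Y[test])
    r = r_per_fold.mean(axis=0)
    return EncodingResult(
        r.reshape(n_sensors, n_time),
        r_per_fold.reshape(scheme.k, n_sensors, n_time),
        list(feature_names),
        lams,
    )


def unique_variance_surprisal(
    full: EncodingResult,
    reduced: EncodingResult,
    n_perms: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Per-bin drop in encoding correlation when surprisal is removed.

    The difference of sensor-averaged held-out correlations (full minus
    reduced) per time bin estimates the activity uniquely predicted by
    surprisal.  Significance per bin is a one-sided sign-flip test over the
    per-fold differences: all ``2^k`` sign patterns are enumerated when that
    is fewer than ``n_perms``, otherwise patterns are sampled.  With few
    folds the attainable p-value is floored at ``2^-k``.
    """
    if full.r_per_fold.shape != reduced.r_per_fold.shape:
        raise ValueError("full and reduced results have different shapes")
    diff_by_time = full.by_time() - reduced.by_time()
    fold_diff = (full.r_per_fold - reduced.r_per_fold).mean(axis=1)  # k x n_time
    k, n_time = fold_diff.shape
    obs = fold_diff.mean(axis=0)
    if 2**k <= n_perms:
        signs = np.array(list(product((-1.0, 1.0), repeat=k)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perms, k))
    null = signs @ fold_diff / k  # (n_patterns, n_time)
    p = (null >= obs).mean(axis=0) if 2**k <= n_perms else (
        1 + (null >= obs).sum(axis=0)
    ) / (1 + len(signs))
    peak = int(np.argmax(diff_by_time))
    return {
        "difference_by_time": diff_by_time,
        "p_by_time": p,
        "significant": p <= alpha,
        "peak_bin": peak,
    }
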