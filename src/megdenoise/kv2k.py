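"""The Kv(2K) classification statistic for evaluating predictions at low SNR.

Given a prediction matrix and a row-aligned gold matrix, the 1v2 variant
repeatedly draws one gold row ``x1`` together with its matched prediction
``xh1`` and one mismatched prediction ``xh2`` and scores 1.0 when
``E(x1, xh1) < E(x1, xh2)`` (Euclidean distance).  The Kv(2K) generalisation
draws K such pairs and compares the *summed* matched distance against the
summed mismatched distance, which raises the power of the test when the
per-row signal is weak: chance level stays at 50% but a small consistent
advantage of the matched predictions accumulates over the K terms.

Negative (mismatched) rows can be constrained to share an attribute with
their positive row -- e.g. drawing only same-word-length negatives removes
word length, and anything correlated with it such as saccade artifacts, as a
shortcut for the classifier.

Conventions chosen here: exact distance ties score 0.5 (unbiased under the
null); within one comparison the K positives and K negatives are 2K distinct
rows (sampling without replacement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("megdenoise")

DEFAULT_VARIANTS = tuple(range(1, 21))


@dataclass
class KvConfig:
    """Settings for the Kv(2K) statistic.

    K: matched/mismatched pairs per comparison (K=20 gives the 20v40 variant).
    n_draws: random comparisons averaged per accuracy estimate.
    match_attribute: if True, each negative must share its positive's
        attribute value (supplied separately per row, e.g. word length).
    distance: metric name passed to scipy cdist, or a callable
        ``(gold, pred) -> distance matrix``.
    """

    K: int = 20
    n_draws: int = 1000
    match_attribute: bool = False
    distance: str | Callable = "euclidean"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class EvalReport:
    """Accuracy per Kv(2K) variant, with optional permutation p-values."""

    variants: list[int]
    accuracy: np.ndarray
    p_values: np.ndarray | None = None
    label: str = ""
    config: KvConfig | None = None

    def to_frame(self):
        import pandas as pd

        cols = {"K": self.variants, "accuracy": self.accuracy}
        if self.p_values is not None:
            cols["p_value"] = self.p_values
        return pd.DataFrame(cols)


def _distance_matrix(pred: np.ndarray, gold: np.ndarray, config: KvConfig) -> np.ndarray:
    pred = np.asarray(pred, float)
    gold = np.asarray(gold, float)
    if pred.shape != gold.shape:
        raise ValueError(f"pred {pred.shape} and gold {gold.shape} must be row-aligned")
    if np.isnan(pred).any() or np.isnan(gold).any():
        raise ValueError("NaNs in prediction or gold matrix")
    if callable(config.distance):
        return np.asarray(config.distance(gold, pred), float)
    return cdist(gold, pred, metric=config.distance)


def _score(matched: np.ndarray, mismatched: np.ndarray) -> np.ndarray:
    out = np.where(matched < mismatched, 1.0, 0.0)
    out[matched == mismatched] = 0.5
    return out


def kv2k_accuracy(
    pred: np.ndarray,
    gold: np.ndarray,
    config: KvConfig,
    attributes: Sequence | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean Kv(2K) accuracy over ``config.n_draws`` sampled comparisons.

    ``pred`` and ``gold`` are row-aligned ``n x d`` matrices.  When
    ``config.match_attribute`` is set, ``attributes`` gives one hashable value
    per row and negatives are drawn only from rows sharing their positive's
    value; rows with no same-attribute partner are excluded from the positive
    pool (logged once).
    """
    D = _distance_matrix(pred, gold, config)
    n = D.shape[0]
    K = config.K
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if not config.match_attribute:
        if n < 2 * K:
            raise ValueError(f"need at least 2K={2 * K} rows, have {n}")
        # vectorised sampling: per draw, 2K distinct rows; first K matched
        keys = rng.random((config.n_draws, n))
        idx = np.argpartition(keys, 2 * K - 1, axis=1)[:, : 2 * K]
        idx = rng.permuted(idx, axis=1)  # uniform positive/negative assignment
        pos, neg = idx[:, :K], idx[:, K:]
        matched = D[pos, pos].sum(axis=1)
        mismatched = D[pos, neg].sum(axis=1)
        return float(_score(matched, mismatched).mean())

    if attributes is None:
        raise ValueError("match_attribute=True requires per-row attributes")
    attributes = np.asarray(attributes)
    if len(attributes) != n:
        raise ValueError("attributes length must equal the number of rows")
    groups: dict = {}
    for i, a in enumerate(attributes):
        groups.setdefault(a, []).append(i)
    eligible = np.array([i for i, a in enumerate(attributes) if len(groups[a]) >= 2], int)
    n_skipped = n - len(eligible)
    if n_skipped:
        logger.warning(
            "kv2k: %d event(s) have no same-attribute negative and are skipped", n_skipped
        )
    if len(eligible) < K:
        raise ValueError("not enough events with a same-attribute negative for K pairs")
    group_arrays = {a: np.asarray(v) for a, v in groups.items()}

    total = 0.0
    for _ in range(config.n_draws):
        for _attempt in range(20):
            pos = rng.choice(eligible, size=K, replace=False)
            used = set(pos.tolist())
            neg = np.empty(K, int)
            ok = True
            for t, p in enumerate(pos):
                cand = group_arrays[attributes[p]]
                cand = cand[~np.isin(cand, list(used))]
                if len(cand) == 0:
                    ok = False
                    break
                neg[t] = rng.choice(cand)
                used.add(int(neg[t]))
            if ok:
                break
        else:
            raise RuntimeError("could not draw a constrained comparison after 20 attempts")
        total += _score(D[pos, pos].sum(), D[pos, neg].sum())
    return float(total / config.n_draws)


def exhaustive_oracle(
    pred: np.ndarray,
    gold: np.ndarray,
    config: KvConfig | None = None,
    attributes: Sequence | None = None,
) -> float:
    """Exact 1v2 accuracy by enumerating every ordered (positive, negative) pair.

    This is the population value that sampled :func:`kv2k_accuracy` with K=1
    converges to as ``n_draws`` grows.  Intended for small ``n``.
    """
    config = config or KvConfig(K=1, n_draws=1)
    if config.K != 1:
        raise ValueError("the exhaustive oracle is defined for K=1")
    D = _distance_matrix(pred, gold, config)
    n = D.shape[0]
    diag = np.diag(D)
    scores = []
    for i in range(n):
        if config.match_attribute:
            cand = np.flatnonzero(np.asarray(attributes) == np.asarray(attributes)[i])
            cand = cand[cand != i]
        else:
            cand = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if len(cand) == 0:
            continue
        scores.append(_score(np.full(len(cand), diag[i]), D[i, cand]))
    if not scores:
        raise ValueError("no admissible (positive, negative) pair exists")
    return float(np.concatenate(scores).mean())


def permutation_test(
    pred: np.ndarray,
    gold: np.ndarray,
    config: KvConfig,
    n_perms: int = 1000,
    attributes: Sequence | None = None,
) -> tuple[float, float]:
    """Permutation p-value for the Kv(2K) accuracy.

    Row correspondence is broken by permuting the prediction rows; the add-one
    estimator ``p = (1 + #{perm >= observed}) / (1 + n_perms)`` avoids zero
    p-values.  Returns ``(observed accuracy, p)``.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    rng = np.random.default_rng(config.seed)
    observed = kv2k_accuracy(pred, gold, config, attributes, rng=rng)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(len(gold))
        acc = kv2k_accuracy(np.asarray(pred)[perm], gold, config, attributes, rng=rng)
        if acc >= observed:
            count += 1
    return observed, (1 + count) / (1 + n_perms)


def kv_curve(
    pred: np.ndarray,
    gold: np.ndarray,
    config: KvConfig,
    variants: Sequence[int] = DEFAULT_VARIANTS,
    attributes: Sequence | None = None,
    n_perms: int | None = None,
    label: str = "",
) -> EvalReport:
    """Accuracy for a ladder of Kv(2K) variants (1v2, 2v4, ... 20v40).

    Each variant reuses the seed in ``config`` so that curves computed for
    different prediction matrices with the same config are paired draws.
    """
    accs, ps = [], []
    for K in variants:
        cfg = replace(config, K=K)
        if n_perms:
            a, p = permutation_test(pred, gold, cfg, n_perms, attributes)
            accs.append(a)
            ps.append(p)
        else:
            accs.append(kv2k_accuracy(pred, gold, cfg, attributes))
    return EvalReport(
        list(variants),
        np.asarray(accs),
        np.asarray(ps) if n_perms else None,
        label=label,
        config=config,
    )
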