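"""Semantic decoding: ridge maps from brain data to word-embedding space.

A decoder maps each event's flattened brain vector (original or denoised) to
the word's semantic embedding, fit per outer fold with inner-CV penalty
selection, and is scored on held-out events with the ladder of Kv(2K)
variants.  Comparing curves for original vs denoised inputs measures whether
the denoising transformation preserved (or enhanced) semantic information.
Length-matched negatives remove word length -- and confounds correlated with
it, like saccade magnitude -- as a decoding shortcut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._ridge import DEFAULT_LAMBDAS, RidgeDesign, fit_ridge_cv
from .folds import FoldScheme, train_test_split
from .kv2k import DEFAULT_VARIANTS, EvalReport, KvConfig, kv_curve

logger = logging.getLogger("megdenoise")


@dataclass
class DecodingResult:
    """Held-out embedding predictions and Kv(2K) accuracy curves."""

    predictions: np.ndarray  # n_events x D, NaN at events never tested
    test_usable: np.ndarray
    curve: EvalReport | None = None
    curve_length_matched: EvalReport | None = None
    penalties: dict | None = None
    label: str = ""


def fit_decoder(
    brain: np.ndarray,
    embeddings: np.ndarray,
    scheme: FoldScheme,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDAS,
    n_inner: int = 3,
    kv_config: KvConfig | None = None,
    variants: Sequence[int] = DEFAULT_VARIANTS,
    word_lengths: np.ndarray | None = None,
    label: str = "",
) -> DecodingResult:
    """Per-fold ridge decoding brain -> embeddings with held-out evaluation.

    ``brain`` is an ``n_events x d`` matrix (rows at non-test-usable events
    may be NaN, as produced by denoising; they are never used).  Curves are
    computed on the concatenated held-out predictions; if ``word_lengths`` is
    given, a second curve restricted to length-matched negatives is added.
    """
    brain = np.asarray(brain, float)
    embeddings = np.asarray(embeddings, float)
    if len(brain) != len(embeddings):
        raise ValueError("brain and embeddings must align on events")
    if np.isnan(embeddings).any():
        raise ValueError("NaNs in embeddings")
    n = len(brain)
    preds = np.full((n, embeddings.shape[1]), np.nan)
    penalties = {}
    for j in range(scheme.k):
        train, test = train_test_split(scheme, j)
        # denoised inputs are defined only at test-usable events
        train = train[~np.isnan(brain[train]).any(axis=1)]
        if len(train) == 0:
            raise ValueError(f"fold {j}: no usable training events")
        design = RidgeDesign(brain, train, n_inner)
        fit = fit_ridge_cv(design, embeddings, lambda_grid)
        penalties[j] = fit.lam
        preds[test] = fit.predict(brain[test])
    tested = ~np.isnan(preds).any(axis=1)
    kv_config = kv_config or KvConfig(seed=0)

    # accuracy per fold, then averaged over folds: comparisons never straddle
    # folds, so per-fold prediction offsets cannot masquerade as (anti)signal
    def fold_mean_curve(cfg: KvConfig, attrs=None) -> EvalReport:
        per_fold = []
        for j in range(scheme.k):
            sel = tested & (scheme.fold_id == j)
            if sel.sum() < 2 * max(variants):
                raise ValueError(f"fold {j}: too few tested events for K={max(variants)}")
            per_fold.append(
                kv_curve(
                    preds[sel], embeddings[sel], cfg, variants,
                    attributes=None if attrs is None else np.asarray(attrs)[sel],
                ).accuracy
            )
        return EvalReport(list(variants), np.mean(per_fold, axis=0), label=label, config=cfg)

    curve = fold_mean_curve(kv_config)
    curve_lm = None
    if word_lengths is not None:
        cfg = KvConfig(K=kv_config.K, n_draws=kv_config.n_draws, match_attribute=True,
                       distance=kv_config.distance, seed=kv_config.seed)
        curve_lm = fold_mean_curve(cfg, word_lengths)
        curve_lm.label = label + " (length-matched)"
    return DecodingResult(preds, tested, curve, curve_lm, penalties, label)


def compare_decoding(results: Sequence[DecodingResult], labels: Sequence[str] | None = None):
    """Side-by-side table of Kv(2K) decoding curves.

    No ordering between inputs is assumed; the table simply reports each
    curve (and the length-matched curve when present) per variant.
    """
    import pandas as pd

    labels = list(labels) if labels is not None else [r.label or f"model{i}" for i, r in enumerate(results)]
    if len(labels) != len(results):
        raise ValueError("labels must match results")
    frames = {}
    for lab, r in zip(labels, results):
        frames[lab] = pd.Series(r.curve.accuracy, index=r.curve.variants)
        if r.curve_length_matched is not None:
            frames[f"{lab} (length-matched)"] = pd.Series(
                r.curve_length_matched.accuracy, index=r.curve_length_matched.variants
            )
    table = pd.DataFrame(frames)
    table.index.name = "K"
    return table
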