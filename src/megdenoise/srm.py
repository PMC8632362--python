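"""Shared Response Model denoising with leave-one-subject-out reconstruction.

The SRM is a factor model: each subject's flattened data ``X_i``
(``n_events x d``) is a subject-specific linear image of one shared latent
response ``Z`` (``n_events x L``),

    X_i = Z W_i + eps_i,      with  W_i W_i' = I_L,

where the row-orthonormal basis ``W_i`` (``L x d``) maps the latent space
into subject ``i``'s sensor-time space.  Bases and shared response minimise
the summed squared Frobenius reconstruction error by block-coordinate
descent: given ``Z``, each ``W_i`` update is an orthogonal Procrustes
problem; given the bases, ``Z`` is the all-subject average of the projections
``X_i W_i'``.  The objective is non-increasing at every step.

At test time the denoiser is deliberately cross-subject: the latent response
for subject ``i``'s test fold is averaged over the *other* subjects'
projections, so a subject's denoised estimate never sees its own test data:

    Zhat_i = 1/(N-1) sum_{k != i} X_k W_k',      Xhat_i = Zhat_i W_i.

The estimate lives in the rank-L row space of ``W_i``; L trades noise
suppression against expressiveness and is chosen by inner cross-validation on
the Kv(2K) accuracy of the reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from ._utils import derive_seed
from .data_model import MultiSubjectDataset, flatten
from .folds import FoldScheme, inner_splits, make_folds, train_test_split
from .kv2k import KvConfig, kv2k_accuracy
from .pairwise_mapping import DenoisedDataset

logger = logging.getLogger("megdenoise")

DEFAULT_N_ITER = 10
DEFAULT_TOL = 1e-6


@dataclass
class SRMFoldFit:
    """Per-fold SRM parameters: one L x d row-orthonormal basis per subject."""

    bases: dict[str, np.ndarray]
    L: int
    objective: list[float] = field(default_factory=list)


@dataclass
class SRMModel:
    L: int
    scheme: FoldScheme
    folds: dict[int, SRMFoldFit]


def _srm_solve(
    X: dict[str, np.ndarray],
    L: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> SRMFoldFit:
    """Alternating minimisation for one training set (deterministic given seed)."""
    subjects = list(X)
    n, d = X[subjects[0]].shape
    if not 1 <= L <= min(d, n):
        raise ValueError(f"latent dimension L={L} out of range [1, {min(d, n)}]")
    for s in subjects:
        if X[s].shape != (n, d):
            raise ValueError("all subjects must share n_train and d")
    rng = np.random.default_rng(seed)
    # init: QR of a seeded Gaussian per subject -> row-orthonormal basis
    bases = {}
    for s in subjects:
        Q, _ = np.linalg.qr(rng.standard_normal((d, L)))
        bases[s] = Q.T
    objective = []
    prev = np.inf
    for it in range(n_iter):
        Z = np.mean([X[s] @ bases[s].T for s in subjects], axis=0)
        for s in subjects:
            # min ||X_s - Z W||_F  s.t. W W' = I  ->  orthogonal Procrustes
            U, _, Vt = scipy.linalg.svd(Z.T @ X[s], full_matrices=False)
            bases[s] = U @ Vt
        obj = float(sum(np.linalg.norm(X[s] - Z @ bases[s], "fro") ** 2 for s in subjects))
        objective.append(obj)
        if prev - obj <= tol * max(abs(obj), 1.0):
            break
        prev = obj
    return SRMFoldFit(bases, L, objective)


def fit_srm(
    dataset: MultiSubjectDataset,
    scheme: FoldScheme,
    L: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
) -> SRMModel:
    """Fit one SRM per outer fold on that fold's training events."""
    X = {s: flatten(dataset, s).values for s in dataset.subjects}
    for s, x in X.items():
        if np.isnan(x).any():
            raise ValueError(f"NaNs in data of subject {s}")
    folds = {}
    for j in range(scheme.k):
        train, _ = train_test_split(scheme, j)
        Xtr = {s: X[s][train] for s in dataset.subjects}
        folds[j] = _srm_solve(Xtr, L, n_iter, derive_seed(seed, f"srm-fold{j}"), tol)
        logger.info("SRM fold %d: objective %.4g after %d iters", j,
                    folds[j].objective[-1], len(folds[j].objective))
    return SRMModel(L, scheme, folds)


def denoise_srm_loo(model: SRMModel, dataset: MultiSubjectDataset) -> DenoisedDataset:
    """Leave-one-subject-out SRM reconstruction of every subject's test data."""
    if dataset.n_subjects < 2:
        raise ValueError("leave-one-out reconstruction requires at least 2 subjects")
    X = {s: flatten(dataset, s).values for s in dataset.subjects}
    n, d = dataset.n_events, dataset.n_sensors * dataset.n_time
    out = {s: np.full((n, d), np.nan) for s in dataset.subjects}
    scheme = model.scheme
    for j in range(scheme.k):
        _, test = train_test_split(scheme, j)
        fit = model.folds[j]
        proj = {s: X[s][test] @ fit.bases[s].T for s in dataset.subjects}
        for i in dataset.subjects:
            Zi = np.mean([proj[k] for k in dataset.subjects if k != i], axis=0)
            out[i][test] = Zi @ fit.bases[i]
    tensors = {
        s: out[s].reshape(n, dataset.n_sensors, dataset.n_time) for s in dataset.subjects
    }
    ds = MultiSubjectDataset(
        list(dataset.subjects), tensors, dataset.time_axis.copy(), dataset.sensors, list(dataset.runs)
    )
    prov = {"method": "srm", "L": model.L, "n_folds": scheme.k, "n_edge_drop": scheme.n_edge_drop}
    return DenoisedDataset(ds, scheme.test_usable.copy(), prov)


def choose_L(
    dataset: MultiSubjectDataset,
    scheme: FoldScheme,
    L_grid: Sequence[int],
    kv_config: KvConfig | None = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    n_inner: int = 2,
) -> int:
    """Select the latent dimensionality by inner cross-validation.

    For each candidate L, SRMs are fit on inner-training blocks of each outer
    fold's training events and scored by the mean Kv(2K) accuracy of the
    leave-one-subject-out reconstruction on the inner validation block.  Ties
    prefer the smaller L.
    """
    if len(L_grid) == 0:
        raise ValueError("empty L grid")
    kv_config = kv_config or KvConfig(seed=derive_seed(seed, "choose-L"))
    X = {s: flatten(dataset, s).values for s in dataset.subjects}
    scores = []
    for L in sorted(L_grid):
        acc = []
        for j in range(scheme.k):
            train, _ = train_test_split(scheme, j)
            for si, (tr, val) in enumerate(inner_splits(train, n_inner)):
                fit = _srm_solve(
                    {s: X[s][tr] for s in dataset.subjects}, L, n_iter,
                    derive_seed(seed, f"chooseL-{L}-{j}-{si}"),
                )
                proj = {s: X[s][val] @ fit.bases[s].T for s in dataset.subjects}
                for i in dataset.subjects:
                    Zi = np.mean([proj[k] for k in dataset.subjects if k != i], axis=0)
                    acc.append(kv2k_accuracy(Zi @ fit.bases[i], X[i][val], kv_config))
        scores.append(float(np.mean(acc)))
        logger.info("choose_L: L=%d mean accuracy %.4f", L, scores[-1])
    best = int(np.array(sorted(L_grid))[int(np.argmax(scores))])
    return best
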