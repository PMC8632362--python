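"""Pairwise mapping (PM): cross-subject predictive denoising in subject space.

Every subject watched the same single-trial stimulus stream, so the part of a
target subject's response that can be predicted from *other* subjects is, by
construction, stimulus-driven rather than subject-specific noise.  PM models a
target subject's flattened response ``X_t`` as a cross-validated ridge
function of each source subject's response ``X_s``

    X_t = W_{t<-s}' X_s + b_{t<-s} + eps,

collects the held-out test-fold predictions ``Xhat_{t<-s}`` across folds, and
averages them over the N-1 sources:

    Xhat_t = 1/(N-1) * sum_{s != t} Xhat_{t<-s}.

The averaged estimate is the denoised version of the target's data.
Averaging matters: per-source prediction errors are largely independent, so
the average is closer to the shared response than any single source's
estimate.

Predictor settings
------------------
Each response value (one sensor at one time bin of the target) can be
predicted from four predictor subsets of the source -- all sensors or a
spatial neighborhood, crossed with all time bins or a temporal window:
``SGTG``, ``SGTL``, ``SLTG``, ``SLTL``.  Global settings model more but blur
spatial/temporal provenance; local settings keep denoised values traceable to
the matching sensors/latencies and thus permit spatial/temporal inference.
Because ridge decouples across response columns, responses sharing a
predictor set are fit jointly in one multivariate model (one model for SGTG,
one per time bin for SGTL, one per sensor for SLTG, one per sensor-time pair
for SLTL) -- exactly equivalent to fitting each column separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._ridge import DEFAULT_LAMBDAS, FittedRidge, RidgeDesign, fit_ridge_cv
from ._utils import derive_seed
from .data_model import MultiSubjectDataset, SensorTable, flatten
from .folds import FoldScheme, train_test_split
from .kv2k import KvConfig, kv2k_accuracy

logger = logging.getLogger("megdenoise")

DEFAULT_K_SENSORS = 9
DEFAULT_HALF_WIDTH = 2


@dataclass(frozen=True)
class PredictorSetting:
    """Spatial x temporal predictor subset for cross-subject models.

    ``spatial``/``temporal`` are "global" or "local"; a local spatial
    neighborhood is the ``k_sensors`` nearest sensors in layout coordinates
    (always containing the response's own sensor), a local temporal window
    spans ``half_width`` bins on each side of the response bin, clipped at the
    epoch edges.
    """

    spatial: str = "global"
    temporal: str = "global"
    k_sensors: int = DEFAULT_K_SENSORS
    half_width: int = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if self.spatial not in ("global", "local") or self.temporal not in ("global", "local"):
            raise ValueError("spatial and temporal must be 'global' or 'local'")

    @property
    def name(self) -> str:
        return f"s{self.spatial[0]}t{self.temporal[0]}"

    @classmethod
    def from_name(cls, name: str, k_sensors: int = DEFAULT_K_SENSORS,
                  half_width: int = DEFAULT_HALF_WIDTH) -> "PredictorSetting":
        name = name.lower()
        table = {"sgtg": ("global", "global"), "sgtl": ("global", "local"),
                 "sltg": ("local", "global"), "sltl": ("local", "local")}
        if name not in table:
            raise ValueError(f"unknown setting {name!r}; choose one of {sorted(table)}")
        sp, te = table[name]
        return cls(sp, te, k_sensors, half_width)


SGTG = PredictorSetting("global", "global")
SGTL = PredictorSetting("global", "local")
SLTG = PredictorSetting("local", "global")
SLTL = PredictorSetting("local", "local")


def build_predictors(
    setting: PredictorSetting,
    sensors: SensorTable,
    n_time: int,
    response: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Predictor (sensor indices, time indices) for one response (sensor, bin)."""
    s, t = response
    if not (0 <= s < len(sensors) and 0 <= t < n_time):
        raise IndexError(f"response ({s}, {t}) out of range")
    if setting.spatial == "global":
        sens = np.arange(len(sensors))
    else:
        sens = sensors.nearest(s, setting.k_sensors)
        if len(sens) == 0:
            raise ValueError("empty spatial neighborhood")
    if setting.temporal == "global":
        times = np.arange(n_time)
    else:
        lo = max(0, t - setting.half_width)
        hi = min(n_time, t + setting.half_width + 1)
        times = np.arange(lo, hi)
    return sens, times


def _cols(sens: np.ndarray, times: np.ndarray, n_time: int) -> np.ndarray:
    # sensor-major flattening: column = sensor * n_time + time
    return (sens[:, None] * n_time + times[None, :]).ravel()


def response_groups(
    setting: PredictorSetting, sensors: SensorTable, n_time: int
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Response columns grouped by shared predictor set.

    Returns ``(group key, predictor columns, response columns)`` triples in
    flattened (sensor-major) column indices.  Ridge decouples across response
    columns, so fitting each group jointly is exact.
    """
    n_s = len(sensors)
    all_s, all_t = np.arange(n_s), np.arange(n_time)
    groups: list[tuple[str, np.ndarray, np.ndarray]] = []
    if setting.spatial == "global" and setting.temporal == "global":
        cols = _cols(all_s, all_t, n_time)
        groups.append(("all", cols, cols))
    elif setting.spatial == "global":
        for t in range(n_time):
            sens, times = build_predictors(setting, sensors, n_time, (0, t))
            groups.append((f"t{t}", _cols(all_s, times, n_time), _cols(all_s, np.array([t]), n_time)))
    elif setting.temporal == "global":
        for s in range(n_s):
            sens, times = build_predictors(setting, sensors, n_time, (s, 0))
            groups.append((f"s{s}", _cols(sens, all_t, n_time), _cols(np.array([s]), all_t, n_time)))
    else:
        for s in range(n_s):
            sens = sensors.nearest(s, setting.k_sensors)
            for t in range(n_time):
                _, times = build_predictors(setting, sensors, n_time, (s, t))
                groups.append(
                    (f"s{s}t{t}", _cols(sens, times, n_time), _cols(np.array([s]), np.array([t]), n_time))
                )
    return groups


@dataclass
class PairwiseMapModel:
    """Fitted cross-subject ridge maps for one (source, target) pair."""

    source: str
    target: str
    setting: PredictorSetting
    scheme: FoldScheme
    models: dict[tuple[int, str], FittedRidge]
    groups: list[tuple[str, np.ndarray, np.ndarray]]
    lambda_grid: tuple


def fit_pairwise(
    dataset: MultiSubjectDataset,
    source: str,
    target: str,
    scheme: FoldScheme,
    setting: PredictorSetting = SGTG,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDAS,
    n_inner: int = 3,
    design_cache: dict | None = None,
) -> PairwiseMapModel:
    """Fit per-fold ridge maps predicting ``target`` from ``source``.

    For each outer fold the model is fit on the training events only, with the
    penalty selected by inner contiguous-block CV on mean squared error.
    ``design_cache`` (optional) shares predictor-side decompositions across
    calls with the same source.
    """
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")
    Xs = flatten(dataset, source).values
    Xt = flatten(dataset, target).values
    if np.isnan(Xs).any() or np.isnan(Xt).any():
        raise ValueError("NaNs in subject data")
    groups = response_groups(setting, dataset.sensors, dataset.n_time)
    models: dict[tuple[int, str], FittedRidge] = {}
    cache = design_cache if design_cache is not None else {}
    for j in range(scheme.k):
        train, _ = train_test_split(scheme, j)
        for key, pred_cols, resp_cols in groups:
            ckey = (source, j, key)
            design = cache.get(ckey)
            if design is None:
                design = RidgeDesign(Xs[:, pred_cols], train, n_inner)
                cache[ckey] = design
            models[(j, key)] = fit_ridge_cv(design, Xt[:, resp_cols], lambda_grid)
    return PairwiseMapModel(source, target, setting, scheme, models, groups, tuple(lambda_grid))


def predict_heldout(model: PairwiseMapModel, dataset: MultiSubjectDataset) -> np.ndarray:
    """Concatenated held-out predictions ``Xhat_{t<-s}``.

    Returns an ``n_events x d`` matrix: every test-usable event is predicted
    exactly once, by the ridge map of its own fold; all other events are NaN.
    """
    Xs = flatten(dataset, model.source).values
    out = np.full_like(Xs, np.nan)
    for j in range(model.scheme.k):
        _, test = train_test_split(model.scheme, j)
        for key, pred_cols, resp_cols in model.groups:
            out[test[:, None], resp_cols[None, :]] = model.models[(j, key)].predict(
                Xs[np.ix_(test, pred_cols)]
            )
    return out


def heldout_accuracy(
    pred: np.ndarray,
    gold: np.ndarray,
    scheme: FoldScheme,
    kv_config: KvConfig | None = None,
) -> float:
    """Kv(2K) accuracy of held-out predictions: per-fold, then averaged.

    Comparisons are drawn within each test fold and the per-fold accuracies
    averaged (Acc = 1/k * sum_j 20v40 on fold j).  Evaluating within folds is
    essential: predictions of different folds come from different models with
    different intercepts, and pooled comparisons would convert those offsets
    into a systematic bias (below chance under the null).
    """
    kv_config = kv_config or KvConfig(seed=0)
    accs = []
    for j in range(scheme.k):
        mask = (scheme.fold_id == j) & scheme.test_usable
        cfg = KvConfig(
            K=kv_config.K, n_draws=kv_config.n_draws, distance=kv_config.distance,
            match_attribute=kv_config.match_attribute,
            seed=derive_seed(kv_config.seed or 0, f"fold{j}"),
        )
        accs.append(kv2k_accuracy(pred[mask], gold[mask], cfg))
    return float(np.mean(accs))


@dataclass
class DenoisedDataset:
    """Denoised tensors with the same layout as the input dataset.

    Values are defined only at test-usable events (NaN elsewhere, since edge
    events never receive held-out predictions).  ``pairwise`` optionally
    retains the per-source flattened estimates for the source-target accuracy
    matrix analysis.
    """

    dataset: MultiSubjectDataset
    test_usable: np.ndarray
    provenance: dict
    pairwise: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def denoise_pm(
    dataset: MultiSubjectDataset,
    scheme: FoldScheme,
    setting: PredictorSetting = SGTG,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDAS,
    n_inner: int = 3,
    keep_pairwise: bool = False,
) -> DenoisedDataset:
    """Denoise every subject by averaged cross-subject prediction (PM).

    For each target subject, fits ridge maps from each of the other N-1
    subjects, concatenates held-out test predictions across folds, and
    averages the per-source estimates.
    """
    if dataset.n_subjects < 2:
        raise ValueError("pairwise denoising requires at least 2 subjects")
    n, d = dataset.n_events, dataset.n_sensors * dataset.n_time
    cache: dict = {}
    denoised: dict[str, np.ndarray] = {}
    pairwise: dict[tuple[str, str], np.ndarray] = {}
    for target in dataset.subjects:
        acc = np.zeros((n, d))
        for source in dataset.subjects:
            if source == target:
                continue
            logger.info("PM %s: fitting %s <- %s", setting.name, target, source)
            model = fit_pairwise(
                dataset, source, target, scheme, setting, lambda_grid, n_inner, cache
            )
            pred = predict_heldout(model, dataset)
            if keep_pairwise:
                pairwise[(target, source)] = pred
            acc += np.where(np.isnan(pred), 0.0, pred)
        avg = acc / (dataset.n_subjects - 1)
        avg[~scheme.test_usable] = np.nan
        denoised[target] = avg.reshape(n, dataset.n_sensors, dataset.n_time)
    out = MultiSubjectDataset(
        list(dataset.subjects), denoised, dataset.time_axis.copy(), dataset.sensors, list(dataset.runs)
    )
    prov = {
        "method": "pm",
        "setting": setting.name,
        "k_sensors": setting.k_sensors,
        "half_width": setting.half_width,
        "lambda_grid": [float(v) for v in lambda_grid],
        "n_folds": scheme.k,
        "n_edge_drop": scheme.n_edge_drop,
        "sources": {t: [s for s in dataset.subjects if s != t] for t in dataset.subjects},
    }
    return DenoisedDataset(out, scheme.test_usable.copy(), prov, pairwise)


def pairwise_accuracy_matrix(
    denoised: DenoisedDataset,
    dataset: MultiSubjectDataset,
    scheme: FoldScheme,
    kv_config: KvConfig | None = None,
):
    """Source-target 20v40 accuracy matrix plus the averaged-estimate column.

    Entry (target, source) is the mean over folds of the Kv(2K) accuracy
    between the held-out prediction of the target from that source and the
    target's measured data; the extra ``averaged`` column evaluates the
    N-1-source average the same way.  Requires ``denoise_pm(...,
    keep_pairwise=True)`` output.  Within a fold, all entries are evaluated on
    identical sampled comparisons (common random numbers), so differences
    between entries are not sampling noise.
    """
    if not denoised.pairwise:
        raise ValueError("denoised dataset lacks per-pair predictions; rerun with keep_pairwise=True")
    import pandas as pd

    kv_config = kv_config or KvConfig(seed=0)
    subs = dataset.subjects
    mat = pd.DataFrame(np.nan, index=subs, columns=subs)
    avg_col = pd.Series(0.0, index=subs)
    fold_masks = [
        (scheme.fold_id == j) & scheme.test_usable for j in range(scheme.k)
    ]
    for t in subs:
        gold = flatten(dataset, t).values
        avg = flatten(denoised.dataset, t).values
        per_pair = {s: denoised.pairwise[(t, s)] for s in subs if s != t}
        accs_avg = []
        for j, mask in enumerate(fold_masks):
            cfg = KvConfig(
                K=kv_config.K, n_draws=kv_config.n_draws,
                distance=kv_config.distance,
                seed=derive_seed(kv_config.seed or 0, f"fold{j}"),
            )
            for s, pred in per_pair.items():
                a = kv2k_accuracy(pred[mask], gold[mask], cfg)
                mat.loc[t, s] = (0.0 if np.isnan(mat.loc[t, s]) else mat.loc[t, s]) + a / scheme.k
            accs_avg.append(kv2k_accuracy(avg[mask], gold[mask], cfg))
        avg_col[t] = float(np.mean(accs_avg))
    return mat, avg_col
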