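"""Contiguous-block cross-validation for non-IID event streams.

Event-locked MEG is a time series: adjacent events are temporally correlated,
so shuffled cross-validation splits leak information from training into test
and yield over-optimistic estimates.  Folds here are contiguous blocks
(acquisition runs by default), and events at fold edges -- which are
temporally adjacent to training data of the neighboring fold -- are dropped
from *test* evaluation.  At the usual RSVP presentation rate (one event per
500 ms) the default drop of 60 events removes 30 s at each fold boundary.

Dropped edge events remain available as training data for other folds: the
leakage concern is test events sitting close to training events, not the
reverse direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

DEFAULT_EDGE_DROP = 60


@dataclass
class FoldScheme:
    """Assignment of events to contiguous folds with edge-drop masks.

    Attributes
    ----------
    fold_id
        Per-event fold index in ``[0, k)``; each fold is a contiguous block.
    test_usable
        Per-event flag; False for the ``n_edge_drop`` events at the start and
        end of each fold, which are excluded from test evaluation.
    note
        How the folds were derived ("runs-as-folds" or "equal-blocks").
    """

    fold_id: np.ndarray
    test_usable: np.ndarray
    n_edge_drop: int
    note: str = ""

    @property
    def k(self) -> int:
        return int(self.fold_id.max()) + 1

    @property
    def n_events(self) -> int:
        return len(self.fold_id)

    def fold_bounds(self, j: int) -> tuple[int, int]:
        idx = np.flatnonzero(self.fold_id == j)
        return int(idx[0]), int(idx[-1]) + 1

    def __iter__(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for j in range(self.k):
            yield train_test_split(self, j)


def make_folds(
    n_events: int,
    runs: Sequence[tuple[int, int]] | None = None,
    n_blocks: int | None = None,
    n_edge_drop: int = DEFAULT_EDGE_DROP,
) -> FoldScheme:
    """Build a contiguous-block fold scheme.

    Either ``runs`` (each acquisition run becomes one fold) or ``n_blocks``
    (the event axis is cut into equal contiguous blocks) must be given.  Every
    fold must be longer than ``2 * n_edge_drop`` so that at least one
    test-usable event remains.
    """
    if (runs is None) == (n_blocks is None):
        raise ValueError("give exactly one of runs or n_blocks")
    if n_edge_drop < 0:
        raise ValueError("n_edge_drop must be >= 0")
    if runs is not None:
        bounds = [(int(a), int(b)) for a, b in sorted(runs)]
        note = "runs-as-folds"
    else:
        edges = np.linspace(0, n_events, n_blocks + 1).round().astype(int)
        bounds = list(zip(edges[:-1], edges[1:]))
        note = "equal-blocks"
    if bounds[0][0] != 0 or bounds[-1][1] != n_events or any(
        a1 != b0 for (_, a1), (b0, _) in zip(bounds, bounds[1:])
    ):
        raise ValueError(f"fold blocks must partition [0, {n_events})")
    fold_id = np.empty(n_events, dtype=int)
    test_usable = np.ones(n_events, dtype=bool)
    for j, (a, b) in enumerate(bounds):
        if b - a <= 2 * n_edge_drop:
            raise ValueError(
                f"fold {j} has {b - a} events, not more than 2*{n_edge_drop}; "
                "use a smaller n_edge_drop or longer blocks"
            )
        fold_id[a:b] = j
        test_usable[a : a + n_edge_drop] = False
        test_usable[b - n_edge_drop : b] = False
    return FoldScheme(fold_id, test_usable, n_edge_drop, note)


def train_test_split(scheme: FoldScheme, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Event indices for outer fold ``j``: (train, test).

    Test events are the test-usable events of fold ``j``; training events are
    all events of every other fold.
    """
    if not 0 <= j < scheme.k:
        raise IndexError(f"fold index {j} out of range [0, {scheme.k})")
    test = np.flatnonzero((scheme.fold_id == j) & scheme.test_usable)
    train = np.flatnonzero(scheme.fold_id != j)
    return train, test


def inner_splits(
    train_idx: np.ndarray, n_blocks: int = 3, n_edge_drop: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous sub-splits of a training set for hyperparameter selection.

    The training events (already a union of contiguous blocks) are cut into
    ``n_blocks`` consecutive chunks; each chunk serves once as the validation
    set with the same edge-drop logic applied at chunk boundaries.  Returns a
    list of (inner-train, inner-validation) index arrays (absolute indices).
    """
    train_idx = np.asarray(train_idx)
    n = len(train_idx)
    if n_blocks < 2:
        raise ValueError("need at least 2 inner blocks")
    if n_edge_drop is None:
        n_edge_drop = min(DEFAULT_EDGE_DROP, max(0, n // (n_blocks * 10)))
    edges = np.linspace(0, n, n_blocks + 1).round().astype(int)
    out = []
    for j in range(n_blocks):
        a, b = edges[j], edges[j + 1]
        lo, hi = a + n_edge_drop, b - n_edge_drop
        if hi <= lo:
            raise ValueError("inner block too short for the edge drop")
        val = train_idx[lo:hi]
        tr = np.concatenate([train_idx[:a], train_idx[b:]])
        out.append((tr, val))
    return out


def save_folds(scheme: FoldScheme, h5path) -> None:
    """Append the fold scheme to an existing HDF5 container (group /folds)."""
    import h5py

    with h5py.File(h5path, "a") as f:
        if "folds" in f:
            del f["folds"]
        g = f.create_group("folds")
        g.create_dataset("fold_id", data=scheme.fold_id)
        g.create_dataset("test_usable", data=scheme.test_usable)
        g.attrs["n_edge_drop"] = scheme.n_edge_drop
        g.attrs["note"] = scheme.note


def load_folds(h5path) -> FoldScheme:
    import h5py

    with h5py.File(h5path, "r") as f:
        if "folds" not in f:
            raise KeyError(f"{h5path} has no /folds group")
        g = f["folds"]
        return FoldScheme(
            g["fold_id"][()],
            g["test_usable"][()].astype(bool),
            int(g.attrs["n_edge_drop"]),
            str(g.attrs.get("note", "")),
        )
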