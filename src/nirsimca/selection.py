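"""Sample selection, cross-validation and performance reporting.

Kennard-Stone maximin train/test splitting, batch-wise splitting that never
lets a falsified batch into training, venetian-blinds cross-validation for
choosing the number of principal components, and sensitivity/specificity
reports for one-class decisions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SpectrumSet

__all__ = [
    "SplitResult",
    "ClassificationReport",
    "kennard_stone",
    "split_by_batches",
    "venetian_blinds_select",
    "evaluate",
]


@dataclass(frozen=True)
class SplitResult:
    training: tuple
    test: tuple
    method: str

    def __post_init__(self) -> None:
        if set(self.training) & set(self.test):
            raise ValueError("training and test sets overlap")


def kennard_stone(X: np.ndarray, train_fraction: float) -> SplitResult:
    """Classic Kennard-Stone maximin selection on Euclidean distances.

    Seeds with the two mutually farthest samples, then repeatedly adds the
    candidate whose minimum distance to the already-selected set is largest,
    until ceil(train_fraction * n) samples are selected. Fully deterministic;
    ties break toward the lowest row index. Returned ids are row positions.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 samples")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = min(math.ceil(train_fraction * n), n)
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    # farthest pair; argmax on the flattened matrix takes the lowest index first
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)] if i != j else [0, 1]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        np.minimum(min_dist, D[nxt], out=min_dist)
    train = sorted(selected[:n_train])
    test = sorted(set(range(n)) - set(train))
    return SplitResult(tuple(train), tuple(test), "kennard_stone")


def split_by_batches(
    spectra: SpectrumSet, brand: str, n_train_batches: int
) -> SplitResult:
    """Assign whole batches of one brand to training or test.

    The first ``n_train_batches`` batch ids in sorted order go to training
    and the remainder to test, except that batches containing falsified
    samples are never placed in training. Returned ids are sample_ids.
    """
    meta = spectra.metadata
    sub = meta[meta["brand"] == brand]
    if sub.empty:
        raise ValueError(f"no spectra for brand {brand!r}")
    batches = sorted(sub["batch_id"].unique())
    if n_train_batches >= len(batches):
        raise ValueError(
            f"brand {brand!r} has {len(batches)} batches; cannot train on "
            f"{n_train_batches}"
        )
    falsified_batches = set(sub.loc[sub["falsified"], "batch_id"])
    candidates = [b for b in batches if b not in falsified_batches]
    if len(candidates) < n_train_batches:
        raise ValueError(
            f"brand {brand!r} has only {len(candidates)} non-falsified batches"
        )
    train_batches = set(candidates[:n_train_batches])
    train = tuple(sub.loc[sub["batch_id"].isin(train_batches), "sample_id"])
    test = tuple(sub.loc[~sub["batch_id"].isin(train_batches), "sample_id"])
    return SplitResult(train, test, "by_batch")


def venetian_blinds_select(
    X: np.ndarray, max_A: int, n_splits: int = 10, rel_tol: float = 0.05
) -> int:
    """Choose the number of PCs by venetian-blinds cross-validated PRESS.

    For each blind k, every n_splits-th sample starting at k is held out, PCA
    is fitted on the remainder, and the held-out squared residual after
    projection onto the first A loadings is accumulated. The selected A is the
    smallest one whose PRESS is within ``rel_tol`` of the minimum (row-wise
    projection PRESS decreases monotonically, so pure minimisation would
    always pick max_A).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_splits = min(n_splits, n)
    if n_splits < 2:
        raise ValueError("need at least 2 splits (and samples)")
    if max_A < 1:
        raise ValueError("max_A must be >= 1")
    max_fold = math.ceil(n / n_splits)
    cap = n - max_fold - 1
    if max_A > cap:
        warnings.warn(
            f"max_A={max_A} too large for n={n} with {n_splits} blinds; "
            f"capping at {cap}",
            stacklevel=2,
        )
        max_A = cap
    if max_A < 1:
        raise ValueError("too few samples for any cross-validated component")
    press = np.zeros(max_A)
    idx = np.arange(n)
    for k in range(n_splits):
        held = idx % n_splits == k
        Xtr, Xte = X[~held], X[held]
        if len(Xte) == 0:
            continue
        center = Xtr.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xtr - center, full_matrices=False)
        rank = int(np.sum(s > max(s[0], 1e-300) * 1e-10))
        V = Vt[: min(max_A, rank)].T
        Xtc = Xte - center
        total = float(np.einsum("ij,ij->", Xtc, Xtc))
        proj = Xtc @ V  # (n_held x <=max_A)
        cum = np.cumsum(np.einsum("ij,ij->j", proj, proj))
        fold_press = total - cum
        if cum.size < max_A:  # rank-limited fold: flat beyond the rank
            fold_press = np.concatenate(
                [fold_press, np.full(max_A - cum.size, fold_press[-1])]
            )
        press += np.maximum(fold_press, 0.0)
    threshold = (1.0 + rel_tol) * float(press.min())
    return int(np.argmax(press <= threshold)) + 1


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class and pooled one-class performance.

    ``table`` has one row per class model with columns brand, n_target,
    n_foreign, true_accept, true_reject, sensitivity, specificity (percent;
    NaN where a test group is empty).
    """

    table: pd.DataFrame

    @property
    def pooled_sensitivity(self) -> float:
        n = self.table["n_target"].sum()
        return float("nan") if n == 0 else 100.0 * self.table["true_accept"].sum() / n

    @property
    def pooled_specificity(self) -> float:
        n = self.table["n_foreign"].sum()
        return float("nan") if n == 0 else 100.0 * self.table["true_reject"].sum() / n


def evaluate(decisions: pd.DataFrame, truth: pd.DataFrame) -> ClassificationReport:
    """Score one-class accept/reject decisions against sample truth.

    ``decisions``: columns sample_id, model_brand, accepted (bool), one row per
    (sample, class model). ``truth``: columns sample_id, brand, falsified.
    A sample is a target of a model iff its brand matches the model brand and
    it is not falsified; everything else (other brands, falsified look-alikes)
    counts toward specificity.
    """
    for col in ("sample_id", "model_brand", "accepted"):
        if col not in decisions.columns:
            raise ValueError(f"decisions missing column {col!r}")
    for col in ("sample_id", "brand", "falsified"):
        if col not in truth.columns:
            raise ValueError(f"truth missing column {col!r}")
    merged = decisions.merge(
        truth[["sample_id", "brand", "falsified"]], on="sample_id", how="left"
    )
    if merged["brand"].isna().any():
        missing = merged.loc[merged["brand"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"decision references unknown sample {missing!r}")
    rows = []
    for model_brand, grp in merged.groupby("model_brand", sort=True):
        is_target = (grp["brand"] == model_brand) & (~grp["falsified"].astype(bool))
        n_target = int(is_target.sum())
        n_foreign = int((~is_target).sum())
        true_accept = int((grp.loc[is_target, "accepted"]).sum())
        true_reject = int((~grp.loc[~is_target, "accepted"].astype(bool)).sum())
        rows.append(
            {
                "brand": model_brand,
                "n_target": n_target,
                "n_foreign": n_foreign,
                "true_accept": true_accept,
                "true_reject": true_reject,
                "sensitivity": (
                    100.0 * true_accept / n_target if n_target else float("nan")
                ),
                "specificity": (
                    100.0 * true_reject / n_foreign if n_foreign else float("nan")
                ),
            }
        )
    return ClassificationReport(pd.DataFrame(rows))
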