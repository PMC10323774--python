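"""Rank chromatin marks by their power to separate up- from down-regulated genes.

A random-forest classifier is trained on per-bin signal-change features and
scored by the AUC of pooled out-of-training vote fractions. Three analyses
build on it: an exhaustive sweep over all non-empty mark subsets (2^k - 1
models), the frequency of each mark among fixed-size subsets whose AUC
exceeds a fraction of the full model's, and a per-bin importance map that
fits one model per bin on the k mark features and ranks marks by permutation
importance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .quantify import SignalChangeMatrix


@dataclass(frozen=True)
class CVConfig:
    """Resampling scheme for out-of-training gene scores.

    ``repeated_split`` (default) repeats a stratified random 30%-train /
    70%-test split and averages each gene's test-set scores across
    repetitions; ``kfold`` uses plain stratified k-fold with out-of-fold
    scores; ``oob`` fits one forest on all genes and scores each gene by its
    out-of-bag vote fraction (cheapest, used for exhaustive subset sweeps).
    """

    mode: str = "repeated_split"
    n_repeats: int = 10
    train_frac: float = 0.3
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("repeated_split", "kfold", "oob"):
            raise ValueError(f"unknown cv mode {self.mode!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion at the 0.5 vote threshold (up = positive class)."""

    n_up: int
    n_down: int
    up_called_down: int
    down_called_up: int

    @property
    def sensitivity(self) -> float:
        return 1.0 - self.up_called_down / self.n_up

    @property
    def specificity(self) -> float:
        return 1.0 - self.down_called_up / self.n_down


@dataclass
class ModelEvaluation:
    auc: float
    confusion: ConfusionCounts
    scores: pd.Series  # per-gene mean out-of-training vote fraction for "up"
    labels: pd.Series


def build_features(
    changes: SignalChangeMatrix,
    degs: pd.DataFrame,
    marks: Sequence[str],
    bins: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Signal-change feature matrix and up/down labels for the DEGs.

    One column per (mark, bin); rows are the up/down genes of ``degs``.
    ``bins`` (1-based) restricts the bin set, e.g. ``[b]`` for a single-bin
    model.
    """
    if not marks:
        raise ValueError("mark subset must be non-empty")
    labels = degs.loc[degs["klass"].isin(["up", "down"]), "klass"]
    missing = [g for g in labels.index if g not in changes.genes]
    if missing:
        raise KeyError(f"genes absent from signal changes: {missing[:5]}")
    X = changes.feature_frame(marks).loc[labels.index]
    if bins is not None:
        keep = [f"{m}:bin{b}" for m in marks for b in bins]
        X = X[keep]
    return X, labels


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def evaluate_model(
    X: pd.DataFrame,
    y: pd.Series,
    cv: CVConfig = CVConfig(),
    n_trees: int = 500,
    seed: int = 0,
) -> ModelEvaluation:
    """Out-of-training vote fractions, AUC, and threshold-0.5 confusion.

    Every gene receives a score in [0, 1] (fraction of trees voting "up")
    from splits where it was held out; the AUC is the trapezoidal area under
    the ROC of the pooled per-gene scores, identical to the normalised
    Mann-Whitney U statistic of up- vs down-gene scores.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both up and down genes")
    if counts.min() < 2:
        raise ValueError("need >= 2 genes per class")
    y_bin = (y == "up").to_numpy().astype(int)
    Xv = X.to_numpy()
    score_sum = np.zeros(len(y))
    score_n = np.zeros(len(y))

    def run_splits(splitter, rounds_seed):
        for fit_idx, (train, test) in enumerate(splitter.split(Xv, y_bin)):
            clf = _forest(n_trees, seed=(rounds_seed + fit_idx) % 2**31)
            clf.fit(Xv[train], y_bin[train])
            up_col = list(clf.classes_).index(1)
            score_sum[test] += clf.predict_proba(Xv[test])[:, up_col]
            score_n[test] += 1

    if cv.mode == "oob":
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", oob_score=True,
            bootstrap=True, random_state=seed % 2**31, n_jobs=1,
        )
        clf.fit(Xv, y_bin)
        up_col = list(clf.classes_).index(1)
        oob = clf.oob_decision_function_[:, up_col]
        score_sum[:] = np.where(np.isnan(oob), 0.5, oob)
        score_n[:] = 1
    elif cv.mode == "repeated_split":
        splitter = StratifiedShuffleSplit(
            n_splits=cv.n_repeats, train_size=cv.train_frac, random_state=seed
        )
        run_splits(splitter, seed)
        if (score_n == 0).any():
            # one targeted fit: train only on already-scored genes so every
            # remaining gene gets an out-of-training score
            rng = np.random.default_rng(seed)
            scored_idx = np.where(score_n > 0)[0]
            train = []
            for cls in (0, 1):
                pool = scored_idx[y_bin[scored_idx] == cls]
                want = max(int(round(cv.train_frac * (y_bin == cls).sum())), 1)
                train.extend(rng.choice(pool, size=min(want, len(pool)),
                                        replace=False))
            train = np.asarray(train)
            test = np.where(score_n == 0)[0]
            clf = _forest(n_trees, seed=(seed + 104729) % 2**31)
            clf.fit(Xv[train], y_bin[train])
            up_col = list(clf.classes_).index(1)
            score_sum[test] += clf.predict_proba(Xv[test])[:, up_col]
            score_n[test] += 1
    else:
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=seed)
        run_splits(splitter, seed)

    scored = score_n > 0
    raw = np.where(scored, score_sum / np.maximum(score_n, 1), 0.5)
    # a gene with no defined vote fraction (e.g. never out-of-bag) scores 0.5
    scores = pd.Series(np.nan_to_num(raw, nan=0.5), index=y.index, name="score")
    auc = float(roc_auc_score(y_bin, scores))
    pred_up = scores.to_numpy() >= 0.5
    n_up = int((y_bin == 1).sum())
    n_down = int((y_bin == 0).sum())
    confusion = ConfusionCounts(
        n_up=n_up,
        n_down=n_down,
        up_called_down=int(((y_bin == 1) & ~pred_up).sum()),
        down_called_up=int(((y_bin == 0) & pred_up).sum()),
    )
    return ModelEvaluation(auc=auc, confusion=confusion, scores=scores,
                           labels=y.copy())


def _subset_seed(base_seed: int, subset: tuple[str, ...]) -> int:
    return (base_seed + zlib.crc32(",".join(subset).encode())) % 2**31


def sweep_combinations(
    changes: SignalChangeMatrix,
    degs: pd.DataFrame,
    marks: Sequence[str] | None = None,
    cv: CVConfig = CVConfig(),
    n_trees: int = 500,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Evaluate every non-empty mark subset (2^k - 1 models).

    Returns a table with columns ``marks`` (comma-joined, lexicographic),
    ``size`` and ``auc``, ordered by (size, marks). The best AUC per size —
    the envelope curve over subset sizes — can be read off with
    :func:`best_per_size`. ``sizes`` restricts the sweep to the given subset
    sizes (default: all, i.e. the full 2^k - 1 enumeration).
    """
    marks = sorted(marks) if marks is not None else sorted(changes.marks)
    rows = []
    for size in (sizes if sizes is not None else range(1, len(marks) + 1)):
        for subset in combinations(marks, size):
            X, y = build_features(changes, degs, subset)
            ev = evaluate_model(X, y, cv=cv, n_trees=n_trees,
                                seed=_subset_seed(seed, subset))
            rows.append({"marks": ",".join(subset), "size": size, "auc": ev.auc})
    return pd.DataFrame(rows)


def best_per_size(results: pd.DataFrame) -> pd.Series:
    """Highest AUC at each subset size (index: size)."""
    return results.groupby("size")["auc"].max()


def mark_frequencies(
    results: pd.DataFrame,
    size: int,
    full_model_auc: float,
    fraction: float = 0.95,
) -> pd.Series:
    """Percent of qualifying size-``size`` subsets containing each mark.

    A subset qualifies when its AUC exceeds ``fraction`` of the full-model
    AUC. Frequencies are percentages of the qualifying subsets.
    """
    sub = results[results["size"] == size]
    if sub.empty:
        raise ValueError(f"no subsets of size {size} in results")
    qualifying = sub[sub["auc"] > fraction * full_model_auc]
    if qualifying.empty:
        raise ValueError("no qualifying subsets at this fraction")
    all_marks = sorted({m for s in sub["marks"] for m in s.split(",")})
    freqs = {}
    for m in all_marks:
        n_with = qualifying["marks"].apply(lambda s: m in s.split(",")).sum()
        freqs[m] = 100.0 * n_with / len(qualifying)
    return pd.Series(freqs).sort_values(ascending=False)


def per_bin_importance(
    changes: SignalChangeMatrix,
    degs: pd.DataFrame,
    cv: CVConfig = CVConfig(),
    n_trees: int = 500,
    seed: int = 0,
    n_perm: int = 5,
    test_frac: float = 0.3,
) -> pd.DataFrame:
    """Rank marks within each bin by permutation importance (1 = strongest).

    For every bin one forest is fit on the k mark-change features at that
    bin; each feature's importance is the mean decrease in held-out AUC when
    it is permuted. Importances are converted to ranks per bin, ties broken
    by mark-name order, so each column of the returned (marks x bins) table
    is a permutation of 1..k.
    """
    marks = sorted(changes.marks)
    rank_mat = np.zeros((len(marks), 0), dtype=int)
    cols = []
    ranks = []
    for b in range(1, changes.values.shape[2] + 1):
        X, y = build_features(changes, degs, marks, bins=[b])
        y_bin = (y == "up").astype(int).to_numpy()
        rng_seed = (seed + b) % 2**31
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                          random_state=rng_seed)
        train, test = next(splitter.split(X, y_bin))
        clf = _forest(n_trees, rng_seed)
        clf.fit(X.iloc[train], y_bin[train])
        imp = permutation_importance(
            clf, X.iloc[test], y_bin[test], scoring="roc_auc",
            n_repeats=n_perm, random_state=rng_seed,
        ).importances_mean
        # rank 1 = largest importance; ties broken by mark-name order
        order = sorted(range(len(marks)), key=lambda i: (-imp[i], marks[i]))
        r = np.empty(len(marks), dtype=int)
        for pos, i in enumerate(order, start=1):
            r[i] = pos
        ranks.append(r)
        cols.append(b)
    rank_mat = np.stack(ranks, axis=1)
    return pd.DataFrame(rank_mat, index=marks, columns=cols)
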