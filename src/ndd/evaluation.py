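"""Stratified repeated cross-validation, metrics, and hyperparameter search.

Evaluation enumerates the unordered pair universe {(i, j) : i < j} —
self-pairs are excluded, and because the interaction label is symmetric an
ordered duplicate of a pair carries no extra information at test time. Each
repeat draws a fresh stratified k-fold split; within a fold, the test
pairs' labels are masked before the GIP kernel, the similarity selection,
the fusion, and the classifier ever see the interaction matrix, so no
held-out label can leak into the features.

Precision, recall and F-measure are reported at the threshold that
maximizes F; AUC and AUPR summarize the ranking independently of any
threshold. Fold-level metrics are averaged within a repeat and then across
repeats, with the standard deviation taken over all fold×repeat values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import NNConfig, build_dataset, score_unordered_pairs, train
from .data_model import InteractionMatrix, SimilarityMatrix
from .exceptions import MetricUndefinedError, ParameterError
from .gip import GIPConfig, gip_similarity, mask_pairs
from .selection import SelectionConfig, select_similarities
from .snf import FusionConfig, fuse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of each unordered pair to one of k folds."""

    assignments: Mapping[tuple[int, int], int]
    k: int
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.assignments.items() if f == fold]

    def train_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.assignments.items() if f != fold]


@dataclass(frozen=True)
class MetricsReport:
    """Aggregated CV metrics; ``per_fold`` has one row per fold×repeat."""

    precision: float
    recall: float
    f_measure: float
    auc: float
    aupr: float
    best_threshold: float
    n_repeats: int
    k: int
    sd: Mapping[str, float]
    per_fold: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "aupr": self.aupr,
            "best_threshold": self.best_threshold,
            "n_repeats": self.n_repeats,
            "k": self.k,
            "sd": dict(self.sd),
        }


def all_unordered_pairs(m: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(m), 2))


def stratified_folds(
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> FoldSplit:
    """Stratified k-fold assignment preserving the positive fraction per fold."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    if len(pairs) < k:
        raise ParameterError("fewer pairs than folds")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes must be present for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[tuple[int, int], int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for t in test_idx:
            assignments[tuple(pairs[t])] = fold
    return FoldSplit(assignments=assignments, k=k, seed=seed)


def confusion_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> tuple[float, float, float]:
    """Precision, recall and F at the rule ``score > threshold``.

    0/0 cases resolve to 0: no predicted positives -> precision 0, no true
    positives -> recall 0, precision+recall = 0 -> F 0.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pred = s > threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def best_threshold_metrics(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, float, float, float]:
    """Sweep every distinct score (plus 0 and 1) and return the F-maximizing
    (precision, recall, f, threshold); ties resolve to the lowest threshold."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("best-threshold metrics need both classes")
    candidates = np.unique(np.concatenate([s, [0.0, 1.0]]))
    best = (0.0, 0.0, -1.0, 0.0)
    for t in candidates:  # ascending; strict > keeps the first (lowest) maximizer
        p, r, f = confusion_metrics(y, s, t)
        if f > best[2]:
            best = (p, r, f, float(t))
    return best


def ranking_metrics(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, float]:
    """(AUC, AUPR). AUC gives ½ credit to ties; AUPR is the interpolation-free
    step-curve area (average precision)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("ranking metrics need both classes")
    s = np.asarray(scores, dtype=float)
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


# ---------------------------------------------------------------------------
# full cross-validated pipeline


def _fold_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31))


def run_cv(
    views: Sequence[SimilarityMatrix],
    Y: InteractionMatrix,
    selection_cfg: SelectionConfig = SelectionConfig(),
    fusion_cfg: FusionConfig = FusionConfig(),
    gip_cfg: GIPConfig = GIPConfig(),
    nn_cfg: NNConfig = NNConfig(),
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    gip_scope: str = "fold",
    include_gip: bool = True,
    collect_scores: bool = False,
    audit: bool = False,
):
    """Repeated stratified k-fold evaluation of the full pipeline.

    Per fold: mask the test pairs out of Y, compute GIP from the masked
    matrix (``gip_scope='fold'``; ``'global'`` computes it once from the full
    Y, which is faster but lets test labels shape the features), select and
    fuse the candidate views, train on the training pairs (both orderings),
    and score the held-out pairs as the mean of their two directional scores.

    Returns a :class:`MetricsReport`; with ``collect_scores`` also a
    DataFrame of out-of-fold scores from the first repeat, and with
    ``audit`` also a per-fold audit trail (masked matrix, pair lists, the
    GIP input) for leakage checks.
    """
    if gip_scope not in ("fold", "global"):
        raise ParameterError("gip_scope must be 'fold' or 'global'")
    pairs = all_unordered_pairs(Y.m)
    labels = [int(Y.Y[i, j]) for i, j in pairs]

    rows = []
    oof: list[dict] = []
    audits: list[dict] = []
    global_gip = gip_similarity(Y, gip_cfg) if (include_gip and gip_scope == "global") else None

    for rep in range(repeats):
        split = stratified_folds(pairs, labels, k=k, seed=_fold_seed(seed, rep))
        for fold in range(k):
            test_pairs = split.test_pairs(fold)
            train_pairs = split.train_pairs(fold)
            Y_masked = mask_pairs(Y, test_pairs)
            candidates = list(views)
            if include_gip:
                candidates.append(
                    global_gip if global_gip is not None else gip_similarity(Y_masked, gip_cfg)
                )
            sel = select_similarities(candidates, selection_cfg)
            chosen = [v for v in candidates if v.name in sel.selected]
            fused = fuse(chosen, fusion_cfg)

            fold_nn = replace(nn_cfg, seed=_fold_seed(seed, rep, fold))
            samples = build_dataset(fused, Y_masked, train_pairs, both_orders=True)
            model = train(samples, fold_nn)
            scores = score_unordered_pairs(model, fused, test_pairs)
            y_test = np.array([Y.Y[i, j] for i, j in test_pairs])

            p, r, f, thr = best_threshold_metrics(y_test, scores)
            auc, aupr = ranking_metrics(y_test, scores)
            rows.append(
                dict(repeat=rep, fold=fold, precision=p, recall=r, f_measure=f,
                     auc=auc, aupr=aupr, best_threshold=thr,
                     selected=",".join(sel.selected))
            )
            logger.info(
                "repeat %d fold %d: selected=%s auc=%.3f aupr=%.3f f=%.3f",
                rep, fold, list(sel.selected), auc, aupr, f,
            )
            if collect_scores and rep == 0:
                for (i, j), sc, yt in zip(test_pairs, scores, y_test):
                    oof.append(dict(i=i, j=j, label=int(yt), score=float(sc)))
            if audit:
                audits.append(
                    dict(repeat=rep, fold=fold, test_pairs=list(test_pairs),
                         train_pairs=list(train_pairs), Y_masked=Y_masked,
                         gip_input=candidates[-1] if include_gip else None)
                )

    per_fold = pd.DataFrame(rows)
    metric_cols = ["precision", "recall", "f_measure", "auc", "aupr", "best_threshold"]
    per_repeat = per_fold.groupby("repeat")[metric_cols].mean()
    means = per_repeat.mean()
    sds = per_fold[metric_cols].std(ddof=1) if len(per_fold) > 1 else per_fold[metric_cols].iloc[0] * 0.0
    report = MetricsReport(
        precision=float(means["precision"]), recall=float(means["recall"]),
        f_measure=float(means["f_measure"]), auc=float(means["auc"]),
        aupr=float(means["aupr"]), best_threshold=float(means["best_threshold"]),
        n_repeats=repeats, k=k, sd={c: float(sds[c]) for c in metric_cols},
        per_fold=per_fold,
    )
    out = [report]
    if collect_scores:
        out.append(pd.DataFrame(oof))
    if audit:
        out.append(audits)
    return out[0] if len(out) == 1 else tuple(out)


def permute_interactions(Y: InteractionMatrix, seed: int = 0) -> InteractionMatrix:
    """Shuffle the upper-triangle labels (a no-signal control), re-symmetrized."""
    rng = np.random.default_rng(seed)
    m = Y.m
    iu = np.triu_indices(m, k=1)
    vals = Y.Y[iu].copy()
    rng.shuffle(vals)
    Z = np.zeros((m, m), dtype=np.int8)
    Z[iu] = vals
    Z = Z + Z.T
    return InteractionMatrix(Y=Z)


def tune_nested_cv(
    views: Sequence[SimilarityMatrix],
    Y: InteractionMatrix,
    grids: Mapping[str, Sequence],
    base_nn: NNConfig = NNConfig(),
    selection_cfg: SelectionConfig = SelectionConfig(),
    fusion_cfg: FusionConfig = FusionConfig(),
    gip_cfg: GIPConfig = GIPConfig(),
    n_outer_folds: int = 3,
    seed: int = 0,
) -> NNConfig:
    """Grid search over classifier hyperparameters by mean outer-fold AUPR.

    ``grids`` maps NNConfig field names (e.g. ``hidden_sizes``,
    ``activation``, ``dropout``) to candidate values; every combination is
    scored by a stratified ``n_outer_folds``-fold run of the full pipeline
    and the best mean AUPR wins (first in enumeration order on ties).
    """
    keys = sorted(grids)
    combos = list(itertools.product(*(grids[k] for k in keys)))
    if not combos:
        raise ParameterError("empty hyperparameter grid")
    best_cfg, best_score = None, -np.inf
    for combo in combos:
        cfg = replace(base_nn, **dict(zip(keys, combo)))
        report = run_cv(
            views, Y, selection_cfg, fusion_cfg, gip_cfg, cfg,
            k=n_outer_folds, repeats=1, seed=seed,
        )
        logger.info("grid point %s: aupr=%.4f", dict(zip(keys, combo)), report.aupr)
        if report.aupr > best_score:
            best_cfg, best_score = cfg, report.aupr
    return best_cfg
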