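"""Drug-wise (inductive) cross-validation and ranking metrics.

The unit of splitting is the *drug molecule*, not the interaction pair:
each fold's test drugs are removed from the training network entirely,
so every test prediction is a genuine cold start. Per fold, the degree
threshold is selected by leave-one-drug-out on the training drugs, w1
is fitted on the training network, every test drug is screened against
the retained targets, and the pooled (score, label) pairs give the
fold's AUROC and AUPR.

AUROC is the Mann-Whitney statistic (probability that a random positive
outscores a random negative, ties counted 1/2). AUPR is average
precision with equal-score groups ordered pessimistically — negatives
ranked ahead of positives within a tie — so the value is deterministic
and never flattered by tie ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .chem import Fingerprint
from .errors import CSLNError, DataError
from .network import DTINetwork
from .scoring import ScoringEngine
from .training import DEFAULT_W1_GRID, fit_w1, select_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "FoldReport",
    "split_drugs",
    "auroc",
    "aupr",
    "cross_validate",
]


@dataclass(frozen=True)
class FoldReport:
    """Metrics and fitted parameters for one cross-validation fold."""

    fold_index: int
    auroc: float
    aupr: float
    n_test_drugs: int
    n_pairs: int
    theta: int
    w1: float


def split_drugs(drug_ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Partition drugs into k folds of near-equal size, seeded.

    Every drug appears in exactly one fold; fold sizes differ by at
    most one; the partition is deterministic given the seed.
    """
    ids = list(drug_ids)
    if k < 2 or k > len(ids):
        raise DataError(f"k must be in [2, {len(ids)}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return folds


def _check_binary(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be 0/1")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney formulation).

    Equals the probability that a uniformly chosen positive scores
    higher than a uniformly chosen negative, with ties counted 1/2.
    Requires at least one positive and one negative.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise DataError("scores and labels differ in length")
    _check_binary(y)
    if y.sum() == 0 or y.sum() == y.size:
        raise DataError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(y, s))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision with pessimistic (worst-case) tie ordering.

    Items are ranked by score descending; within an equal-score group
    negatives are placed first, so tied positives receive the lowest
    precision consistent with the scores. AP = mean over positives of
    precision at that positive's rank.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise DataError("scores and labels differ in length")
    _check_binary(y)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise DataError("AUPR needs at least one positive")
    # sort by (-score, label): ties put label 0 before label 1
    order = np.lexsort((y, -s))
    y_sorted = y[order]
    ranks = np.arange(1, y.size + 1)
    cum_pos = np.cumsum(y_sorted)
    prec_at_pos = cum_pos[y_sorted == 1] / ranks[y_sorted == 1]
    return float(prec_at_pos.sum() / n_pos)


def _drop_drugs(net: DTINetwork, drop: set[str]) -> DTINetwork:
    keep = [i for i, d in enumerate(net.drug_ids) if d not in drop]
    return DTINetwork(
        drug_ids=tuple(net.drug_ids[i] for i in keep),
        target_ids=net.target_ids,
        adjacency=net.adjacency[keep, :].copy(),
    )


def cross_validate(
    net: DTINetwork,
    fingerprints: Mapping[str, Fingerprint],
    k: int = 10,
    seed: int = 0,
    *,
    theta_candidates: Sequence[int] = (2, 3, 4, 5),
    w1_grid: Sequence[float] = DEFAULT_W1_GRID,
    neg_ratio: float = 1.0,
    metric: str = "auroc",
    cosine_variant: str = "standard",
    per_drug_average: bool = False,
    collect_pairs: bool = False,
) -> tuple[list[FoldReport], dict]:
    """Drug-wise k-fold cross-validation of the full CSLN pipeline.

    Per fold: the test drugs' rows are removed from the training
    network; theta is selected by leave-one-drug-out on the training
    drugs and w1 fitted at that theta; each test drug is scored fresh
    against the targets retained at theta; (score, label) pairs are
    pooled within the fold (or averaged per drug when
    ``per_drug_average``). Labels come from the original adjacency.

    Returns the per-fold reports and an aggregate dict with mean and sd
    of both metrics (plus raw pairs per fold if ``collect_pairs``).
    """
    folds = split_drugs(net.drug_ids, k, seed)
    reports: list[FoldReport] = []
    dumped: list[list[tuple[str, str, float, int]]] = []
    for fi, test_drugs in enumerate(folds):
        train_net = _drop_drugs(net, set(test_drugs))
        try:
            theta, _ = select_threshold(
                train_net,
                fingerprints,
                w1_grid=w1_grid,
                theta_candidates=theta_candidates,
                metric=metric,
                seed=seed + fi,
                neg_ratio=neg_ratio,
                cosine_variant=cosine_variant,
            )
            w1, _ = fit_w1(
                train_net, fingerprints, theta, w1_grid, neg_ratio, seed + fi,
                cosine_variant,
            )
        except CSLNError as exc:
            warnings.warn(f"fold {fi}: {exc}; skipped", stacklevel=2)
            continue
        engine = ScoringEngine(train_net, fingerprints)
        pairs: list[tuple[str, str, float, int]] = []
        for drug in test_drugs:
            i = net.drug_index(drug)
            rows, _ = engine.score_query(
                fingerprints[drug], w1=w1, theta=theta, variant=cosine_variant
            )
            for tid, _, _, _, _, score in rows:
                label = int(net.adjacency[i, net.target_index(tid)])
                pairs.append((drug, tid, score, label))
        labels = np.array([p[3] for p in pairs])
        scores = np.array([p[2] for p in pairs])
        if labels.size == 0 or labels.sum() == 0 or labels.sum() == labels.size:
            warnings.warn(
                f"fold {fi}: no usable (score,label) pairs; skipped", stacklevel=2
            )
            continue
        if per_drug_average:
            au_list, ap_list = [], []
            for drug in test_drugs:
                mask = np.array([p[0] == drug for p in pairs])
                ly, ls = labels[mask], scores[mask]
                if ly.size and 0 < ly.sum() < ly.size:
                    au_list.append(auroc(ls, ly))
                    ap_list.append(aupr(ls, ly))
            if not au_list:
                warnings.warn(f"fold {fi}: no per-drug metrics; skipped", stacklevel=2)
                continue
            fold_auroc = float(np.mean(au_list))
            fold_aupr = float(np.mean(ap_list))
        else:
            fold_auroc = auroc(scores, labels)
            fold_aupr = aupr(scores, labels)
        reports.append(
            FoldReport(
                fold_index=fi,
                auroc=fold_auroc,
                aupr=fold_aupr,
                n_test_drugs=len(test_drugs),
                n_pairs=len(pairs),
                theta=theta,
                w1=w1,
            )
        )
        if collect_pairs:
            dumped.append(pairs)
    if not reports:
        raise CSLNError("no fold produced usable metrics")
    au = np.array([r.auroc for r in reports])
    ap = np.array([r.aupr for r in reports])
    aggregate = {
        "auroc_mean": float(au.mean()),
        "auroc_sd": float(au.std(ddof=1)) if au.size > 1 else 0.0,
        "aupr_mean": float(ap.mean()),
        "aupr_sd": float(ap.std(ddof=1)) if ap.size > 1 else 0.0,
        "n_folds": len(reports),
    }
    if collect_pairs:
        aggregate["pairs"] = dumped
    return reports, aggregate
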