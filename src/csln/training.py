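"""Model fitting: the global weight w1 and the degree threshold.

w1 weights the cosine channel against the local-network ratio in the
binding score. It is fitted by minimising the summed absolute residual
Error = sum_i |y_i - yhat_i| over training pairs, where y is the 0/1
interaction label and yhat the raw binding score. The objective is
piecewise linear in w1, so an exhaustive grid search (default step
0.01) is exact at grid granularity and fully reproducible; no
stochastic optimiser is involved.

Training pairs are every observed edge (label 1) plus a seeded uniform
sample of non-edges (label 0, ``neg_ratio`` per positive). For each
pair the drug is *excluded* from the target's profile and local network
before scoring — the leave-one-out contract that prevents a positive
pair from scoring itself through its own fingerprint.

The degree threshold theta is selected per training set by
leave-one-drug-out: every drug in turn has its edges deleted, is scored
as if fresh against the targets retained at theta, and the pooled
(score, label) pairs yield one AUROC (or AUPR) per candidate theta.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import Fingerprint
from .errors import CSLNError, DataError
from .network import DTINetwork
from .scoring import COSINE_VARIANTS, ScoringEngine

logger = logging.getLogger(__name__)

DEFAULT_W1_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 101) / 100, 2))

__all__ = [
    "CSLNModel",
    "DEFAULT_W1_GRID",
    "training_error",
    "fit_w1",
    "select_threshold",
]


@dataclass(frozen=True)
class CSLNModel:
    """Trained CSLN parameters plus provenance.

    w1 in [0, 1] weights the cosine score; theta >= 2 is the minimum
    target degree for scoreability; ``training_error`` is the Error
    value w1 achieved on its training pairs.
    """

    w1: float
    theta: int
    cosine_variant: str = "standard"
    training_error: float = float("nan")
    selection_metric: str = "auroc"
    seed: int = 0
    grid: tuple[float, ...] = field(default=DEFAULT_W1_GRID)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise DataError(f"w1 must be in [0, 1], got {self.w1}")
        if self.theta < 2:
            raise DataError(f"theta must be >= 2, got {self.theta}")
        if self.cosine_variant not in COSINE_VARIANTS:
            raise DataError(f"unknown cosine variant {self.cosine_variant!r}")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["grid"] = list(doc["grid"])
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CSLNModel":
        doc = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise DataError(f"unknown model fields in {path}: {sorted(unknown)}")
        doc["grid"] = tuple(doc.get("grid", DEFAULT_W1_GRID))
        return cls(**doc)


def training_error(predictions: Sequence[float], labels: Sequence[int]) -> float:
    """Summed absolute residual: Error = sum_i |y_i - yhat_i|."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise DataError(
            f"predictions and labels differ in length: {p.size} vs {y.size}"
        )
    return float(np.abs(y - p).sum())


def _training_pairs(
    net: DTINetwork, neg_ratio: float, seed: int
) -> list[tuple[int, int, int]]:
    """(drug_idx, target_idx, label) pairs: all edges + sampled non-edges."""
    pos = np.argwhere(net.adjacency == 1)
    pairs = [(int(i), int(j), 1) for i, j in pos]
    n_neg = int(round(neg_ratio * len(pairs)))
    if n_neg > 0:
        neg = np.argwhere(net.adjacency == 0)
        rng = np.random.default_rng(seed)
        take = rng.choice(len(neg), size=min(n_neg, len(neg)), replace=False)
        pairs += [(int(neg[t][0]), int(neg[t][1]), 0) for t in take]
    return pairs


def _pair_components(
    engine: ScoringEngine, pairs, theta: int, variant: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scos and S2/S1 for each scoreable (drug, target, label) pair.

    The pair's drug is excluded from the target's members. Pairs whose
    target drops below two members, below theta, or has S1 == 0 after
    exclusion are dropped.
    """
    net = engine.net
    scos_l, ratio_l, label_l = [], [], []
    q_norms = np.linalg.norm(engine.F, axis=1)
    q_l1 = engine.F.sum(axis=1).astype(np.float64)
    for i, j, label in pairs:
        members = np.flatnonzero(net.adjacency[:, j])
        members = members[members != i]
        x = members.size
        if x < 2 or x < theta:
            continue
        sub = engine.TN[np.ix_(members, members)]
        pair_sum = float(sub[np.triu_indices(x, k=1)].sum())
        s1 = pair_sum / (x * (x - 1) / 2)
        if s1 == 0.0:
            continue
        s2 = (pair_sum + float(engine.TN[members, i].sum())) / (x * (x + 1) / 2)
        counts = engine.F[members].sum(axis=0).astype(np.float64)
        dot = float(counts @ engine.F[i])
        if variant == "standard":
            denom = float(np.linalg.norm(counts)) * float(q_norms[i])
        else:
            denom = float(np.sqrt(counts.sum())) * float(np.sqrt(q_l1[i]))
        scos = dot / denom if denom else 0.0
        scos_l.append(scos)
        ratio_l.append(s2 / s1)
        label_l.append(label)
    return (
        np.asarray(scos_l, dtype=np.float64),
        np.asarray(ratio_l, dtype=np.float64),
        np.asarray(label_l, dtype=np.float64),
    )


def fit_w1(
    net: DTINetwork,
    fingerprints: Mapping[str, Fingerprint],
    theta: int,
    grid: Sequence[float] = DEFAULT_W1_GRID,
    neg_ratio: float = 1.0,
    seed: int = 0,
    cosine_variant: str = "standard",
) -> tuple[float, float]:
    """Grid-search w1 minimising the absolute-error objective.

    Returns ``(w1, error)``; ties in Error are broken toward the larger
    w1. Deterministic given (net, fingerprints, grid, neg_ratio, seed).
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise DataError("empty w1 grid")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise DataError("w1 grid values must lie in [0, 1]")
    engine = ScoringEngine(net, fingerprints)
    pairs = _training_pairs(net, neg_ratio, seed)
    scos, ratio, labels = _pair_components(engine, pairs, theta, cosine_variant)
    if labels.size == 0:
        raise CSLNError("no scoreable training pairs at this threshold")
    best_w1, best_err = None, np.inf
    for w in grid:
        err = float(np.abs(labels - (w * scos + (1 - w) * ratio)).sum())
        if err < best_err or (err == best_err and best_w1 is not None and w > best_w1):
            best_w1, best_err = w, err
    return best_w1, best_err


def _loo_pairs(
    engine: ScoringEngine, theta: int, w1: float, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-drug-out pooled (score, label) pairs at threshold theta.

    Each drug in turn is treated as fresh: its edges are removed, target
    degrees are recomputed, and it is scored against every target still
    at degree >= theta. Labels come from the drug's held-out row.
    """
    net = engine.net
    scores, labels = [], []
    for i, drug in enumerate(net.drug_ids):
        rows, _ = engine.score_query(
            Fingerprint(bits=engine.F[i].astype(np.uint8), molecule_id=drug),
            w1=w1,
            theta=theta,
            variant=variant,
            exclude_drug=drug,
        )
        for tid, _, _, _, _, score in rows:
            scores.append(score)
            labels.append(int(net.adjacency[i, net.target_index(tid)]))
    return np.asarray(scores), np.asarray(labels)


def select_threshold(
    net: DTINetwork,
    fingerprints: Mapping[str, Fingerprint],
    w1_grid: Sequence[float] = DEFAULT_W1_GRID,
    theta_candidates: Sequence[int] = (2, 3, 4, 5),
    metric: str = "auroc",
    seed: int = 0,
    neg_ratio: float = 1.0,
    cosine_variant: str = "standard",
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the degree threshold by leave-one-drug-out performance.

    For each candidate theta, w1 is first fitted on the theta-filtered
    network, then every drug is held out in turn and scored as fresh;
    the pooled (score, label) pairs give one metric value per theta.
    Returns the best theta (ties toward the smaller value) and the full
    (theta, metric) curve for diagnostics.
    """
    from .evaluation import auroc, aupr  # local import to avoid a cycle

    if metric not in ("auroc", "aupr"):
        raise DataError(f"metric must be 'auroc' or 'aupr', got {metric!r}")
    metric_fn = auroc if metric == "auroc" else aupr
    if any(t < 2 for t in theta_candidates):
        raise DataError("all theta candidates must be >= 2")
    engine = ScoringEngine(net, fingerprints)
    curve: list[tuple[int, float]] = []
    for theta in theta_candidates:
        if not (net.target_degrees() >= theta).any():
            warnings.warn(f"theta={theta} leaves no targets; skipped", stacklevel=2)
            continue
        try:
            w1, _ = fit_w1(
                net, fingerprints, theta, w1_grid, neg_ratio, seed, cosine_variant
            )
        except CSLNError:
            warnings.warn(f"theta={theta}: no scoreable pairs; skipped", stacklevel=2)
            continue
        scores, labels = _loo_pairs(engine, theta, w1, cosine_variant)
        if labels.size == 0 or len(set(labels.tolist())) < 2:
            warnings.warn(
                f"theta={theta}: degenerate LOO label set; skipped", stacklevel=2
            )
            continue
        curve.append((int(theta), float(metric_fn(scores, labels))))
    if not curve:
        raise CSLNError("no usable threshold candidate")
    best_theta = max(curve, key=lambda tv: (tv[1], -tv[0]))[0]
    return best_theta, curve
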