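"""Single-sample rank-based signature scoring and kNN subtype transfer.

Each sample is scored against each subtype signature using a rank-only
statistic: genes are ranked ascending within the sample (average ties) and
the mean rank of the signature's up set is mapped to [-0.5, +0.5], with 0
meaning the set sits at the middle of the transcriptome; the down set is
scored the same way on reversed ranks and the two components are summed.
Because only within-sample ranks enter, the score is invariant to any
monotone transform of a sample's expression values and needs no
between-sample normalization.

Unlabeled tumors are then assigned to the subtype of the majority of their
k nearest labeled neighbors in (standardized) score space. Distances are
Euclidean and ties are broken deterministically by training sample id, so
assignments never depend on input ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .signatures import GeneSignature

log = logging.getLogger(__name__)


def _set_component(mean_rank: float, m: int, n: int) -> float:
    # mean rank of m genes among n, mapped so the minimum attainable mean
    # rank (m+1)/2 gives -0.5 and the maximum (2n-m+1)/2 gives +0.5
    if m == n:
        return 0.0
    return (mean_rank - (m + 1) / 2.0) / (n - m) - 0.5


def rank_score(expression: pd.Series, signature: GeneSignature,
               warn_missing: bool = True) -> float:
    """Score one sample against one signature; sum of up and down parts.

    Signature genes absent from the expression vector are dropped (with a
    warning); an up set spanning the whole transcriptome is degenerate and
    contributes 0. Scores lie in [-1, 1] when both sets are present,
    [-0.5, 0.5] with a single set.
    """
    n = len(expression)
    ranks = pd.Series(rankdata(expression.to_numpy(dtype=float)),
                      index=expression.index)
    score = 0.0
    for direction, genes in (("up", signature.up), ("down", signature.down)):
        if not genes:
            continue
        present = [g for g in genes if g in ranks.index]
        if warn_missing and len(present) < len(genes):
            log.warning("signature %s/%s: %d gene(s) missing from expression",
                        signature.subtype, direction, len(genes) - len(present))
        if not present:
            continue
        r = ranks[present].to_numpy()
        if direction == "down":
            r = n + 1 - r
        if len(present) == n:
            log.warning("signature %s/%s spans the whole transcriptome; "
                        "degenerate score 0", signature.subtype, direction)
        score += _set_component(float(r.mean()), len(present), n)
    return score


def score_matrix(expression: pd.DataFrame,
                 signatures: dict[str, GeneSignature]) -> pd.DataFrame:
    """Score every sample (column) against every signature.

    Returns samples x subtypes. Columns follow sorted subtype order. An
    all-constant sample gets uniform tied ranks, hence score 0 (flagged).
    """
    usable = {s: sig for s, sig in signatures.items() if sig.usable}
    if not usable:
        raise ValueError("no usable signatures to score against")
    vals = expression.to_numpy(dtype=float)
    n = vals.shape[0]
    ranks = rankdata(vals, axis=0)
    constant = np.all(vals == vals[0, :], axis=0)
    if constant.any():
        log.warning("%d all-constant sample(s); scores are 0",
                    int(constant.sum()))
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    out = {}
    for s in sorted(usable):
        sig = usable[s]
        col = np.zeros(vals.shape[1])
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            present = [gene_pos[g] for g in genes if g in gene_pos]
            if len(present) < len(genes):
                log.warning("signature %s/%s: %d gene(s) missing",
                            s, direction, len(genes) - len(present))
            m = len(present)
            if m == 0 or m == n:
                continue
            r = ranks[present, :]
            if direction == "down":
                r = n + 1 - r
            col += (r.mean(axis=0) - (m + 1) / 2.0) / (n - m) - 0.5
        out[s] = col
    return pd.DataFrame(out, index=expression.columns)


def knn_assign(train_scores: pd.DataFrame, train_labels: pd.Series,
               test_scores: pd.DataFrame, k: int = 30,
               standardize: bool = True) -> pd.DataFrame:
    """k-nearest-neighbor label transfer in signature-score space.

    Score dimensions are standardized with the training mean/sd (signature
    sets differ in size, hence in score variance). The per-class
    probability is the unweighted fraction of the k nearest training
    samples carrying that label, so probabilities are exact multiples of
    1/k; the assignment is the argmax, with ties between classes broken by
    the class of the nearest neighbor among the tied classes. Equal
    distances are ordered by training sample id.
    """
    if k < 1 or k > len(train_scores):
        raise ValueError(f"k must be in 1..{len(train_scores)}, got {k}")
    if list(train_scores.columns) != list(test_scores.columns):
        raise ValueError("train and test score dimensions differ")
    labels = train_labels.loc[train_scores.index].astype(str)
    classes = sorted(labels.unique())

    xtr = train_scores.to_numpy(dtype=float)
    xte = test_scores.to_numpy(dtype=float)
    if standardize:
        mu = xtr.mean(axis=0)
        sd = xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xtr = (xtr - mu) / sd
        xte = (xte - mu) / sd

    dist = cdist(xte, xtr)
    train_ids = train_scores.index.to_numpy(dtype=object)
    id_rank = np.argsort(np.argsort(train_ids))  # lexicographic rank of ids
    lab_arr = labels.to_numpy()

    rows = []
    for i in range(xte.shape[0]):
        order = np.lexsort((id_rank, dist[i]))[:k]
        neigh = lab_arr[order]
        counts = {c: int((neigh == c).sum()) for c in classes}
        best = max(counts.values())
        tied = [c for c in classes if counts[c] == best]
        if len(tied) == 1:
            assigned = tied[0]
        else:
            # nearest neighbor belonging to any tied class decides
            assigned = next(c for c in neigh if c in tied)
        probs = [counts[c] / k for c in classes]
        rows.append([assigned] + probs)
    out = pd.DataFrame(rows, index=test_scores.index,
                       columns=["assigned"] + [f"p_{c}" for c in classes])
    return out
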