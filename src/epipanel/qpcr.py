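"""Relative qPCR quantification (delta-delta-Ct) and adaptive FDR.

Expression fold changes are computed with the classic 2^(-ddCt) method:
per replicate, the target's cycle threshold is normalized by the
arithmetic mean Ct of the housekeeping genes (equivalent to the geometric
mean of their abundances); the condition-vs-control difference of mean
delta-Ct gives ddCt and the fold change 2^(-ddCt), with amplification
efficiency fixed at 2. Wells at the 40-cycle cap are treated as
undetected, and a comparison whose replicates are all undetected is
reported as a censored bound rather than a point estimate.

The accompanying multiple-testing procedure is the two-stage linear
step-up of Benjamini, Krieger and Yekutieli: a first BH pass at
q' = q/(1+q) estimates the number of true nulls, and a second BH pass at
q* = q'·m/(m - r1) produces the final rejections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import bh_adjust

log = logging.getLogger(__name__)

CT_CAP = 40.0

RESULT_COLUMNS = ["target", "condition", "dct_mean", "ddct", "fold",
                  "n_reps", "censored"]


class CtTableError(ValueError):
    """The Ct table is missing required structure."""


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format Ct TSV with columns condition, target, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "target", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise CtTableError(f"{path}: Ct table needs columns {sorted(required)}")
    df["ct"] = df["ct"].astype(float)
    if ((df["ct"] <= 0) | (df["ct"] > CT_CAP)).any():
        bad = df.loc[(df["ct"] <= 0) | (df["ct"] > CT_CAP)].iloc[0]
        raise CtTableError(
            f"{path}: Ct {bad['ct']} outside (0, {CT_CAP:g}] "
            f"(target {bad['target']}, condition {bad['condition']})")
    return df


def delta_delta_ct(ct_table: pd.DataFrame, housekeeping: list[str],
                   control_condition: str,
                   targets: list[str] | None = None) -> pd.DataFrame:
    """ddCt relative quantification for every (target, condition) pair.

    Per replicate: dCt = Ct(target) - mean Ct over the housekeeping genes
    of that replicate. ddCt = mean dCt(condition) - mean dCt(control);
    fold = 2^(-ddCt). Replicates missing any housekeeping measurement are
    dropped with a warning. A pair whose target wells are all at the
    40-cycle cap is flagged censored (its fold is a bound, not an
    estimate). Per-replicate folds 2^(-(dCt_rep - mean dCt(control))) are
    attached in ``rep_folds`` for downstream testing.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise CtTableError("need >= 1 housekeeping gene")
    conditions = ct_table["condition"].unique().tolist()
    if control_condition not in conditions:
        raise CtTableError(f"control condition {control_condition!r} absent")
    if targets is None:
        targets = [t for t in ct_table["target"].unique()
                   if t not in housekeeping]

    hk = ct_table[ct_table["target"].isin(housekeeping)]
    hk_counts = hk.groupby(["condition", "replicate"])["target"].nunique()
    hk_mean = hk.groupby(["condition", "replicate"])["ct"].mean()
    complete = hk_counts[hk_counts == len(housekeeping)].index
    dropped = hk_counts.index.difference(complete)
    if len(dropped):
        log.warning("%d replicate(s) dropped for missing housekeeping "
                    "measurements: %s", len(dropped), list(dropped[:5]))
    hk_mean = hk_mean.loc[complete]

    rows = []
    for target in targets:
        sub = ct_table[ct_table["target"] == target]
        if sub.empty:
            raise CtTableError(f"target {target!r} not measured")
        dct: dict[str, pd.Series] = {}
        undet: dict[str, pd.Series] = {}
        for cond, grp in sub.groupby("condition"):
            reps = grp.set_index("replicate")
            keep = [r for r in reps.index if (cond, r) in hk_mean.index]
            if not keep:
                continue
            reps = reps.loc[keep]
            dct[cond] = reps["ct"] - pd.Series(
                {r: hk_mean.loc[(cond, r)] for r in keep})
            undet[cond] = reps["ct"] >= CT_CAP
        if control_condition not in dct:
            raise CtTableError(
                f"target {target!r}: no usable control replicates")
        control_mean = float(dct[control_condition].mean())
        for cond in conditions:
            if cond not in dct:
                continue
            ddct = float(dct[cond].mean()) - control_mean
            rep_folds = 2.0 ** (-(dct[cond] - control_mean))
            censored = bool(undet[cond].all())
            if censored:
                log.warning("target %s, condition %s: all replicates "
                            "undetected; fold is a censored bound",
                            target, cond)
            rows.append({
                "target": target, "condition": cond,
                "dct_mean": float(dct[cond].mean()), "ddct": ddct,
                "fold": 2.0 ** (-ddct), "n_reps": int(len(dct[cond])),
                "censored": censored,
                "rep_folds": rep_folds.tolist(),
            })
    return pd.DataFrame(rows)


def bky_two_stage(p, q: float = 0.05) -> np.ndarray:
    """Two-stage Benjamini-Krieger-Yekutieli step-up rejection flags.

    Stage 1 runs BH at q' = q/(1+q); with r1 rejections out of m tests,
    stage 2 reruns BH at q* = q'·m/(m - r1). r1 = 0 rejects nothing,
    r1 = m rejects everything. Flags are returned in input order.
    """
    p = np.asarray(p, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    q1 = q / (1.0 + q)
    stage1 = bh_adjust(p) <= q1
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    q_star = q1 * m / (m - r1)
    return bh_adjust(p) <= q_star
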