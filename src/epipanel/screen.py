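"""Epigenetic-silencing screen, targetability calls and panel coverage.

The screen looks for genes whose promoter methylation anticorrelates with
their expression across tumors (Spearman by default, rank-robust to the
beta/logTPM scale mismatch) and whose expression is higher in normal
tissue. A gene is called hypermethylated in a tumor when any of its
promoter probes strictly exceeds that probe's maximum beta across all
normal samples; a (gene, tumor) pair is "targetable" when the gene is
hypermethylated with no copy-number loss (call >= 0) — the precondition
for reactivating the locus rather than compensating a deletion. Panel
coverage is the percentage of tumors with at least one targetable gene in
a panel, and a greedy set-cover selector orders genes by marginal coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortBundle
from .signatures import bh_adjust_with_nan

log = logging.getLogger(__name__)


def promoter_summary(methylation: pd.DataFrame, promoter_map: pd.DataFrame,
                     method: str = "mean") -> pd.DataFrame:
    """Per-gene promoter beta summary (mean or max of mapped probes).

    Missing probes are excluded pairwise; a gene whose probes are all
    missing in a sample gets a missing summary there.
    """
    if method not in ("mean", "max"):
        raise ValueError(f"method must be 'mean' or 'max', got {method!r}")
    pm = promoter_map[promoter_map["probe_id"].isin(methylation.index)]
    if pm.empty:
        raise ValueError("no promoter probes found in the methylation matrix")
    grouped = methylation.loc[pm["probe_id"]].groupby(
        pm["gene_id"].to_numpy(), sort=True)
    return grouped.mean() if method == "mean" else grouped.max()


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two equally shaped matrices.

    NaNs are handled pairwise-complete per row.
    """
    n_rows = x.shape[0]
    rho = np.full(n_rows, np.nan)
    finite = np.isfinite(x) & np.isfinite(y)
    clean = finite.all(axis=1)
    if clean.any():
        rx = stats.rankdata(x[clean], axis=1)
        ry = stats.rankdata(y[clean], axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            rho[clean] = (rx * ry).sum(axis=1) / denom
    for i in np.flatnonzero(~clean):
        mask = finite[i]
        if mask.sum() >= 3:
            res = stats.spearmanr(x[i, mask], y[i, mask])
            rho[i] = res.statistic
    return rho


def anticorrelation_screen(expression: pd.DataFrame,
                           beta_summary: pd.DataFrame,
                           annotations: pd.DataFrame,
                           rho_max: float = -0.3,
                           alpha: float = 0.05,
                           method: str = "spearman") -> pd.DataFrame:
    """Rank genes by methylation-expression anticorrelation across tumors.

    Per gene: correlation over tumors (pairwise-complete), p-value from the
    t approximation on n-2 df (two-sided), BH across genes; plus a
    one-sided Mann-Whitney test of normal expression exceeding tumor
    expression. Candidate = rho <= rho_max AND BH p < alpha AND
    normal-higher p < alpha. Genes with constant methylation or expression
    have undefined rho and are excluded (evaluable = False). The result is
    sorted by rho ascending (strongest anticorrelation first).
    """
    tumors = annotations.index[annotations["tissue"] == "tumor"]
    tumors = tumors.intersection(expression.columns)
    normals = annotations.index[annotations["tissue"] == "normal"]
    normals = normals.intersection(expression.columns)
    if len(tumors) < 10:
        raise ValueError(f"need >= 10 tumors for the screen, got {len(tumors)}")
    if len(normals) < 3:
        raise ValueError(f"need >= 3 normals for the normal-higher test, "
                         f"got {len(normals)}")
    genes = expression.index.intersection(beta_summary.index)
    ex = expression.loc[genes, tumors].to_numpy(dtype=float)
    be = beta_summary.loc[genes, tumors].to_numpy(dtype=float)
    n = len(tumors)

    if method == "spearman":
        rho = _spearman_rows(be, ex)
    elif method == "pearson":
        exc = ex - np.nanmean(ex, axis=1, keepdims=True)
        bec = be - np.nanmean(be, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            rho = np.nansum(exc * bec, axis=1) / np.sqrt(
                np.nansum(exc ** 2, axis=1) * np.nansum(bec ** 2, axis=1))
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    evaluable = np.isfinite(rho)
    p = np.where(evaluable, p, np.nan)
    p_adj = bh_adjust_with_nan(p)

    ex_n = expression.loc[genes, normals].to_numpy(dtype=float)
    mwu = stats.mannwhitneyu(ex_n, ex, axis=1, alternative="greater",
                             nan_policy="omit")
    normal_higher_p = np.asarray(mwu.pvalue, dtype=float)
    median_diff = np.nanmedian(ex_n, axis=1) - np.nanmedian(ex, axis=1)

    candidate = (evaluable
                 & (rho <= rho_max)
                 & (p_adj < alpha)
                 & (normal_higher_p < alpha))
    out = pd.DataFrame({
        "rho": rho, "p": p, "p_adj": p_adj,
        "normal_higher_p": normal_higher_p, "median_diff": median_diff,
        "evaluable": evaluable, "candidate": candidate,
    }, index=genes)
    n_excluded = int((~evaluable).sum())
    if n_excluded:
        log.warning("%d gene(s) with undefined correlation excluded", n_excluded)
    return out.sort_values("rho", kind="stable")


def call_hypermethylation(methylation: pd.DataFrame,
                          promoter_map: pd.DataFrame,
                          normal_samples, tumor_samples,
                          rule: str = "any-probe") -> pd.DataFrame:
    """Gene x tumor hypermethylation calls against the normal maxima.

    Under ``any-probe`` (default) a tumor is hypermethylated for a gene iff
    ANY promoter probe strictly exceeds that probe's maximum beta over all
    normal samples. Under ``summary`` the gene's mean-probe summary must
    exceed the summarized normal maximum. Genes with no measurable probe
    give a missing call (pandas NA).
    """
    if rule not in ("any-probe", "summary"):
        raise ValueError(f"rule must be 'any-probe' or 'summary', got {rule!r}")
    normal_samples = pd.Index(normal_samples)
    tumor_samples = pd.Index(tumor_samples)
    if len(normal_samples) < 1:
        raise ValueError("need >= 1 normal sample for hypermethylation calls")
    if rule == "summary":
        summ = promoter_summary(methylation, promoter_map, method="mean")
        thresh = summ[normal_samples].max(axis=1).to_numpy()
        tum = summ[tumor_samples].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            calls = pd.DataFrame(tum > thresh[:, None], index=summ.index,
                                 columns=tumor_samples)
        missing = np.isnan(tum) | np.isnan(thresh)[:, None]
        return calls.mask(missing).astype("boolean")

    pm = promoter_map[promoter_map["probe_id"].isin(methylation.index)]
    row_of = {p: i for i, p in enumerate(methylation.index)}
    rows = np.fromiter((row_of[p] for p in pm["probe_id"]), dtype=int)
    mn = methylation[normal_samples].to_numpy(dtype=float)[rows]
    mt = methylation[tumor_samples].to_numpy(dtype=float)[rows]
    all_nan = np.all(np.isnan(mn), axis=1)
    thresh = np.where(all_nan, np.nan,
                      np.nanmax(np.where(np.isnan(mn), -np.inf, mn), axis=1))
    with np.errstate(invalid="ignore"):
        probe_call = mt > thresh[:, None]           # strict inequality
    measurable = np.isfinite(mt) & np.isfinite(thresh)[:, None]
    gene_keys = pm["gene_id"].to_numpy()
    any_call = pd.DataFrame(probe_call, columns=tumor_samples).groupby(
        gene_keys, sort=True).any()
    any_measurable = pd.DataFrame(measurable, columns=tumor_samples).groupby(
        gene_keys, sort=True).any()
    return any_call.mask(~any_measurable).astype("boolean")


@dataclass
class TargetabilityMatrix:
    """Gene x tumor booleans: hypermethylated, no-loss, and their AND."""

    hypermethylated: pd.DataFrame
    no_loss: pd.DataFrame
    targetable: pd.DataFrame
    missing_cnv_flagged: int = 0


def targetable_matrix(hyper_calls: pd.DataFrame,
                      cnv: pd.DataFrame) -> TargetabilityMatrix:
    """Combine hypermethylation calls with a no-copy-loss filter.

    No-loss means CNV call >= 0 (GISTIC-like -1/-2 excluded). Missing CNV
    is treated as no-loss but counted in ``missing_cnv_flagged``. Missing
    hypermethylation calls propagate to a not-targetable (False) call.
    """
    genes = hyper_calls.index.intersection(cnv.index)
    samples = hyper_calls.columns.intersection(cnv.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("hypermethylation calls and CNV do not align")
    hyper = hyper_calls.loc[genes, samples]
    calls = cnv.loc[genes, samples]
    missing = int(calls.isna().sum().sum())
    if missing:
        log.warning("%d missing CNV call(s) treated as no-loss", missing)
    no_loss = calls.isna() | (calls >= 0)
    targetable = (hyper.fillna(False) & no_loss).astype(bool)
    return TargetabilityMatrix(
        hypermethylated=hyper, no_loss=no_loss.astype(bool),
        targetable=targetable, missing_cnv_flagged=missing)


@dataclass
class PanelCoverage:
    """Coverage of a gene panel: overall, per sample group, per gene."""

    panel: list[str]
    overall_pct: float
    group_pct: dict[str, float]        # NaN for empty groups (flagged)
    gene_pct: dict[str, float]         # marginal singleton coverage, overall


def panel_coverage(targetable: pd.DataFrame, groups: pd.Series,
                   panel: list[str]) -> PanelCoverage:
    """Percentage of tumors with >= 1 targetable panel gene.

    ``groups`` maps each tumor to its group; groups must partition the
    targetable columns. An empty group gets NaN coverage, never 0.
    """
    panel = list(panel)
    unknown = set(panel) - set(targetable.index)
    if unknown:
        raise ValueError(f"panel genes not in targetability matrix: "
                         f"{sorted(unknown)[:5]}")
    samples = targetable.columns
    groups = groups.reindex(samples)
    covered = (targetable.loc[panel].to_numpy(dtype=bool).any(axis=0)
               if panel else np.zeros(len(samples), dtype=bool))
    covered = pd.Series(covered, index=samples)
    overall = 100.0 * covered.mean() if len(samples) else math.nan

    group_pct: dict[str, float] = {}
    for g in sorted(groups.dropna().unique()):
        members = samples[groups == g]
        group_pct[str(g)] = (100.0 * covered[members].mean()
                             if len(members) else math.nan)
    gene_pct = {
        g: 100.0 * targetable.loc[g].astype(bool).mean() for g in panel
    }
    return PanelCoverage(panel=panel, overall_pct=float(overall),
                         group_pct=group_pct, gene_pct=gene_pct)


def greedy_panel(targetable: pd.DataFrame, groups: pd.Series,
                 max_size: int) -> tuple[list[str], pd.DataFrame]:
    """Greedy set-cover panel selection by marginal overall coverage.

    Adds at each step the gene with the greatest marginal overall coverage;
    ties go to the gene giving the higher minimum per-group coverage, then
    to the lexicographically smaller gene id. Stops at ``max_size`` genes
    or 100% coverage. Returns the ordered panel and a coverage trajectory
    (one row per addition: gene, overall and per-group coverage).
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    samples = targetable.columns
    groups = groups.reindex(samples)
    group_names = sorted(groups.dropna().unique())
    mat = targetable.to_numpy(dtype=bool)
    gene_ids = list(targetable.index)
    group_masks = {g: (groups == g).to_numpy() for g in group_names}

    covered = np.zeros(len(samples), dtype=bool)
    panel: list[str] = []
    remaining = set(range(len(gene_ids)))
    rows = []
    for _ in range(min(max_size, len(gene_ids))):
        best_key, best_gi = None, None
        for gi in sorted(remaining, key=lambda i: gene_ids[i]):
            new_cov = covered | mat[gi]
            overall = new_cov.mean()
            mins = min(
                (new_cov[m].mean() for m in group_masks.values() if m.any()),
                default=0.0)
            key = (overall, mins)
            if best_key is None or key > best_key:
                best_key, best_gi = key, gi
        assert best_gi is not None
        remaining.discard(best_gi)
        covered |= mat[best_gi]
        panel.append(gene_ids[best_gi])
        row = {"gene_id": gene_ids[best_gi],
               "overall_pct": 100.0 * covered.mean()}
        for g in group_names:
            m = group_masks[g]
            row[f"pct_{g}"] = 100.0 * covered[m].mean() if m.any() else math.nan
        rows.append(row)
        if covered.all():
            break
    return panel, pd.DataFrame(rows)


def screen_cohort(bundle: CohortBundle, rho_max: float = -0.3,
                  alpha: float = 0.05, method: str = "spearman",
                  summary_method: str = "mean") -> pd.DataFrame:
    """Convenience: promoter summary + anticorrelation screen on a bundle."""
    beta = promoter_summary(bundle.methylation, bundle.promoter_map,
                            method=summary_method)
    return anticorrelation_screen(bundle.expression, beta, bundle.annotations,
                                  rho_max=rho_max, alpha=alpha, method=method)
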