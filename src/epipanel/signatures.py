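"""Per-subtype differential-expression signatures via a moderated t-test.

The subtype signatures are derived with an empirical-Bayes moderated
two-sample t-test: per-gene pooled variances are shrunk toward a common
prior variance s0^2 with d0 prior degrees of freedom, the prior being
estimated from the ensemble of gene variances by a method of moments on
log variances. A fold-change threshold test (testing |log2 FC| > tau
rather than != 0) converts the moderated statistic into a conservative
p-value for calling genes whose effect exceeds the threshold, and
Benjamini-Hochberg step-up adjustment controls the FDR across genes.

A subtype signature is the pair of up- and down-regulated gene sets from a
one-versus-rest contrast of labeled tumors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)

MIN_PRIOR_GENES = 50


class PriorEstimationError(ValueError):
    """Too few genes to estimate the variance prior; supply a fixed prior."""


@dataclass
class VariancePrior:
    """Inverse-chi-square prior on gene variances.

    d0 is the prior degrees of freedom (math.inf for a point prior) and
    s0_sq the prior variance. d0 = 0 disables moderation entirely, giving
    the ordinary pooled-variance t-test.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 or infinite")
        if not (self.s0_sq > 0) and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class GeneSignature:
    """Up/down differential gene sets for one subtype."""

    subtype: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return (len(self.up) > 0 or len(self.down) > 0) and not (self.up & self.down)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing), by Newton."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def estimate_prior(s_sq: np.ndarray, df: np.ndarray) -> VariancePrior:
    """Method-of-moments prior from per-gene variances and residual df.

    Works on e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2), whose mean and
    excess variance identify s0^2 and d0 under the scaled-inverse-chi-square
    prior. If the excess variance is non-positive the spread of the gene
    variances is fully explained by sampling noise and d0 is infinite.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df >= 1)
    if ok.sum() < MIN_PRIOR_GENES:
        raise PriorEstimationError(
            f"need >= {MIN_PRIOR_GENES} genes with df >= 1 and positive variance "
            f"to estimate the prior (got {int(ok.sum())}); supply a fixed prior")
    s_sq, df = s_sq[ok], df[ok]
    e = np.log(s_sq) - special.digamma(df / 2.0) + np.log(df / 2.0)
    target = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if target <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(np.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                         - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def _posterior_variance(s_sq: np.ndarray, df: np.ndarray,
                        prior: VariancePrior) -> tuple[np.ndarray, np.ndarray]:
    """Shrunken variances and total df = residual + prior df."""
    if math.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq), np.full_like(df, np.inf)
    post = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
    return post, df + prior.d0


def _t_sf(x: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Upper-tail of the t distribution, Normal when df is infinite."""
    x = np.asarray(x, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), x.shape)
    out = np.empty_like(x)
    inf = np.isinf(df)
    out[inf] = stats.norm.sf(x[inf])
    out[~inf] = stats.t.sf(x[~inf], df[~inf])
    return out


def moderated_t_de(expression: pd.DataFrame,
                   group_a: list[str],
                   group_b: list[str],
                   prior: VariancePrior | None = None) -> pd.DataFrame:
    """Moderated two-sample t-test per gene for group A minus group B.

    Returns a frame indexed by gene with columns logfc, t, df_residual,
    df_total, p, p_adj (BH across genes). With prior d0 = 0 the result is
    the ordinary pooled-variance t-test; genes with zero pooled variance
    are then flagged with missing t and p. ``prior=None`` estimates the
    prior from the data.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = expression[list(group_a)].to_numpy(dtype=float)
    b = expression[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df_res = float(na + nb - 2)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s_sq = ss / df_res
    df_vec = np.full_like(s_sq, df_res)

    if prior is None:
        prior = estimate_prior(s_sq, df_vec)
    post_var, df_total = _posterior_variance(s_sq, df_vec, prior)

    scale = math.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(post_var) * scale)
    undefined = post_var <= 0
    t = np.where(undefined, np.nan, t)
    t = np.where(~undefined & (logfc == 0), 0.0, t)
    p = 2.0 * _t_sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    if undefined.any():
        log.warning("%d gene(s) with zero pooled variance and no prior: "
                    "t undefined", int(undefined.sum()))
    out = pd.DataFrame({
        "logfc": logfc, "se": np.sqrt(post_var) * scale, "t": t,
        "df_residual": df_vec, "df_total": df_total, "p": p,
    }, index=expression.index)
    out["p_adj"] = bh_adjust_with_nan(out["p"].to_numpy())
    out.attrs["prior"] = prior
    return out


def treat_pvalue(logfc, se, df_total, tau: float):
    """Fold-change threshold p-value: tests |log2 FC| > tau, not != 0.

    p = P(T >= (|logfc| - tau)/se) + P(T >= (|logfc| + tau)/se), clipped to
    (0, 1]. At tau = 0 this is the ordinary two-sided t p-value.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    logfc = np.asarray(logfc, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    lo = (np.abs(logfc) - tau) / se
    hi = (np.abs(logfc) + tau) / se
    p = _t_sf(lo, df_total) + _t_sf(hi, df_total)
    p = np.minimum(p, 1.0)
    p = np.where(p <= 0, np.finfo(float).tiny, p)
    return p if p.ndim else float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_adjust_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the non-missing entries, NaN propagated."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = bh_adjust(p[ok])
    return out


def derive_signatures(expression: pd.DataFrame,
                      labels: pd.Series,
                      logfc_threshold: float = 1.5,
                      alpha: float = 0.05,
                      prior: VariancePrior | None = None,
                      min_set_size: int = 5,
                      ) -> dict[str, GeneSignature]:
    """One-vs-rest signatures for each subtype of the labeled tumors.

    For each subtype the moderated t fit provides logFC and shrunken
    standard errors; the threshold test at tau = ``logfc_threshold`` is
    BH-adjusted across genes, and the up (down) set collects genes with
    logFC beyond +tau (-tau) at adjusted p < alpha. A direction with fewer
    than ``min_set_size`` genes is emptied: the mean-rank score of a
    one- or two-gene set is dominated by single-gene rank noise and such
    fragments degrade downstream scoring rather than inform it. A subtype
    whose up and down sets are both empty is flagged unusable with a
    warning.
    """
    labels = labels.astype(str)
    subtypes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each subtype needs >= 2 labeled tumors")
    signatures: dict[str, GeneSignature] = {}
    for s in subtypes:
        grp_a = labels.index[labels == s].tolist()
        grp_b = labels.index[labels != s].tolist()
        de = moderated_t_de(expression, grp_a, grp_b, prior=prior)
        tp = treat_pvalue(de["logfc"].to_numpy(), de["se"].to_numpy(),
                          de["df_total"].to_numpy(), logfc_threshold)
        padj = bh_adjust_with_nan(tp)
        up = set(de.index[(de["logfc"] > logfc_threshold) & (padj < alpha)])
        down = set(de.index[(de["logfc"] < -logfc_threshold) & (padj < alpha)])
        if len(up) < min_set_size:
            up = set()
        if len(down) < min_set_size:
            down = set()
        sig = GeneSignature(subtype=s, up=up, down=down)
        if not sig.usable:
            log.warning("subtype %s: empty up and down sets; signature unusable", s)
        log.info("subtype %s signature: %d up, %d down", s, len(up), len(down))
        signatures[s] = sig
    return signatures


def signatures_to_frame(signatures: dict[str, GeneSignature]) -> pd.DataFrame:
    """Flatten signatures for the TSV export (subtype, gene, direction)."""
    rows = []
    for s, sig in sorted(signatures.items()):
        for g in sorted(sig.up):
            rows.append((s, g, "up"))
        for g in sorted(sig.down):
            rows.append((s, g, "down"))
    return pd.DataFrame(rows, columns=["subtype", "gene_id", "direction"])


def signatures_from_frame(frame: pd.DataFrame) -> dict[str, GeneSignature]:
    out: dict[str, GeneSignature] = {}
    for s, grp in frame.groupby("subtype"):
        out[str(s)] = GeneSignature(
            subtype=str(s),
            up=set(grp.loc[grp["direction"] == "up", "gene_id"]),
            down=set(grp.loc[grp["direction"] == "down", "gene_id"]),
        )
    return out
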