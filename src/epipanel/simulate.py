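"""Synthetic cohorts, genomes/guides and qPCR plates with known ground truth.

The cohort generator emulates the statistical structure the downstream
analyses assume: three latent tumor subtypes separable in expression space
through subtype-specific up-regulated signature genes; a set of "silenced"
genes whose promoter methylation (beta) is high in a subset of tumors and
anticorrelates with their expression; matched normal samples with low
promoter methylation and unshifted expression; and iid categorical
copy-number calls. Beta-values are generated on the logit scale and mapped
through the inverse logit, so they land in [0, 1] by construction.

Every generator is driven by a single integer seed; sub-streams for the
cohort, genome and qPCR generators are spawned from it, so the same seed
reproduces every artifact bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortBundle, SUBTYPES, UNKNOWN


class SimulationConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortSimConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the cohort scale the analyses are designed for: 100
    tumors per subtype (300 total), 40 matched normals, 2,000 genes with
    200 signature genes per subtype shifted by 1.0 logTPM standard
    deviations, and 12 planted silenced genes each hypermethylated in 40%
    of tumors with a target methylation-expression anticorrelation of
    Spearman rho = -0.8.
    """

    n_tumors_per_subtype: int = 100
    n_normals: int = 40
    n_genes: int = 2000
    n_signature_genes: int = 200
    signature_effect: float = 1.0
    n_silenced_genes: int = 12
    silenced_fraction: float = 0.4
    anticorrelation_strength: float = 0.8
    beta_noise_sd: float = 0.5
    cnv_loss_prob: float = 0.10
    labeled_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_tumors_per_subtype, self.n_normals, self.n_genes,
                  self.n_signature_genes, self.n_silenced_genes)
        if any(c < 0 for c in counts) or self.n_tumors_per_subtype < 1:
            raise SimulationConfigError("counts must be positive")
        if 3 * self.n_signature_genes + self.n_silenced_genes > self.n_genes:
            raise SimulationConfigError(
                "signature and silenced genes exceed the number of genes")
        for name in ("silenced_fraction", "labeled_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise SimulationConfigError(f"{name} must be in (0, 1]")
        if not 0 <= self.anticorrelation_strength < 1:
            raise SimulationConfigError("anticorrelation_strength must be in [0, 1)")
        if not np.isfinite(self.signature_effect):
            raise SimulationConfigError("signature_effect must be finite")
        if not 0 <= self.cnv_loss_prob < 1:
            raise SimulationConfigError("cnv_loss_prob must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery tests."""

    subtype: pd.Series                      # tumor sample -> "1"/"2"/"3"
    signature_genes: dict[str, list[str]]   # subtype -> planted up-genes
    silenced_genes: list[str]
    hypermethylated_patients: dict[str, list[str]]  # gene -> tumor samples


# beta-value anchors on the logit scale: hypermethylated promoters sit
# around beta = 0.7, unmethylated promoters around beta = 0.2
_LOGIT_HIGH = _logit(0.7)
_LOGIT_LOW = _logit(0.2)
_PROBE_NOISE_SD = 0.25
_PROBES_PER_GENE = 2


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortBundle, GroundTruth]:
    """Generate a cohort bundle and its ground truth from the config.

    Expression is baseline Normal(mu_g, 1) logTPM, with the signature effect
    added to each subtype's signature genes in that subtype's tumors. For
    each planted silenced gene, a random fraction of tumors receives high
    promoter methylation, and the gene's expression is coupled negatively to
    the methylation latent so the realized tumor-wide Spearman correlation
    reaches at least -(strength - 0.1); the coupling is strengthened and
    redrawn (bounded retries) if a draw falls short. Matched normals share
    their paired tumor's baseline, keep low methylation and an unshifted
    expression level.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    n_sub = config.n_tumors_per_subtype
    n_tumors = 3 * n_sub
    if config.n_normals > n_tumors:
        raise SimulationConfigError("more matched normals than tumors")

    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    tumors = [f"T{i:04d}" for i in range(n_tumors)]
    normals = [f"N{i:04d}" for i in range(config.n_normals)]
    subtype = pd.Series(
        np.repeat(list(SUBTYPES), n_sub), index=tumors, name="subtype")

    # disjoint planted gene sets
    perm = rng.permutation(config.n_genes)
    sig_genes: dict[str, list[str]] = {}
    pos = 0
    for s in SUBTYPES:
        sig_genes[s] = sorted(genes[perm[pos:pos + config.n_signature_genes]])
        pos += config.n_signature_genes
    silenced = sorted(genes[perm[pos:pos + config.n_silenced_genes]])
    gene_pos = {g: i for i, g in enumerate(genes)}

    mu = rng.uniform(2.0, 10.0, size=config.n_genes)
    expr_t = mu[:, None] + rng.standard_normal((config.n_genes, n_tumors))
    for s in SUBTYPES:
        rows = [gene_pos[g] for g in sig_genes[s]]
        cols = np.flatnonzero((subtype == s).to_numpy())
        expr_t[np.ix_(rows, cols)] += config.signature_effect

    # matched normals: shared gene baseline with the paired tumor via a
    # small per-pair offset added to both members of the pair
    pair_offset = rng.normal(0.0, 0.2, size=config.n_normals)
    expr_n = mu[:, None] + rng.standard_normal((config.n_genes, config.n_normals))
    expr_n += pair_offset[None, :]
    expr_t[:, :config.n_normals] += pair_offset[None, :]

    # methylation latents: baseline low everywhere
    lat_t = _LOGIT_LOW + config.beta_noise_sd * rng.standard_normal(
        (config.n_genes, n_tumors))
    lat_n = _LOGIT_LOW + config.beta_noise_sd * rng.standard_normal(
        (config.n_genes, config.n_normals))

    hyper_patients: dict[str, list[str]] = {}
    n_sil_tumors = max(1, round(config.silenced_fraction * n_tumors))
    strength = config.anticorrelation_strength
    floor = -(strength - 0.1)
    for g in silenced:
        gi = gene_pos[g]
        chosen = rng.choice(n_tumors, size=n_sil_tumors, replace=False)
        hyper_patients[g] = sorted(tumors[i] for i in chosen)
        lat = np.full(n_tumors, _LOGIT_LOW, dtype=float)
        lat[chosen] = _LOGIT_HIGH
        lat = lat + config.beta_noise_sd * rng.standard_normal(n_tumors)
        lat_t[gi] = lat
        if strength > 0:
            gamma = strength / math.sqrt(1.0 - strength ** 2)
            # couple expression to methylation relative to the unmethylated
            # baseline, so silenced tumors are shifted DOWN (never up) and
            # normals stay higher on average
            z = (lat - _LOGIT_LOW) / lat.std(ddof=0)
            for _ in range(6):
                noise = rng.standard_normal(n_tumors)
                expr = mu[gi] - gamma * z + noise
                rho = _spearman(lat, expr)
                if rho <= floor:
                    break
                gamma *= 1.5
            else:
                raise SimulationConfigError(
                    f"could not realize anticorrelation {floor:.2f} for gene {g}")
            expr_t[gi] = expr

    probes, beta_rows, pm_rows = [], [], []
    lat_all = np.concatenate([lat_t, lat_n], axis=1)
    for gi, g in enumerate(genes):
        for p in range(_PROBES_PER_GENE):
            probes.append(f"cg_{g}_{p}")
            beta_rows.append(lat_all[gi] + _PROBE_NOISE_SD
                             * rng.standard_normal(lat_all.shape[1]))
            pm_rows.append((f"cg_{g}_{p}", g, int(-200 + 150 * p)))
    beta = _invlogit(np.asarray(beta_rows))

    samples = tumors + normals
    cnv_vals = rng.choice(
        CNV_CHOICES, size=(config.n_genes, len(samples)),
        p=_cnv_probs(config.cnv_loss_prob))

    n_labeled = max(2 * 3, round(config.labeled_fraction * n_tumors))
    labeled_mask = np.zeros(n_tumors, dtype=bool)
    # stratified: same labeled fraction in every subtype
    for s in SUBTYPES:
        idx = np.flatnonzero((subtype == s).to_numpy())
        take = rng.choice(idx, size=max(2, round(len(idx) * n_labeled / n_tumors)),
                          replace=False)
        labeled_mask[take] = True

    ann = pd.DataFrame(index=pd.Index(samples, name="sample_id"),
                       columns=["tissue", "matched_pair_id", "subtype_label"],
                       dtype=object)
    ann.loc[tumors, "tissue"] = "tumor"
    ann.loc[normals, "tissue"] = "normal"
    ann["matched_pair_id"] = pd.array([pd.NA] * len(ann), dtype=object)
    ann.loc[normals, "matched_pair_id"] = tumors[:config.n_normals]
    ann["subtype_label"] = UNKNOWN
    ann.loc[np.array(tumors)[labeled_mask], "subtype_label"] = \
        subtype[labeled_mask].to_numpy()

    bundle = CohortBundle(
        expression=pd.DataFrame(
            np.concatenate([expr_t, expr_n], axis=1),
            index=pd.Index(genes, name="gene_id"), columns=samples),
        methylation=pd.DataFrame(
            beta, index=pd.Index(probes, name="probe_id"), columns=samples),
        promoter_map=pd.DataFrame(
            pm_rows, columns=["probe_id", "gene_id", "tss_distance"]),
        cnv=pd.DataFrame(
            cnv_vals.astype(float), index=pd.Index(genes, name="gene_id"),
            columns=samples),
        annotations=ann,
    )
    truth = GroundTruth(
        subtype=subtype, signature_genes=sig_genes,
        silenced_genes=list(silenced),
        hypermethylated_patients=hyper_patients,
    )
    return bundle, truth


CNV_CHOICES = np.array([-2, -1, 0, 1, 2])


def _cnv_probs(loss_prob: float) -> np.ndarray:
    gain = min(0.10, (1.0 - loss_prob) / 2)
    p = np.array([loss_prob / 3, 2 * loss_prob / 3,
                  1.0 - loss_prob - gain, 0.7 * gain, 0.3 * gain])
    return p / p.sum()


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


# ---------------------------------------------------------------------------
# genome + guide fixture generation

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GenomeTruth:
    """Planted guide-binding sites: coordinates, strand and mismatch count."""

    sites: pd.DataFrame  # guide, contig, start, end, strand, mismatches
    regulatory: pd.DataFrame  # BED-like: contig, start, end, name


def simulate_genome_and_guides(
    n_contigs: int = 2,
    contig_length: int = 10_000,
    n_guides: int = 3,
    n_planted_offtargets: int = 3,
    max_planted_mismatches: int = 3,
    seed: int = 0,
    regulatory_fraction: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, GenomeTruth]:
    """Random contigs with each guide planted exactly once (0 mismatches,
    NGG PAM) plus the requested number of mutated off-target copies.

    Returns (contigs, guides table, BED feature table, truth). Planted sites
    never overlap; a bounded retry loop raises if placements are exhausted.
    """
    if contig_length < 100:
        raise SimulationConfigError("contig_length must be >= 100")
    if not 0 <= max_planted_mismatches <= 20:
        raise SimulationConfigError("max_planted_mismatches must be in 0..20")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    contigs = {
        f"chr{c + 1}": rng.choice(_BASES, size=contig_length)
        for c in range(n_contigs)
    }
    guide_rows = []
    site_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in contigs}

    def _place(length: int) -> tuple[str, int]:
        for _ in range(200):
            name = f"chr{int(rng.integers(n_contigs)) + 1}"
            pos = int(rng.integers(0, contig_length - length))
            if all(pos + length + 5 <= s or pos >= e + 5
                   for s, e in occupied[name]):
                occupied[name].append((pos, pos + length))
                return name, pos
        raise SimulationConfigError("could not place a site without overlap")

    for g in range(n_guides):
        proto = "".join(rng.choice(_BASES, size=20))
        guide_rows.append((f"g{g + 1}", proto, "NGG"))
        plants = [0] + [int(rng.integers(1, max_planted_mismatches + 1))
                        for _ in range(n_planted_offtargets)] \
            if max_planted_mismatches > 0 else [0] * (1 + n_planted_offtargets)
        for n_mm in plants:
            seq = list(proto)
            mut_pos = rng.choice(20, size=n_mm, replace=False)
            for m in mut_pos:
                seq[m] = str(rng.choice(_BASES[_BASES != seq[m]]))
            pam = str(rng.choice(_BASES)) + "GG"
            site = "".join(seq) + pam
            strand = "+" if rng.random() < 0.5 else "-"
            name, pos = _place(23)
            if strand == "+":
                contigs[name][pos:pos + 23] = list(site)
                start, end = pos, pos + 20
            else:
                contigs[name][pos:pos + 23] = list(_revcomp(site))
                start, end = pos + 3, pos + 23
            site_rows.append((f"g{g + 1}", name, start, end, strand, n_mm))

    genome = {name: "".join(arr) for name, arr in contigs.items()}
    truth_sites = pd.DataFrame(
        site_rows, columns=["guide", "contig", "start", "end", "strand",
                            "mismatches"]
    ).sort_values(["contig", "start", "strand"]).reset_index(drop=True)

    n_reg = max(1, round(regulatory_fraction * len(truth_sites)))
    reg_idx = sorted(rng.choice(len(truth_sites), size=n_reg, replace=False))
    bed = truth_sites.iloc[reg_idx][["contig", "start", "end"]].copy()
    bed["name"] = [f"reg{i + 1}" for i in range(len(bed))]
    bed = bed.reset_index(drop=True)

    guides = pd.DataFrame(guide_rows, columns=["name", "protospacer", "pam"])
    return genome, guides, bed, GenomeTruth(sites=truth_sites, regulatory=bed)


def write_fasta(contigs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[["contig", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# qPCR plate generation

CT_CAP = 40.0


def simulate_qpcr(
    targets: list[str],
    housekeeping: list[str],
    true_folds: dict[str, float],
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format Ct table for a control vs treated comparison.

    Housekeeping genes cycle around Ct 20; each target's control delta-Ct is
    drawn uniformly in [5, 12]; the treated Ct is shifted down by
    log2(true fold) plus Normal(0, ct_noise_sd) noise. Ct values are capped
    at 40 cycles and flagged undetected at the cap. Returns the table and
    the true fold per target.
    """
    if n_replicates < 2:
        raise SimulationConfigError("n_replicates must be >= 2")
    for t in targets:
        if true_folds.get(t, 1.0) <= 0:
            raise SimulationConfigError(f"true fold for {t} must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))

    rows = []
    base_dct = {t: float(rng.uniform(5.0, 12.0)) for t in targets}
    for condition in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            hk_cts = {}
            for hk in housekeeping:
                hk_cts[hk] = 20.0 + ct_noise_sd * rng.standard_normal()
                rows.append((condition, hk, rep, hk_cts[hk]))
            hk_mean = float(np.mean(list(hk_cts.values())))
            for t in targets:
                ct = hk_mean + base_dct[t]
                if condition == "treated":
                    ct -= math.log2(true_folds.get(t, 1.0))
                ct += ct_noise_sd * rng.standard_normal()
                rows.append((condition, t, rep, min(ct, CT_CAP)))
    table = pd.DataFrame(rows, columns=["condition", "target", "replicate", "ct"])
    table["undetected"] = table["ct"] >= CT_CAP
    truth = pd.Series({t: float(true_folds.get(t, 1.0)) for t in targets},
                      name="true_fold")
    return table, truth
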