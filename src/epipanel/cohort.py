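"""Containers and TSV I/O for a multi-omic tumor cohort.

The analyses in this package operate on four feature-by-sample matrices plus
a sample annotation table:

* expression — log-scale transcript abundance (logTPM), genes x samples;
* methylation — array probe beta-values in [0, 1], probes x samples;
* a promoter map linking methylation probes to the gene whose promoter
  they interrogate (optionally with a signed distance to the TSS,
  negative = upstream);
* copy number — integer GISTIC-style calls in {-2, -1, 0, +1, +2},
  genes x samples;
* annotations — tissue (tumor/normal), optional matched-pair link from a
  normal to its tumor, and a molecular subtype label (1/2/3/unknown) for
  tumors.

All files are tab-delimited UTF-8 with a header row and feature identifiers
in the first column. Missing values are written as the token ``NA`` and
carried as NaN in memory; statistics downstream exclude them pairwise.
Samples are aligned by intersection of identifiers across platforms, since
real cohorts rarely have every sample measured on every platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NA_TOKEN = "NA"
TISSUES = ("tumor", "normal")
SUBTYPES = ("1", "2", "3")
UNKNOWN = "unknown"
CNV_CALLS = (-2, -1, 0, 1, 2)

ANNOTATION_COLUMNS = ("tissue", "matched_pair_id", "subtype_label")


class TSVParseError(ValueError):
    """A cohort TSV could not be parsed; message names the file (and line)."""


class CohortValidationError(ValueError):
    """A matrix or annotation violates a cohort invariant."""


@dataclass
class CohortBundle:
    """Aligned multi-omic matrices plus per-sample annotations.

    ``expression`` and ``cnv`` are indexed by gene, ``methylation`` by probe;
    columns of all three are sample ids. ``promoter_map`` has columns
    ``probe_id``, ``gene_id`` and optional ``tss_distance`` (bp, signed,
    negative = upstream). ``annotations`` is indexed by sample id with
    columns ``tissue``, ``matched_pair_id``, ``subtype_label``.
    """

    expression: pd.DataFrame
    methylation: pd.DataFrame
    promoter_map: pd.DataFrame
    cnv: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns

    @property
    def tumors(self) -> pd.Index:
        ann = self.annotations
        return ann.index[ann["tissue"] == "tumor"].intersection(self.samples)

    @property
    def normals(self) -> pd.Index:
        ann = self.annotations
        return ann.index[ann["tissue"] == "normal"].intersection(self.samples)

    def labeled_tumors(self) -> pd.Series:
        """Subtype labels of tumors with a known label, indexed by sample."""
        ann = self.annotations.loc[self.tumors]
        known = ann["subtype_label"].astype(str)
        return known[known.isin(SUBTYPES)]


@dataclass
class ValidationReport:
    """Outcome of every cohort invariant check, with offending identifiers."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, passed, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]

    def to_text(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            status = "PASS" if ok else "FAIL"
            lines.append(f"{status}\t{name}" + (f"\t{detail}" if detail else ""))
        lines.append(f"overall\t{'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines) + "\n"


def read_feature_matrix(path: str | Path, name: str = "matrix") -> pd.DataFrame:
    """Read a feature-by-sample TSV (header row, feature ids in column 1)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0,
            na_values=[NA_TOKEN], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise TSVParseError(f"{path}: malformed {name} TSV: {exc}") from exc
    except ValueError as exc:
        raise TSVParseError(f"{path}: cannot read {name} TSV: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TSVParseError(f"{path}: non-numeric value in {name} TSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise CohortValidationError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise CohortValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_promoter_map(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        pm = pd.read_csv(path, sep="\t", dtype=str,
                         na_values=[NA_TOKEN], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TSVParseError(f"{path}: malformed promoter map TSV: {exc}") from exc
    required = {"probe_id", "gene_id"}
    if not required.issubset(pm.columns):
        raise TSVParseError(f"{path}: promoter map must have columns {sorted(required)}")
    if "tss_distance" in pm.columns:
        pm["tss_distance"] = pd.to_numeric(pm["tss_distance"], errors="coerce")
    if pm.duplicated(subset=["probe_id", "gene_id"]).any():
        bad = pm[pm.duplicated(subset=["probe_id", "gene_id"])].iloc[0]
        raise CohortValidationError(
            f"{path}: duplicate (probe, gene) pair ({bad['probe_id']}, {bad['gene_id']})")
    return pm.reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        ann = pd.read_csv(path, sep="\t", dtype=str,
                          na_values=[NA_TOKEN], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TSVParseError(f"{path}: malformed annotation TSV: {exc}") from exc
    if "sample_id" not in ann.columns:
        raise TSVParseError(f"{path}: annotation TSV must have a sample_id column")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = np.nan
    ann = ann.set_index("sample_id")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise CohortValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    ann["subtype_label"] = ann["subtype_label"].fillna(UNKNOWN)
    return ann[list(ANNOTATION_COLUMNS)]


def _check_beta_range(methylation: pd.DataFrame, source: str = "methylation") -> None:
    vals = methylation.to_numpy(dtype=float)
    bad = (vals < 0.0) | (vals > 1.0)
    if np.any(bad & np.isfinite(vals)):
        i, j = np.argwhere(bad & np.isfinite(vals))[0]
        raise CohortValidationError(
            f"{source}: beta-value {vals[i, j]:g} outside [0, 1] "
            f"(probe {methylation.index[i]}, sample {methylation.columns[j]})")


def read_cohort(expression_path, methylation_path, promoter_map_path,
                cnv_path, annotation_path) -> CohortBundle:
    """Read and align the five cohort files into a validated bundle.

    Samples are the intersection of ids across expression, methylation, CNV
    and annotation files; dropped/unmatched samples are logged. An empty
    intersection is fatal. Beta-values outside [0, 1] and CNV calls outside
    {-2..+2} raise with the offending feature and sample named.
    """
    expr = read_feature_matrix(expression_path, "expression")
    meth = read_feature_matrix(methylation_path, "methylation")
    cnv = read_feature_matrix(cnv_path, "copy-number")
    pm = read_promoter_map(promoter_map_path)
    ann = read_annotations(annotation_path)

    _check_beta_range(meth, str(methylation_path))
    _check_cnv_calls(cnv, str(cnv_path))

    shared = expr.columns.intersection(meth.columns)
    shared = shared.intersection(cnv.columns).intersection(ann.index)
    if len(shared) == 0:
        raise CohortValidationError(
            "no samples shared across expression, methylation, CNV and annotations")
    for label, cols in (("expression", expr.columns), ("methylation", meth.columns),
                        ("copy-number", cnv.columns), ("annotation", ann.index)):
        dropped = cols.difference(shared)
        if len(dropped):
            log.warning("%d %s sample(s) dropped (not on all platforms): %s%s",
                        len(dropped), label, ", ".join(dropped[:5]),
                        "..." if len(dropped) > 5 else "")
    log.info("%d samples retained", len(shared))

    bundle = CohortBundle(
        expression=expr[shared], methylation=meth[shared],
        promoter_map=pm, cnv=cnv[shared], annotations=ann.loc[shared],
    )
    return bundle


def _check_cnv_calls(cnv: pd.DataFrame, source: str = "copy-number") -> None:
    vals = cnv.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    ok = np.isin(vals, CNV_CALLS)
    if np.any(finite & ~ok):
        i, j = np.argwhere(finite & ~ok)[0]
        raise CohortValidationError(
            f"{source}: copy-number call {vals[i, j]:g} not in {CNV_CALLS} "
            f"(gene {cnv.index[i]}, sample {cnv.columns[j]})")


def write_cohort(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the five cohort TSVs; inverse of :func:`read_cohort`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "methylation": directory / "methylation.tsv",
        "promoter_map": directory / "promoter_map.tsv",
        "cnv": directory / "cnv.tsv",
        "annotations": directory / "annotations.tsv",
    }
    bundle.expression.to_csv(paths["expression"], sep="\t", na_rep=NA_TOKEN,
                             index_label="gene_id")
    bundle.methylation.to_csv(paths["methylation"], sep="\t", na_rep=NA_TOKEN,
                              index_label="probe_id")
    bundle.promoter_map.to_csv(paths["promoter_map"], sep="\t", na_rep=NA_TOKEN,
                               index=False)
    bundle.cnv.to_csv(paths["cnv"], sep="\t", na_rep=NA_TOKEN, index_label="gene_id")
    bundle.annotations.to_csv(paths["annotations"], sep="\t", na_rep=NA_TOKEN,
                              index_label="sample_id")
    return paths


def z_normalize(matrix: pd.DataFrame, axis: str = "feature"
                ) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score a matrix per feature row (or per sample column).

    Uses the sample (n-1) standard deviation. Constant rows become all-zero
    and are returned as the flagged index. Missing values stay missing and
    are excluded from the moments.
    """
    if axis not in ("feature", "sample"):
        raise ValueError(f"axis must be 'feature' or 'sample', got {axis!r}")
    mat = matrix if axis == "feature" else matrix.T
    if mat.shape[1] < 2:
        raise ValueError("z_normalize requires at least 2 observations per feature")
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    constant = mat.index[(sd == 0) | sd.isna()]
    safe_sd = sd.replace(0, np.nan)
    z = mat.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = z.loc[constant].where(mat.loc[constant].isna(), 0.0)
    if axis == "sample":
        z = z.T
    return z, constant


def validate_cohort(bundle: CohortBundle) -> ValidationReport:
    """Check every cohort invariant; reporting only, never raises."""
    rep = ValidationReport()
    expr, meth, cnv = bundle.expression, bundle.methylation, bundle.cnv
    ann, pm = bundle.annotations, bundle.promoter_map

    rep.add("expression ids unique",
            not expr.index.has_duplicates and not expr.columns.has_duplicates)
    rep.add("at least 2 samples", expr.shape[1] >= 2,
            f"{expr.shape[1]} sample(s)")
    finite = np.isfinite(expr.to_numpy(dtype=float))
    rep.add("expression values finite", bool(finite.all()),
            "" if finite.all() else
            f"gene {expr.index[np.argwhere(~finite)[0][0]]}")

    vals = meth.to_numpy(dtype=float)
    bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
    detail = ""
    if bad.any():
        i, j = np.argwhere(bad)[0]
        detail = f"probe {meth.index[i]}, sample {meth.columns[j]}"
    rep.add("beta-values in [0,1] or missing", not bad.any(), detail)
    rep.add("probe ids unique", not meth.index.has_duplicates)

    cvals = cnv.to_numpy(dtype=float)
    cbad = np.isfinite(cvals) & ~np.isin(cvals, CNV_CALLS)
    detail = ""
    if cbad.any():
        i, j = np.argwhere(cbad)[0]
        detail = f"gene {cnv.index[i]}, sample {cnv.columns[j]}, call {cvals[i, j]:g}"
    rep.add("CNV calls in {-2..+2} or missing", not cbad.any(), detail)

    unmapped = meth.index.difference(pd.Index(pm["probe_id"].unique()))
    rep.add("every probe maps to >=1 gene", len(unmapped) == 0,
            f"unmapped probes: {list(unmapped[:5])}" if len(unmapped) else "")
    rep.add("(probe, gene) pairs unique",
            not pm.duplicated(subset=["probe_id", "gene_id"]).any())

    bad_tissue = ann.index[~ann["tissue"].isin(TISSUES)]
    rep.add("tissue in {tumor, normal}", len(bad_tissue) == 0,
            f"samples: {list(bad_tissue[:5])}" if len(bad_tissue) else "")

    normals = ann[ann["tissue"] == "normal"]
    labeled_normals = normals.index[normals["subtype_label"].isin(SUBTYPES)]
    rep.add("subtype labels only on tumors", len(labeled_normals) == 0,
            f"samples: {list(labeled_normals[:5])}" if len(labeled_normals) else "")

    tumors = set(ann.index[ann["tissue"] == "tumor"])
    refs = normals["matched_pair_id"].dropna()
    bad_refs = refs.index[~refs.isin(tumors)]
    rep.add("matched normals reference an existing tumor", len(bad_refs) == 0,
            f"samples: {list(bad_refs[:5])}" if len(bad_refs) else "")

    for label, cols in (("expression", expr.columns), ("methylation", meth.columns),
                        ("CNV", cnv.columns)):
        extra = cols.difference(ann.index)
        rep.add(f"{label} samples all annotated", len(extra) == 0,
                f"unannotated: {list(extra[:5])}" if len(extra) else "")

    labels = bundle.labeled_tumors()
    counts = labels.value_counts()
    small = [s for s in counts.index if counts[s] < 2]
    rep.add("tumor count >= 2 per known subtype", len(small) == 0,
            f"subtypes: {small}" if small else "")
    return rep
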