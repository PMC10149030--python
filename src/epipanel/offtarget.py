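"""Exhaustive gRNA off-target search with bounded mismatches.

A binding site for a 20-nt protospacer is any genomic 20-mer whose
3'-adjacent 3-mer matches the PAM pattern (IUPAC, matched exactly; PAM
positions never count as mismatches) and whose Hamming distance to the
protospacer does not exceed the configured maximum (default 3). Both
strands are scanned; minus-strand hits report the forward-strand 0-based
half-open interval of the protospacer. Ambiguous genome bases (N) never
match anything. Hits can be annotated with regulatory features from a BED
track, a feature counting as "in proximity" when its interval expanded by
a window (default 2,000 bp) overlaps the hit by at least one base.

The scan is a vectorized sliding-window comparison, adequate for the
contig sizes this package targets; no index is built for human-scale
genomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

log = logging.getLogger(__name__)

# one-hot base codes; IUPAC patterns are bitmasks over them
_CODE = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_ENC = np.zeros(256, dtype=np.uint8)
for b, c in _CODE.items():
    _ENC[ord(b)] = c
    _ENC[ord(b.lower())] = c
# complement in code space: A<->T, C<->G; unknown stays 0
_COMP_CODE = np.zeros(16, dtype=np.uint8)
for b, c in _CODE.items():
    _COMP_CODE[c] = _CODE[{"A": "T", "T": "A", "C": "G", "G": "C"}[b]]

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")

HIT_COLUMNS = ["guide", "contig", "start", "end", "strand", "mismatches",
               "site_seq", "pam_seq", "features"]


class GuideError(ValueError):
    """Invalid guide definition."""


class BEDParseError(ValueError):
    """Malformed BED line; message carries file and line number."""


@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt SpCas9-style guide with an IUPAC PAM pattern (default NGG)."""

    name: str
    protospacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        if len(proto) != 20 or any(b not in _CODE for b in proto):
            raise GuideError(
                f"guide {self.name}: protospacer must be 20 nt over ACGT, "
                f"got {self.protospacer!r}")
        pam = self.pam.upper()
        if not pam or any(b not in IUPAC for b in pam):
            raise GuideError(
                f"guide {self.name}: PAM pattern {self.pam!r} is not valid IUPAC")
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", pam)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    from pyfaidx import Fasta
    fa = Fasta(str(genome), rebuild=False, build_index=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _scan_strand(codes: np.ndarray, guide_codes: np.ndarray,
                 pam_masks: np.ndarray, max_mismatches: int) -> np.ndarray:
    """Window start positions and mismatch counts on one encoded strand."""
    glen, plen = len(guide_codes), len(pam_masks)
    wlen = glen + plen
    if len(codes) < wlen:
        return np.empty((0, 2), dtype=int)
    win = sliding_window_view(codes, wlen)
    mm = (win[:, :glen] != guide_codes).sum(axis=1)
    pam_ok = np.all((win[:, glen:] & pam_masks) == win[:, glen:], axis=1) \
        & np.all(win[:, glen:] != 0, axis=1)
    keep = np.flatnonzero(pam_ok & (mm <= max_mismatches))
    return np.column_stack([keep, mm[keep]])


def find_offtargets(genome, guides, max_mismatches: int = 3) -> pd.DataFrame:
    """Scan a genome for guide binding sites within a mismatch budget.

    ``genome`` is a contig->sequence dict or a FASTA path; ``guides`` a
    GuideRNA or list of them. Returns a hit table sorted by (guide, contig,
    start, strand) with 0-based half-open forward-strand coordinates of the
    protospacer; ``site_seq``/``pam_seq`` are given as read on the hit
    strand. Contigs shorter than protospacer+PAM are skipped with a note.
    """
    if isinstance(guides, GuideRNA):
        guides = [guides]
    if not 0 <= max_mismatches <= 20:
        raise ValueError("max_mismatches must be in 0..20")
    contigs = _load_genome(genome)

    records = []
    for guide in guides:
        gcodes = _encode(guide.protospacer)
        pmask = np.array([IUPAC[b] for b in guide.pam], dtype=np.uint8)
        glen, plen = len(gcodes), len(pmask)
        for name, seq in contigs.items():
            L = len(seq)
            if L < glen + plen:
                log.info("contig %s shorter than %d bp; skipped", name,
                         glen + plen)
                continue
            fwd = _encode(seq)
            for pos, mm in _scan_strand(fwd, gcodes, pmask, max_mismatches):
                site = seq[pos:pos + glen]
                pam = seq[pos + glen:pos + glen + plen]
                records.append((guide.name, name, int(pos), int(pos + glen),
                                "+", int(mm), site.upper(), pam.upper()))
            rev = _COMP_CODE[fwd][::-1]
            for pos, mm in _scan_strand(rev, gcodes, pmask, max_mismatches):
                start = L - (pos + glen)
                end = L - pos
                site = revcomp(seq[start:end])
                pam = revcomp(seq[start - plen:start])
                records.append((guide.name, name, int(start), int(end),
                                "-", int(mm), site.upper(), pam.upper()))
    hits = pd.DataFrame(records, columns=HIT_COLUMNS[:-1])
    hits["features"] = ""
    hits = hits.sort_values(["guide", "contig", "start", "strand"],
                            kind="stable").reset_index(drop=True)
    return hits


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+name file (0-based half-open, forward strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BEDParseError(f"{path}:{lineno}: expected >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BEDParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start or start < 0:
                raise BEDParseError(f"{path}:{lineno}: invalid interval "
                                    f"[{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"feature{lineno}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


def annotate_hits(hits: pd.DataFrame, features, window_bp: int = 2000
                  ) -> pd.DataFrame:
    """Attach nearby regulatory feature names to each hit.

    ``features`` is a BED path or a frame with contig/start/end/name. A
    feature annotates a hit when its interval expanded by ``window_bp`` on
    both sides overlaps the hit interval by >= 1 bp. Hit order is retained;
    the ``features`` column holds comma-joined names (possibly empty).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    feats = features if isinstance(features, pd.DataFrame) else read_bed(features)
    trees: dict[str, IntervalTree] = {}
    for row in feats.itertuples(index=False):
        lo = max(0, int(row.start) - window_bp)
        hi = int(row.end) + window_bp
        if hi <= lo:
            continue
        trees.setdefault(str(row.contig), IntervalTree()).addi(lo, hi, row.name)
    out = hits.copy()
    annotations = []
    for row in hits.itertuples(index=False):
        tree = trees.get(str(row.contig))
        if tree is None:
            annotations.append("")
            continue
        names = sorted({iv.data for iv in tree.overlap(row.start, row.end)})
        annotations.append(",".join(names))
    out["features"] = annotations
    return out


def read_guides(path: str | Path) -> list[GuideRNA]:
    """Read a guide TSV with columns name, protospacer and optional pam."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "protospacer"}
    if not required.issubset(df.columns):
        raise GuideError(f"{path}: guide TSV must have columns {sorted(required)}")
    guides = []
    for row in df.itertuples(index=False):
        pam = getattr(row, "pam", None) or "NGG"
        guides.append(GuideRNA(name=row.name, protospacer=row.protospacer,
                               pam=pam))
    return guides


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)
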