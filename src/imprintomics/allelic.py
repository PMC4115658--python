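"""SNP lists, read strain-of-origin classification and allele counting.

Coordinates: SNP positions are 1-based (as in SNP list files); aligned read
starts are 0-based leftmost positions (SAM-like, after conversion).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import binom_upper_pvalue

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

ORIGIN_A = "strain_a"
ORIGIN_B = "strain_b"
ORIGIN_UNASSIGNED = "unassigned"
ORIGIN_CONFLICT = "conflict"


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic substitution between two strains (1-based position)."""

    chrom: str
    pos: int
    base_a: str
    base_b: str

    def __post_init__(self):
        if self.base_a not in _BASES or self.base_b not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.base_a == self.base_b:
            raise ValueError(f"identical alleles at {self.chrom}:{self.pos}")

    def inverted(self) -> "SNPRecord":
        return SNPRecord(self.chrom, self.pos, self.base_b, self.base_a)


@dataclass(frozen=True)
class ReadRecord:
    """A simplified aligned read (0-based leftmost position)."""

    chrom: str
    start: int
    strand: str
    sequence: str
    mismatches: int = 0
    quality_sum: float = 0.0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.start < 0:
            raise ValueError("negative read start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class ClassifiedRead:
    read: ReadRecord
    origin: str


class SnpIndex:
    """Position-indexed SNP set supporting range queries per chromosome."""

    def __init__(self, snps):
        by_chrom: dict[str, dict[int, SNPRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, {})[s.pos] = s
        self._lookup = by_chrom
        self._positions = {
            chrom: np.array(sorted(d), dtype=np.int64) for chrom, d in by_chrom.items()
        }

    def overlapping(self, chrom: str, start: int, end: int) -> list[SNPRecord]:
        """SNPs with 1-based pos in the 0-based half-open interval [start, end)."""
        pos = self._positions.get(chrom)
        if pos is None:
            return []
        lo = np.searchsorted(pos, start + 1, side="left")
        hi = np.searchsorted(pos, end, side="right")
        d = self._lookup[chrom]
        return [d[p] for p in pos[lo:hi]]

    def __len__(self) -> int:
        return sum(len(d) for d in self._lookup.values())


def derive_pair_snps(list_ab, list_ac):
    """Derive the B/C SNP list from A/B and A/C lists sharing strain A.

    Rules per position: present only in A/C -> copied (B carries the A base);
    present only in A/B -> inverted (the strain-B allele becomes the first
    base); present in both -> dropped (A differs from both B and C).
    Positions where the two lists disagree on the strain-A base are rejected
    and logged.
    """
    ab = {(s.chrom, s.pos): s for s in list_ab}
    ac = {(s.chrom, s.pos): s for s in list_ac}
    out = []
    for key, s in sorted(ac.items()):
        other = ab.get(key)
        if other is None:
            out.append(SNPRecord(s.chrom, s.pos, s.base_a, s.base_b))
        elif other.base_a != s.base_a:
            logger.warning(
                "inconsistent strain-A base at %s:%d (%s vs %s); record rejected",
                s.chrom, s.pos, other.base_a, s.base_a,
            )
        # shared, consistent position: excluded from the derived list
    for key, s in sorted(ab.items()):
        if key not in ac:
            out.append(s.inverted())
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def _is_ct(snp: SNPRecord) -> bool:
    return {snp.base_a, snp.base_b} == {"C", "T"}


def _is_ga(snp: SNPRecord) -> bool:
    return {snp.base_a, snp.base_b} == {"G", "A"}


def classify_read(read: ReadRecord, snps: SnpIndex, bisulfite_mode: bool = False) -> str:
    """Vote the read's origin from the SNP positions it covers.

    In bisulfite mode C/T SNPs are ignored on + reads and G/A SNPs on -
    reads (bisulfite conversion makes them uninformative).  Unanimous votes
    yield the strain; any disagreement yields ``conflict``; no usable vote
    yields ``unassigned``.
    """
    votes = set()
    for snp in snps.overlapping(read.chrom, read.start, read.end):
        if bisulfite_mode:
            if read.strand == "+" and _is_ct(snp):
                continue
            if read.strand == "-" and _is_ga(snp):
                continue
        base = read.sequence[snp.pos - 1 - read.start]
        if base == snp.base_a:
            votes.add(ORIGIN_A)
        elif base == snp.base_b:
            votes.add(ORIGIN_B)
        # other bases (errors, non-ACGT) cast no vote
    if not votes:
        return ORIGIN_UNASSIGNED
    if len(votes) > 1:
        return ORIGIN_CONFLICT
    return votes.pop()


def classify_reads(reads, snps: SnpIndex, bisulfite_mode: bool = False):
    """Classify a batch of reads; returns a list of ClassifiedRead."""
    return [ClassifiedRead(r, classify_read(r, snps, bisulfite_mode)) for r in reads]


def snp_error_pvalue(misclassified, total, error_rate: float = 0.05):
    """Upper-tail exact binomial p for H0: per-SNP error rate <= error_rate."""
    return binom_upper_pvalue(int(misclassified), int(total), error_rate)


def filter_snps_by_error(control_counts, error_rate: float = 0.05, alpha: float = 0.05):
    """Filter SNPs by misclassification in single-strain control libraries.

    ``control_counts`` maps a SNP key to ``(misclassified, total)``.  A SNP is
    removed when the upper-tail exact binomial p-value against an acceptable
    error rate of ``error_rate`` falls below ``alpha``.  SNPs with zero
    control coverage are kept (no evidence to reject).

    Returns a DataFrame with columns ``misclassified, total, pvalue, kept``
    indexed by the SNP keys.
    """
    rows = {}
    for key, (mis, tot) in control_counts.items():
        if mis > tot:
            raise ValueError(f"misclassified > total for SNP {key!r}")
        p = 1.0 if tot == 0 else binom_upper_pvalue(mis, tot, error_rate)
        rows[key] = (mis, tot, p, p >= alpha)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["misclassified", "total", "pvalue", "kept"]
    )


def deduplicate_reads(reads):
    """Keep one read per (chrom, start, strand) group.

    Within a group reads are ranked by prevalence of their exact sequence
    (descending), then summed base quality (descending), then mismatch count
    (ascending), with a final lexicographic tie-break on the sequence.
    Output order is deterministic (sorted by group key).
    """
    groups: dict[tuple, list[ReadRecord]] = {}
    for r in reads:
        groups.setdefault((r.chrom, r.start, r.strand), []).append(r)
    kept = []
    for key in sorted(groups):
        members = groups[key]
        prevalence = Counter(r.sequence for r in members)
        best = min(
            members,
            key=lambda r: (-prevalence[r.sequence], -r.quality_sum, r.mismatches, r.sequence),
        )
        kept.append(best)
    return kept


def count_alleles(
    classified,
    features: pd.DataFrame,
    mother: str,
    father: str,
    strain_a: str,
    strain_b: str,
    tissue: str = "endosperm",
    replicate: int = 1,
) -> pd.DataFrame:
    """Per-gene maternal/paternal counts from classified reads.

    Strict counting: a read contributes only if its full interval lies
    within exactly one feature's extent.  Conflict and unassigned reads are
    dropped.  ``features`` needs columns gene_id, chrom, start, end
    (0-based half-open).
    """
    if mother not in (strain_a, strain_b) or father not in (strain_a, strain_b):
        raise ValueError("cross strains must match the classified strain pair")
    origin_of = {mother: ORIGIN_A if mother == strain_a else ORIGIN_B}
    maternal_origin = origin_of[mother]

    counts = {g: [0, 0] for g in features["gene_id"]}
    feats = features[["gene_id", "chrom", "start", "end"]].to_records(index=False)
    by_chrom: dict[str, list] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)

    for cr in classified:
        if cr.origin not in (ORIGIN_A, ORIGIN_B):
            continue
        hits = [
            f.gene_id
            for f in by_chrom.get(cr.read.chrom, [])
            if f.start <= cr.read.start and cr.read.end <= f.end
        ]
        if len(hits) != 1:
            continue
        slot = 0 if cr.origin == maternal_origin else 1
        counts[hits[0]][slot] += 1

    return pd.DataFrame(
        {
            "gene_id": list(counts),
            "mother": mother,
            "father": father,
            "tissue": tissue,
            "replicate": replicate,
            "maternal_reads": [v[0] for v in counts.values()],
            "paternal_reads": [v[1] for v in counts.values()],
        }
    )


def maternal_fraction_windows(
    classified,
    windows: pd.DataFrame,
    mother_origin: str = ORIGIN_A,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Maternal read fraction per window; windows below min_reads get NaN.

    A read is assigned to every window containing its start position.
    ``windows`` needs columns chrom, start, end (0-based half-open).
    """
    if mother_origin not in (ORIGIN_A, ORIGIN_B):
        raise ValueError("mother_origin must be strain_a or strain_b")
    out = windows[["chrom", "start", "end"]].copy()
    mat = np.zeros(len(out), dtype=int)
    pat = np.zeros(len(out), dtype=int)
    rows = list(out.itertuples(index=False))
    for cr in classified:
        if cr.origin not in (ORIGIN_A, ORIGIN_B):
            continue
        for i, w in enumerate(rows):
            if w.chrom == cr.read.chrom and w.start <= cr.read.start < w.end:
                if cr.origin == mother_origin:
                    mat[i] += 1
                else:
                    pat[i] += 1
    total = mat + pat
    frac = np.where(total >= min_reads, mat / np.maximum(total, 1), np.nan)
    out["maternal_reads"] = mat
    out["paternal_reads"] = pat
    out["n_reads"] = total
    out["maternal_fraction"] = frac
    return out


def read_sam(path) -> list[ReadRecord]:
    """Ingest a coordinate-sorted SAM file into ReadRecords (optional pysam)."""
    import pysam  # local import: optional dependency

    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            qual = aln.query_qualities
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                nm = 0
            reads.append(
                ReadRecord(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    sequence=aln.query_sequence,
                    mismatches=int(nm),
                    quality_sum=float(sum(qual)) if qual is not None else 0.0,
                )
            )
    return reads
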