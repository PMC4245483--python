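"""Variant calling and classification from whole-plastome alignments.

Counting conventions: a variant is one *event* regardless of its length —
a maximal run of contiguous substituted columns is one SNP (length 1) or one
MNV (length >= 2); a maximal gap run in one row is one deletion or insertion.
The *nucleotide difference* count, by contrast, scores every non-identical
alignment column once.  Both definitions yield a distance matrix; they are
reported side by side.  Ambiguity code N never contributes to a variant or a
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, PairAlignment, align_pair
from .errors import VariantError
from .structure import (
    GeneFeature,
    PlastomeRecord,
    region_map,
    _REGION_INTERGENIC,
    _REGION_INTRON,
)

SNP = "SNP"
MNV = "MNV"
INSERTION = "insertion"
DELETION = "deletion"

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class Variant:
    """A typed difference in reference coordinates (1-based).

    For insertions ``ref_position`` is the reference base *after which* the
    bases are inserted (0 for an insertion before base 1) and ``ref_allele``
    is empty; for deletions ``ref_position`` is the first deleted base and
    ``alt_allele`` is empty.
    """

    type: str
    ref_position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        t = self.type
        r, a = self.ref_allele, self.alt_allele
        if t == SNP and not (len(r) == len(a) == 1 and r != a):
            raise VariantError(f"bad SNP {r}->{a}")
        if t == MNV and (len(r) != len(a) or len(r) < 2):
            raise VariantError(f"bad MNV {r}->{a}")
        if t == INSERTION and (r != "" or a == ""):
            raise VariantError("insertion must have empty ref allele")
        if t == DELETION and (a != "" or r == ""):
            raise VariantError("deletion must have empty alt allele")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))


@dataclass(frozen=True)
class VariantSummary:
    ref_id: str
    qry_id: str
    n_variants: int
    n_deletions: int
    n_insertions: int
    n_mnv: int
    n_snp: int
    n_transitions: int
    n_transversions: int


def call_variants(pair: PairAlignment) -> list[Variant]:
    """Call typed variants of the query relative to the reference.

    Maximal runs of contiguous substituted columns become one SNP/MNV;
    maximal gap runs in the query row become one deletion, in the reference
    row one insertion.  Indels abutting substitutions stay separate events.
    Columns involving N are inert.  Output is sorted by reference position.
    """
    r = np.frombuffer(pair.ref_row.encode(), dtype=np.uint8)
    q = np.frombuffer(pair.qry_row.encode(), dtype=np.uint8)
    gap, nn = ord(GAP), ord("N")
    rgap, qgap = r == gap, q == gap
    anyn = (r == nn) | (q == nn)
    # reference coordinate of each column (1-based; insertion columns carry
    # the position of the preceding reference base)
    refpos = np.cumsum(~rgap)
    mismatch = (~rgap) & (~qgap) & (r != q) & (~anyn)
    out: list[Variant] = []
    for start, stop in _runs(mismatch):
        ref_allele = pair.ref_row[start:stop]
        alt_allele = pair.qry_row[start:stop]
        t = SNP if stop - start == 1 else MNV
        out.append(Variant(t, int(refpos[start]), ref_allele, alt_allele))
    for start, stop in _runs(qgap):
        ref_allele = pair.ref_row[start:stop]
        if set(ref_allele) == {"N"}:
            continue
        out.append(Variant(DELETION, int(refpos[start]), ref_allele, ""))
    for start, stop in _runs(rgap):
        alt_allele = pair.qry_row[start:stop]
        if set(alt_allele) == {"N"}:
            continue
        out.append(Variant(INSERTION, int(refpos[start]), "", alt_allele))
    out.sort(key=lambda v: (v.ref_position, v.type))
    return out


def _runs(mask: np.ndarray):
    if not mask.any():
        return
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    yield from zip(starts, stops)


def classify_ts_tv(snp: Variant) -> str:
    """Transition (A<->G, C<->T) or transversion for a single SNP."""
    if snp.type != SNP:
        raise VariantError(f"classify_ts_tv needs a SNP, got {snp.type}")
    pair = frozenset((snp.ref_allele, snp.alt_allele))
    return "transition" if pair in TRANSITIONS else "transversion"


def summarize_variants(pair: PairAlignment, variants: list[Variant] | None = None) -> VariantSummary:
    if variants is None:
        variants = call_variants(pair)
    n_del = sum(v.type == DELETION for v in variants)
    n_ins = sum(v.type == INSERTION for v in variants)
    n_mnv = sum(v.type == MNV for v in variants)
    snps = [v for v in variants if v.type == SNP]
    n_ts = sum(classify_ts_tv(v) == "transition" for v in snps)
    return VariantSummary(
        ref_id=pair.ref_id,
        qry_id=pair.qry_id,
        n_variants=len(variants),
        n_deletions=n_del,
        n_insertions=n_ins,
        n_mnv=n_mnv,
        n_snp=len(snps),
        n_transitions=n_ts,
        n_transversions=len(snps) - n_ts,
    )


def nucleotide_differences(pair: PairAlignment) -> int:
    """Number of non-identical alignment columns; each gap column counts as
    one non-identical base.  Columns involving N are inert."""
    r = np.frombuffer(pair.ref_row.encode(), dtype=np.uint8)
    q = np.frombuffer(pair.qry_row.encode(), dtype=np.uint8)
    nn = ord("N")
    return int(np.count_nonzero((r != q) & (r != nn) & (q != nn)))


def distance_matrices(
    records: Sequence[PlastomeRecord],
    scoring=None,
    method: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs distance matrices over the given (normally IR-reduced)
    genomes: (variant events, nucleotide differences).  Both are symmetric
    with zero diagonals."""
    if len(records) < 2:
        raise VariantError("need at least 2 records for a distance matrix")
    ids = [r.id for r in records]
    nvar = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    ndiff = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            pair = align_pair(records[i], records[j], scoring=scoring, method=method)
            nv = len(call_variants(pair))
            nd = nucleotide_differences(pair)
            a, b = ids[i], ids[j]
            nvar.loc[a, b] = nvar.loc[b, a] = nv
            ndiff.loc[a, b] = ndiff.loc[b, a] = nd
    return nvar, ndiff


def region_distribution(
    variants: Iterable[Variant],
    features: Sequence[GeneFeature],
    genome_length: int,
) -> dict[str, float]:
    """Proportion of variants falling in coding / intron / intergenic
    regions of the reference, assigned by start position."""
    labels = region_map(genome_length, features)
    counts = {"coding": 0, "intron": 0, "intergenic": 0}
    total = 0
    for v in variants:
        pos = max(v.ref_position, 1)
        if pos > genome_length:
            raise VariantError(f"variant position {pos} outside genome of {genome_length} bp")
        lab = labels[pos - 1]
        if lab == _REGION_INTERGENIC:
            counts["intergenic"] += 1
        elif lab == _REGION_INTRON:
            counts["intron"] += 1
        else:
            counts["coding"] += 1
        total += 1
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: c / total for k, c in counts.items()}


# ---------------------------------------------------------------------------
# Output formats


def summary_table(summaries: Iterable[VariantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "taxon": s.qry_id,
                "n_variants": s.n_variants,
                "deletions": s.n_deletions,
                "insertions": s.n_insertions,
                "mnv": s.n_mnv,
                "snp": s.n_snp,
                "transitions": s.n_transitions,
                "transversions": s.n_transversions,
            }
        )
    return pd.DataFrame(rows)


def variants_to_tsv(variants: Iterable[Variant], path: str) -> None:
    """Native event table preserving empty alleles for pure indels."""
    with open(path, "w") as fh:
        fh.write("type\tref_position\tref_allele\talt_allele\tlength\n")
        for v in variants:
            fh.write(
                f"{v.type}\t{v.ref_position}\t{v.ref_allele or '.'}\t"
                f"{v.alt_allele or '.'}\t{v.length}\n"
            )


def write_vcf(
    variants: Iterable[Variant],
    ref: PlastomeRecord,
    sample_id: str,
    path: str,
) -> None:
    """Minimal VCF v4.2 against the reference taxon.  Indels are left-
    anchored on the preceding reference base per VCF convention."""
    seq = ref.sequence
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={ref.length}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Event type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: x.ref_position):
            if v.type in (SNP, MNV):
                pos, r, a = v.ref_position, v.ref_allele, v.alt_allele
            elif v.type == DELETION:
                pos = v.ref_position - 1
                anchor = seq[pos - 1] if pos >= 1 else "N"
                r, a = anchor + v.ref_allele, anchor
            else:  # insertion after ref_position
                pos = max(v.ref_position, 1)
                anchor = seq[pos - 1]
                r, a = anchor, anchor + v.alt_allele
            if pos < 1:
                continue  # indel at the very start has no anchor base
            fh.write(f"{ref.id}\t{pos}\t.\t{r}\t{a}\t.\tPASS\tTYPE={v.type}\n")
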