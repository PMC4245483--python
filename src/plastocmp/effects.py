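"""Protein-level consequences of plastome variants and clade partitioning.

Coding substitutions are evaluated by rebuilding the affected codon(s) from
the exon-concatenated, strand-corrected CDS and translating with the
bacterial/plastid genetic code (NCBI table 11, configurable).  Coding indels
whose length is not a multiple of three are frameshifts; the truncated
protein length is the number of residues preceding the first in-frame stop
of the shifted sequence.  Multi-nucleotide variants inside one codon are
evaluated as a single codon change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import PlastocmpError, VariantError
from .structure import GeneFeature, revcomp
from .variants import DELETION, INSERTION, MNV, SNP, Variant

log = logging.getLogger(__name__)

PLASTID_CODE = 11

AUSTRALIAN = "Australian"
ASIAN = "Asian"
TAXON_A = "TaxonA"


@dataclass(frozen=True)
class EffectRecord:
    variant: Variant
    gene: str | None
    region: str  # coding | intron | intergenic
    effect: str  # synonymous | nonsynonymous | frameshift | inframe_indel | composite | none
    aa_position: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    truncated_length: int | None = None
    intact_length: int | None = None
    duplicated: bool = False


def _containing_gene(pos: int, length: int, features: Sequence[GeneFeature]):
    """(gene, 'coding'|'intron') for the gene owning [pos, pos+length-1], or
    (None, 'intergenic')."""
    end = pos + length - 1
    for f in features:
        sp = f.span
        if sp.start <= pos and end <= sp.end:
            inside_exons = any(iv.start <= pos and end <= iv.end for iv in f.exons)
            if inside_exons:
                return f, "coding"
            touches_exon = any(iv.start <= end and pos <= iv.end for iv in f.exons)
            return f, "boundary" if touches_exon else "intron"
    return None, "intergenic"


def _cds_and_map(gene: GeneFeature, genome: str) -> tuple[str, dict[int, int]]:
    """Strand-corrected CDS string and genome-position -> CDS-index map."""
    plus = "".join(iv.slice(genome) for iv in gene.exons)
    positions = [p for iv in gene.exons for p in range(iv.start, iv.end + 1)]
    if gene.strand == "+":
        cds = plus
        idx = {p: i for i, p in enumerate(positions)}
    else:
        cds = revcomp(plus)
        n = len(positions)
        idx = {p: n - 1 - i for i, p in enumerate(positions)}
    return cds, idx


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_cds(cds: str, table: int = PLASTID_CODE, to_stop: bool = False) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate(table=table, to_stop=to_stop))


def variant_effect(
    variant: Variant,
    features: Sequence[GeneFeature],
    ref_genome: str,
    table: int = PLASTID_CODE,
) -> EffectRecord:
    """Predict the coding consequence of one variant against the reference.

    Intron/intergenic variants get effect ``none``; a variant spanning an
    exon boundary is flagged ``composite`` rather than silently dropped.
    """
    pos = variant.ref_position
    span = len(variant.ref_allele) if variant.type in (SNP, MNV, DELETION) else 1
    if pos < 1 and variant.type == INSERTION:
        return EffectRecord(variant, None, "intergenic", "none")
    if pos < 1 or pos + span - 1 > len(ref_genome):
        raise VariantError(f"variant at {pos} outside genome")
    gene, region = _containing_gene(max(pos, 1), span, features)
    dup = bool(gene and gene.copy == "ir_duplicated")
    if region == "intergenic" or region == "intron":
        return EffectRecord(variant, gene.name if gene else None, region, "none",
                            duplicated=dup)
    if region == "boundary":
        return EffectRecord(variant, gene.name, "coding", "composite", duplicated=dup)
    if gene.category != "protein_coding":
        return EffectRecord(variant, gene.name, "coding", "none", duplicated=dup)

    cds, idx = _cds_and_map(gene, ref_genome)
    if variant.type in (SNP, MNV):
        mut = list(cds)
        cds_positions = []
        for off, (r, a) in enumerate(zip(variant.ref_allele, variant.alt_allele)):
            gpos = pos + off
            ci = idx[gpos]
            base = a if gene.strand == "+" else _COMP1[a]
            expect = r if gene.strand == "+" else _COMP1[r]
            if cds[ci] != expect:
                raise PlastocmpError(
                    f"{gene.name}: reference allele mismatch at genome {gpos}"
                )
            mut[ci] = base
            cds_positions.append(ci)
        mut = "".join(mut)
        c0, c1 = min(cds_positions) // 3, max(cds_positions) // 3
        aa_ref = translate_cds(cds[c0 * 3 : (c1 + 1) * 3], table)
        aa_alt = translate_cds(mut[c0 * 3 : (c1 + 1) * 3], table)
        effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return EffectRecord(
            variant, gene.name, "coding", effect,
            aa_position=c0 + 1, aa_ref=aa_ref, aa_alt=aa_alt, duplicated=dup,
        )
    # indel in coding sequence
    if variant.type == DELETION:
        cds_idx = sorted(idx[p] for p in range(pos, pos + span))
        mut = "".join(c for i, c in enumerate(cds) if i not in set(cds_idx))
        ins_len = 0
    else:
        ci = idx[pos] if pos in idx else None
        alt = variant.alt_allele if gene.strand == "+" else revcomp(variant.alt_allele)
        if ci is None:
            raise PlastocmpError(f"{gene.name}: insertion anchor {pos} outside CDS")
        at = ci + 1 if gene.strand == "+" else ci
        mut = cds[:at] + alt + cds[at:]
        ins_len = len(alt)
    shift = variant.length % 3
    intact = len(translate_cds(cds, table, to_stop=True))
    if shift == 0:
        return EffectRecord(
            variant, gene.name, "coding", "inframe_indel",
            intact_length=intact, duplicated=dup,
        )
    truncated = len(translate_cds(mut, table, to_stop=True))
    return EffectRecord(
        variant, gene.name, "coding", "frameshift",
        truncated_length=truncated, intact_length=intact, duplicated=dup,
    )


def effect_summary(effects: Iterable[EffectRecord]) -> tuple[int, int, int]:
    """(n_synonymous, n_nonsynonymous, n_frameshift) over coding variants."""
    syn = nonsyn = fs = 0
    for e in effects:
        if e.effect == "synonymous":
            syn += 1
        elif e.effect == "nonsynonymous":
            nonsyn += 1
        elif e.effect == "frameshift":
            fs += 1
    return syn, nonsyn, fs


# ---------------------------------------------------------------------------
# Clade partitioning


@dataclass
class CladePartition:
    """Positions partitioned by phylogenetic origin.

    ``australian_specific`` / ``asian_specific`` hold clade-split positions
    (each clade internally uniform, the two clades differing) labelled by the
    clade whose allele the focal taxon (Taxon A analogue) shares;
    ``taxon_a_unique`` holds positions whose focal-taxon allele occurs in no
    other taxon.  The three sets are pairwise disjoint.
    """

    australian_specific: set[int] = field(default_factory=set)
    asian_specific: set[int] = field(default_factory=set)
    taxon_a_unique: set[int] = field(default_factory=set)
    n_skipped: int = 0
    table: pd.DataFrame | None = None

    @property
    def clade_specific(self) -> set[int]:
        return self.australian_specific | self.asian_specific


def clade_partition(
    allele_table: pd.DataFrame,
    clade_map: Mapping[str, str],
) -> CladePartition:
    """Partition candidate positions into clade-specific and focal-unique
    sets.

    ``allele_table``: rows indexed by reference position, one column per
    taxon, entries are allele strings (base, multi-base, or 'del'/'ins:SEQ'
    markers for indel events).  ``clade_map`` assigns each taxon to
    Australian, Asian or TaxonA; taxa missing from the map (e.g. the
    outgroup) are ignored.
    """
    taxa = [t for t in allele_table.columns if t in clade_map]
    aus = [t for t in taxa if clade_map[t] == AUSTRALIAN]
    asia = [t for t in taxa if clade_map[t] == ASIAN]
    focal = [t for t in taxa if clade_map[t] == TAXON_A]
    if len(focal) != 1 or not aus or not asia:
        raise PlastocmpError("clade map must name one TaxonA and non-empty clades")
    focal = focal[0]
    part = CladePartition()
    rows = []
    for pos, row in allele_table.iterrows():
        alleles = {t: row[t] for t in taxa}
        if any(pd.isna(v) or v == "" for v in alleles.values()):
            part.n_skipped += 1
            log.warning("position %s skipped: missing allele", pos)
            continue
        a_set = {alleles[t] for t in aus}
        s_set = {alleles[t] for t in asia}
        fa = alleles[focal]
        others = {alleles[t] for t in taxa if t != focal}
        if fa not in others:
            part.taxon_a_unique.add(pos)
            rows.append((pos, next(iter(a_set)) if len(a_set) == 1 else "·",
                         next(iter(s_set)) if len(s_set) == 1 else "·", fa, "taxon_a_unique"))
            continue
        if len(a_set) == 1 and len(s_set) == 1 and a_set != s_set:
            a, s = next(iter(a_set)), next(iter(s_set))
            if fa == a:
                part.australian_specific.add(pos)
                rows.append((pos, a, s, fa, "australian_specific"))
            elif fa == s:
                part.asian_specific.add(pos)
                rows.append((pos, a, s, fa, "asian_specific"))
    part.table = pd.DataFrame(
        rows, columns=["position", "australian_allele", "asian_allele",
                       "taxon_a_allele", "set"],
    )
    return part


def allele_table_from_matrix(matrix, ref_id: str | None = None) -> pd.DataFrame:
    """Candidate-position allele table from a multiple alignment.

    Alignment columns where taxa disagree are collected; consecutive columns
    with an identical cross-taxon pattern and the same column type (gap
    pattern) merge into one event, keyed by the reference position of its
    first column.  Gap alleles are reported as 'del'.
    """
    ref_id = ref_id or matrix.ref_id
    taxa = list(matrix.ids)
    rows = {t: matrix.rows[t] for t in taxa}
    ref_row = rows[ref_id]
    n = len(ref_row)
    refpos = []
    p = 0
    for c in ref_row:
        if c != "-":
            p += 1
        refpos.append(p)
    def signature(column):
        # taxa partitioned by allele identity, plus the gap pattern
        first = {}
        groups = []
        for c in column:
            groups.append(first.setdefault(c, len(first)))
        return tuple(groups), tuple(c == "-" for c in column)

    events = []  # [start_refpos, per-taxon allele strings, last_col]
    prev_sig = None
    for col in range(n):
        column = tuple(rows[t][col] for t in taxa)
        if len(set(column)) == 1 or "N" in column:
            prev_sig = None
            continue
        sig = signature(column)
        if prev_sig == sig and events and events[-1][2] == col - 1:
            events[-1][2] = col
            for i, c in enumerate(column):
                if c != "-":
                    events[-1][1][i] += c
        else:
            events.append([refpos[col], ["" if c == "-" else c for c in column], col])
        prev_sig = sig
    out_rows = {}
    for pos, alleles, _last in events:
        labelled = ["del" if a == "" else a for a in alleles]
        key = pos
        while key in out_rows:
            key += 0.1  # distinct events at one reference position
        out_rows[key] = labelled
    df = pd.DataFrame.from_dict(out_rows, orient="index", columns=taxa)
    df.index.name = "position"
    return df.sort_index()


def effects_table(effects: Iterable[EffectRecord]) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "position": e.variant.ref_position,
                "type": e.variant.type,
                "ref": e.variant.ref_allele or ".",
                "alt": e.variant.alt_allele or ".",
                "gene": e.gene or ".",
                "region": e.region,
                "effect": e.effect,
                "aa_position": e.aa_position if e.aa_position else ".",
                "aa_change": (
                    f"{e.aa_ref} -> {e.aa_alt}" if e.effect == "nonsynonymous" else "."
                ),
                "truncated_length": e.truncated_length if e.truncated_length else ".",
                "duplicated": e.duplicated,
            }
        )
    return pd.DataFrame(rows)
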