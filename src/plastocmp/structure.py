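"""Plastome structure: records, quadripartite detection, IR reduction,
composition and gene-inventory summaries.

A typical angiosperm chloroplast genome is a circular molecule of 120-160 kb
with a quadripartite layout: a large single-copy region (LSC, ~80 kb), a
small single-copy region (SSC, ~12 kb) and two inverted repeats (IR_A, IR_B,
~20-26 kb) that are exact reverse complements of each other.  All external
coordinates are 1-based inclusive on the LSC-first linearization; 0-based
half-open coordinates are internal only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AmbiguousStructureError,
    AnnotationConflictError,
    DuplicateIdError,
    EmptySourceError,
    IllegalCharacterError,
    PlastocmpError,
    StructureNotFoundError,
)

ALLOWED = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: default minimum inverted-repeat length (bp).  Plastid IRs are 20-26 kb;
#: 1 kb keeps tRNA-scale dispersed repeats out of consideration.
DEFAULT_MIN_IR = 1000


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise PlastocmpError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self, seq: str) -> str:
        return seq[self.start - 1 : self.end]


@dataclass(frozen=True)
class PlastomeRecord:
    """One plastome sequence with a taxon label."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.id:
            raise PlastocmpError("record id must be non-empty")
        bad = set(self.sequence) - ALLOWED
        if bad:
            raise IllegalCharacterError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Quadripartite:
    """LSC / IR_A / SSC / IR_B intervals on the LSC-first linearization.

    ``rotation_offset`` is the number of bases the input sequence had to be
    rotated left to reach that linearization (0 for canonical input).
    """

    lsc: Interval
    ir_a: Interval
    ssc: Interval
    ir_b: Interval
    rotation_offset: int = 0

    @property
    def ir_length(self) -> int:
        return len(self.ir_a)

    def validate(self, record: PlastomeRecord) -> None:
        n = sum(len(iv) for iv in (self.lsc, self.ir_a, self.ssc, self.ir_b))
        if n != record.length:
            raise PlastocmpError(
                f"quadripartite covers {n} bp but {record.id} is {record.length} bp"
            )
        if self.rotation_offset:
            raise PlastocmpError(
                "quadripartite refers to a rotated linearization; rotate the "
                "record first (rotate_record)"
            )
        seq = record.sequence
        if revcomp(self.ir_a.slice(seq)) != self.ir_b.slice(seq):
            raise PlastocmpError("IR_A is not the reverse complement of IR_B")


@dataclass(frozen=True)
class GeneFeature:
    """One gene copy: name, category, strand and exon structure."""

    name: str
    category: str  # protein_coding | tRNA | rRNA
    strand: str  # + | -
    exons: tuple[Interval, ...]
    copy: str = "single"  # single | ir_duplicated

    def __post_init__(self):
        if self.category not in ("protein_coding", "tRNA", "rRNA"):
            raise PlastocmpError(f"unknown gene category {self.category!r}")
        if self.strand not in "+-":
            raise PlastocmpError(f"bad strand {self.strand!r}")
        starts = [iv.start for iv in self.exons]
        if sorted(starts) != starts:
            raise PlastocmpError(f"{self.name}: exons not sorted")

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.exons)


@dataclass(frozen=True)
class CompositionSummary:
    """Percent-of-genome composition figures (unrounded; round at report
    time only)."""

    at_percent: float
    coding_percent: float
    protein_percent: float
    rrna_percent: float
    trna_percent: float
    intergenic_percent: float
    intron_percent: float

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: round(v, ndigits) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# FASTA input


def read_plastomes(fasta_source, circular: bool = True) -> list[PlastomeRecord]:
    """Read a (multi-)FASTA file or handle into :class:`PlastomeRecord` list.

    Lowercase input is normalized to uppercase; record order is preserved.
    Raises :class:`EmptySourceError`, :class:`DuplicateIdError` or
    :class:`IllegalCharacterError` on the corresponding defects.
    """
    if isinstance(fasta_source, (str,)):
        handle = open(fasta_source)
        close = True
    elif isinstance(fasta_source, io.IOBase) or hasattr(fasta_source, "read"):
        handle, close = fasta_source, False
    else:
        raise PlastocmpError(f"cannot read FASTA from {type(fasta_source)}")
    try:
        records = []
        seen = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                PlastomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)
            )
    finally:
        if close:
            handle.close()
    if not records:
        raise EmptySourceError("FASTA source contains no records")
    return records


def write_fasta(records: Iterable[PlastomeRecord], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular genome left by ``offset`` bases."""
    off = offset % record.length
    seq = record.sequence[off:] + record.sequence[:off]
    return PlastomeRecord(id=record.id, sequence=seq, circular=record.circular)


# ---------------------------------------------------------------------------
# Quadripartite detection


def _ir_candidates(seq: str, min_ir: int, k: int):
    """Maximal disjoint exact reverse-complement segment pairs, via unique
    k-mer seeding on anti-diagonals followed by exact extension."""
    n = len(seq)
    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmers.setdefault(seq[i : i + k], []).append(i)
    seen: dict[int, list[tuple[int, int]]] = {}
    out = []
    for i in range(n - k + 1):
        partner = revcomp(seq[i : i + k])
        for j in kmers.get(partner, ()):
            if j <= i:
                continue
            diag = i + j  # constant along one inverted-repeat pair
            if any(lo <= i < hi for lo, hi in seen.get(diag, ())):
                continue
            # extend the matched pair: seq[a:a+m] == revcomp(seq[b:b+m])
            a, b, m = i, j, k
            while a + m < n and b - 1 >= 0 and seq[a + m] == _COMP_1(seq[b - 1]):
                b -= 1
                m += 1
            while a - 1 >= 0 and b + m < n and seq[a - 1] == _COMP_1(seq[b + m]):
                a -= 1
                m += 1
            seen.setdefault(diag, []).append((a, a + m))
            if m >= min_ir:
                out.append((m, a, b))
    return out


def _COMP_1(c: str) -> str:
    return _COMP_TABLE[c]


_COMP_TABLE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def detect_quadripartite(
    record: PlastomeRecord,
    min_ir_length: int = DEFAULT_MIN_IR,
    rotate: bool = False,
    seed_k: int = 31,
) -> Quadripartite:
    """Detect the quadripartite structure of a plastome.

    Finds the maximal pair of disjoint segments that are exact reverse
    complements of each other with length >= ``min_ir_length``.  The shorter
    arc between the two repeats is the SSC, the longer the LSC, and the
    result is reported on the linearization that starts at LSC position 1.

    With ``rotate=True`` the search tolerates an arbitrary circular start
    point (a repeat copy may wrap the sequence origin); the returned
    ``rotation_offset`` says how far the input must be rotated left to match
    the reported coordinates.
    """
    n = record.length
    if n <= 2 * min_ir_length:
        raise StructureNotFoundError(
            f"{record.id}: genome ({n} bp) shorter than two repeats of {min_ir_length} bp"
        )
    k = min(seed_k, min_ir_length)
    search_seq = record.sequence + record.sequence if rotate else record.sequence
    cands = _ir_candidates(search_seq, min_ir_length, k)
    if rotate:
        # keep candidates whose IR_A copy starts in the first genome copy and
        # that do not span more than one full genome
        cands = [(m, a, b) for (m, a, b) in cands if a < n and b + m <= a + n]
    # disjoint copies only
    cands = [(m, a, b) for (m, a, b) in cands if a + m <= b]
    if not cands:
        raise StructureNotFoundError(
            f"{record.id}: no disjoint inverted repeat >= {min_ir_length} bp"
        )
    cands.sort(key=lambda t: (-t[0], t[1]))
    m, a, b = cands[0]
    key0 = frozenset({a % n, b % n})
    for m2, a2, b2 in cands[1:]:
        if m2 < m:
            break
        if frozenset({a2 % n, b2 % n}) == key0:
            continue  # same physical repeat rediscovered on the doubled sequence
        if a2 < b + m and b2 + m > a:  # genuinely overlapping alternative
            raise AmbiguousStructureError(
                f"{record.id}: two maximal repeat pairs of {m} bp overlap"
            )
    # arcs between the copies, on the circle
    mid_len = b - (a + m)
    wrap_len = n - m - m - mid_len
    if wrap_len < 0:
        raise StructureNotFoundError(f"{record.id}: repeat pair longer than genome")
    if mid_len <= wrap_len:
        ssc_len, lsc_len = mid_len, wrap_len
        lsc_start0 = (b + m) % n  # wrap arc is the LSC; it starts after IR_B
    else:
        ssc_len, lsc_len = wrap_len, mid_len
        lsc_start0 = (a + m) % n  # mid arc is the LSC; it starts after IR_A
    if ssc_len <= 0:
        raise StructureNotFoundError(
            f"{record.id}: repeat copies are adjacent (no single-copy arc); "
            "not a quadripartite structure"
        )
    offset = lsc_start0 % n
    quad = Quadripartite(
        lsc=Interval(1, lsc_len),
        ir_a=Interval(lsc_len + 1, lsc_len + m),
        ssc=Interval(lsc_len + m + 1, lsc_len + m + ssc_len),
        ir_b=Interval(lsc_len + m + ssc_len + 1, n),
        rotation_offset=0,
    )
    if offset == 0:
        quad.validate(record)
        return quad
    if not rotate:
        raise StructureNotFoundError(
            f"{record.id}: repeats found but the input is not LSC-first "
            f"linearized (rotation offset {offset}); pass rotate=True"
        )
    quad = Quadripartite(
        lsc=quad.lsc, ir_a=quad.ir_a, ssc=quad.ssc, ir_b=quad.ir_b,
        rotation_offset=offset,
    )
    rotated = rotate_record(record, offset)
    Quadripartite(quad.lsc, quad.ir_a, quad.ssc, quad.ir_b).validate(rotated)
    return quad


def reduce_single_ir(record: PlastomeRecord, quad: Quadripartite) -> PlastomeRecord:
    """Delete the IR_B copy, leaving LSC + IR_A + SSC.

    Keeps every repeat-resident site represented exactly once so downstream
    site counts are not double-weighted.
    """
    quad.validate(record)
    seq = record.sequence[: quad.ir_b.start - 1] + record.sequence[quad.ir_b.end :]
    return PlastomeRecord(id=record.id, sequence=seq, circular=False)


# ---------------------------------------------------------------------------
# Composition / inventory

_REGION_INTERGENIC = 0
_REGION_PROTEIN = 1
_REGION_RRNA = 2
_REGION_TRNA = 3
_REGION_INTRON = 4

_CAT_CODE = {"protein_coding": _REGION_PROTEIN, "rRNA": _REGION_RRNA, "tRNA": _REGION_TRNA}


def region_map(length: int, features: Sequence[GeneFeature]) -> np.ndarray:
    """Per-base region labels over the full genome (both IR copies).

    Bases inside a gene span but outside its exons are introns; exon bases
    carry the gene category; everything else is intergenic.  Overlapping
    exons of different genes raise :class:`AnnotationConflictError`.
    """
    labels = np.zeros(length, dtype=np.int8)
    owner = np.full(length, -1, dtype=np.int32)
    for gi, f in enumerate(features):
        sp = f.span
        if sp.end > length:
            raise PlastocmpError(f"{f.name}: feature exceeds genome bounds")
        seg = labels[sp.start - 1 : sp.end]
        seg[seg == _REGION_INTERGENIC] = _REGION_INTRON
    for gi, f in enumerate(features):
        code = _CAT_CODE[f.category]
        for iv in f.exons:
            sl = slice(iv.start - 1, iv.end)
            clash = (owner[sl] >= 0) & (owner[sl] != gi)
            if clash.any():
                other = features[int(owner[sl][clash][0])].name
                raise AnnotationConflictError(
                    f"exons of {f.name!r} overlap exons of {other!r}"
                )
            owner[sl] = gi
            labels[sl] = code
    return labels


def composition_summary(
    record: PlastomeRecord, features: Sequence[GeneFeature]
) -> CompositionSummary:
    """AT content and coding/intron/intergenic composition (percent of the
    full genome, both IR copies included)."""
    n = record.length
    counts = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    at = int(np.count_nonzero((counts == ord("A")) | (counts == ord("T"))))
    labels = region_map(n, features)
    frac = lambda code: float(np.count_nonzero(labels == code)) / n * 100.0
    protein, rrna, trna = frac(_REGION_PROTEIN), frac(_REGION_RRNA), frac(_REGION_TRNA)
    return CompositionSummary(
        at_percent=at / n * 100.0,
        coding_percent=protein + rrna + trna,
        protein_percent=protein,
        rrna_percent=rrna,
        trna_percent=trna,
        intergenic_percent=frac(_REGION_INTERGENIC),
        intron_percent=frac(_REGION_INTRON),
    )


def gene_inventory(features: Sequence[GeneFeature]) -> dict:
    """Totals, per-category counts, IR-duplicated entries and one-intron genes."""
    if not features:
        raise PlastocmpError("no features supplied")
    per_cat = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
    duplicated = 0
    one_intron_names = set()
    for f in features:
        per_cat[f.category] += 1
        if f.copy == "ir_duplicated":
            duplicated += 1
        if f.n_introns == 1:
            one_intron_names.add(f.name)
    return {
        "total": len(features),
        "protein_coding": per_cat["protein_coding"],
        "tRNA": per_cat["tRNA"],
        "rRNA": per_cat["rRNA"],
        "ir_duplicated_entries": duplicated,
        "ir_duplicated_pairs": duplicated // 2,
        "one_intron_genes": len(one_intron_names),
    }


# ---------------------------------------------------------------------------
# Annotation input


def read_gff3(path: str) -> list[GeneFeature]:
    """Read gene features from GFF3.

    Expects ``gene`` records with a ``biotype`` (or ``gene_biotype``)
    attribute in {protein_coding, tRNA, rRNA} and child ``exon`` features;
    a gene with no exon children is taken as a single-exon gene over its own
    span.  An optional ``copy`` attribute marks IR-duplicated entries.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for gene in db.features_of_type("gene", order_by="start"):
        name = gene.attributes.get("Name", gene.attributes.get("ID", [gene.id]))[0]
        biotype = (
            gene.attributes.get("biotype", None)
            or gene.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        copy = gene.attributes.get("copy", ["single"])[0]
        exons = [
            Interval(c.start, c.end)
            for c in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [Interval(gene.start, gene.end)]
        feats.append(
            GeneFeature(
                name=name,
                category=biotype,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(exons),
                copy=copy,
            )
        )
    if not feats:
        raise EmptySourceError(f"no gene features in {path}")
    return feats


def write_gff3(features: Sequence[GeneFeature], seqid: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            sp = f.span
            gid = f"gene{i}"
            attrs = f"ID={gid};Name={f.name};biotype={f.category};copy={f.copy}"
            fh.write(
                f"{seqid}\tplastocmp\tgene\t{sp.start}\t{sp.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            for j, iv in enumerate(f.exons):
                fh.write(
                    f"{seqid}\tplastocmp\texon\t{iv.start}\t{iv.end}\t.\t{f.strand}\t."
                    f"\tID={gid}.e{j};Parent={gid}\n"
                )


def read_genbank_features(path: str) -> tuple[PlastomeRecord, list[GeneFeature]]:
    """Read one GenBank flat file (the accession route) into a record plus
    gene features.

    Extracts the ORIGIN sequence and CDS/tRNA/rRNA features (first
    ``/gene`` qualifier as the name; ``join``/``complement`` locations
    honoured); features duplicated by name are tagged ``ir_duplicated``.
    Only gene name, category, strand and exon intervals feed this pipeline.
    """
    from Bio import SeqIO

    rec = SeqIO.read(path, "genbank")
    feats: list[GeneFeature] = []
    cat_by_type = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
    for f in rec.features:
        if f.type not in cat_by_type:
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or ["?"])[0]
        strand = "-" if f.location.strand == -1 else "+"
        exons = sorted(
            (Interval(int(p.start) + 1, int(p.end)) for p in f.location.parts),
            key=lambda iv: iv.start,
        )
        feats.append(
            GeneFeature(name=name, category=cat_by_type[f.type], strand=strand,
                        exons=tuple(exons))
        )
    names = {}
    for f in feats:
        names.setdefault((f.name, f.category), []).append(f)
    out = []
    for group in names.values():
        copy = "ir_duplicated" if len(group) > 1 else "single"
        for f in group:
            out.append(
                GeneFeature(name=f.name, category=f.category, strand=f.strand,
                            exons=f.exons, copy=copy)
            )
    out.sort(key=lambda f: f.span.start)
    record = PlastomeRecord(
        id=rec.id or rec.name, sequence=str(rec.seq).upper(), circular=True
    )
    return record, out


def structure_report(
    records: Sequence[PlastomeRecord], min_ir_length: int = DEFAULT_MIN_IR
) -> "pandas.DataFrame":
    """Quadripartite interval table for a set of plastomes (TSV-ready)."""
    import pandas as pd

    rows = []
    for rec in records:
        q = detect_quadripartite(rec, min_ir_length)
        rows.append(
            dict(
                taxon=rec.id,
                length=rec.length,
                ir_length=q.ir_length,
                reduced_length=rec.length - q.ir_length,
                lsc_start=q.lsc.start, lsc_end=q.lsc.end,
                ira_start=q.ir_a.start, ira_end=q.ir_a.end,
                ssc_start=q.ssc.start, ssc_end=q.ssc.end,
                irb_start=q.ir_b.start, irb_end=q.ir_b.end,
            )
        )
    return pd.DataFrame(rows)
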