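"""Pairwise plastome alignment and reference-pivot multiple alignment.

Plastomes of congeneric species are collinear and nearly identical, so a
whole-genome aligner does not need rearrangement handling: unique shared
k-mers are chained colinearly and the short inter-anchor segments are closed
with exact affine-gap dynamic programming.  A full-DP path is used outright
for small inputs, where it is guaranteed optimal.

Scoring convention: match +1, mismatch -1, and a gap of length L scores
-(4 + L) (open -4, extend -1 per gap column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import AlignmentError
from .structure import PlastomeRecord

GAP = "-"

#: inputs at or below this size are aligned with full dynamic programming
EXACT_SIZE_CAP = 5000
#: largest input for which the no-anchor fallback still runs full DP
FALLBACK_SIZE_CAP = 20000
DEFAULT_ANCHOR_K = 21


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1

    def score_columns(self, row_a: str, row_b: str) -> int:
        """Score a gapped alignment under this scheme (gap run of length L
        costs ``gap_open + L * gap_extend``)."""
        s = 0
        in_gap_a = in_gap_b = False
        for x, y in zip(row_a, row_b):
            if x == GAP:
                s += self.gap_extend + (0 if in_gap_a else self.gap_open)
                in_gap_a, in_gap_b = True, False
            elif y == GAP:
                s += self.gap_extend + (0 if in_gap_b else self.gap_open)
                in_gap_b, in_gap_a = True, False
            else:
                s += self.match if x == y else self.mismatch
                in_gap_a = in_gap_b = False
        return s


@dataclass(frozen=True)
class PairAlignment:
    """A global alignment of a query against a reference."""

    ref_id: str
    qry_id: str
    ref_row: str
    qry_row: str
    score: int

    def __post_init__(self):
        if len(self.ref_row) != len(self.qry_row):
            raise AlignmentError("alignment rows differ in length")

    @property
    def ref_seq(self) -> str:
        return self.ref_row.replace(GAP, "")

    @property
    def qry_seq(self) -> str:
        return self.qry_row.replace(GAP, "")

    def swapped(self) -> "PairAlignment":
        return PairAlignment(self.qry_id, self.ref_id, self.qry_row, self.ref_row, self.score)


def _biopython_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # biopython charges open for the first gap column and extend thereafter;
    # our convention charges open + extend for the first column
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _dp_align(a: str, b: str, scoring: Scoring) -> tuple[str, str]:
    if not a:
        return GAP * len(b), b
    if not b:
        return a, GAP * len(a)
    aln = _biopython_aligner(scoring).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def normalize_gaps(row_a: str, row_b: str) -> tuple[str, str]:
    """Left-shift every gap run while the flanking letters in the opposite
    row are equal.  Deterministic tie-breaking; degapped sequences and the
    alignment score are invariant."""
    A, B = list(row_a), list(row_b)

    def shift(gapped, other):
        n = len(gapped)
        i = 0
        while i < n:
            if gapped[i] != GAP:
                i += 1
                continue
            j = i
            while j < n and gapped[j] == GAP:
                j += 1
            # gap run [i, j); slide left while the letter leaving the run's
            # left flank can re-pair identically at its right flank
            while (
                i > 0
                and gapped[i - 1] != GAP
                and other[i - 1] != GAP
                and other[i - 1] == other[j - 1]
            ):
                gapped[j - 1] = gapped[i - 1]
                gapped[i - 1] = GAP
                i -= 1
                j -= 1
            i = j
        return gapped

    B = shift(B, A)
    A = shift(A, B)
    return "".join(A), "".join(B)


# ---------------------------------------------------------------------------
# Anchoring


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _anchor_blocks(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Colinear blocks (a_start, b_start, length) of unique shared k-mers,
    merged along diagonals."""
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    hits = sorted((ia, kb[km]) for km, ia in ka.items() if km in kb)
    blocks: list[list[int]] = []
    for ia, ib in hits:
        if blocks and ia == blocks[-1][0] + blocks[-1][2] - k + 1 and ib - ia == blocks[-1][1] - blocks[-1][0]:
            blocks[-1][2] += 1
        else:
            blocks.append([ia, ib, k])
    return [tuple(bl) for bl in blocks]


def _chain_blocks(blocks: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Heaviest colinear chain (weighted LIS on non-overlapping blocks)."""
    if not blocks:
        return []
    n = len(blocks)
    best = [bl[2] for bl in blocks]
    prev = [-1] * n
    for i in range(n):
        ai, bi, li = blocks[i]
        for j in range(i):
            aj, bj, lj = blocks[j]
            if aj + lj <= ai and bj + lj <= bi and best[j] + li > best[i]:
                best[i] = best[j] + li
                prev[i] = j
    i = int(np.argmax(best))
    chain = []
    while i >= 0:
        chain.append(blocks[i])
        i = prev[i]
    return chain[::-1]


def align_pair(
    ref: PlastomeRecord,
    qry: PlastomeRecord,
    scoring: Scoring | None = None,
    method: str = "auto",
    anchor_k: int = DEFAULT_ANCHOR_K,
) -> PairAlignment:
    """Globally align two plastomes.

    ``method``: "exact" forces full DP; "anchored" forces k-mer chaining with
    DP gap closing; "auto" picks exact when both inputs are at most
    ``EXACT_SIZE_CAP`` bases.  Gap placement is normalized by left-shifting
    within equal-letter runs, so the output is deterministic.
    """
    scoring = scoring or Scoring()
    a, b = ref.sequence, qry.sequence
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    if method == "auto":
        method = "exact" if max(len(a), len(b)) <= EXACT_SIZE_CAP else "anchored"
    if method == "exact":
        ra, rb = _dp_align(a, b, scoring)
    elif method == "anchored":
        chain = _chain_blocks(_anchor_blocks(a, b, anchor_k))
        if not chain:
            if max(len(a), len(b)) <= FALLBACK_SIZE_CAP:
                ra, rb = _dp_align(a, b, scoring)
            else:
                raise AlignmentError(
                    f"no shared unique {anchor_k}-mers between {ref.id} and "
                    f"{qry.id}; inputs too large for the full-DP fallback"
                )
        else:
            parts_a, parts_b = [], []
            pa = pb = 0
            for sa, sb, ln in chain:
                if sa > pa or sb > pb:
                    ga, gb = _dp_align(a[pa:sa], b[pb:sb], scoring)
                    parts_a.append(ga)
                    parts_b.append(gb)
                parts_a.append(a[sa : sa + ln])
                parts_b.append(b[sb : sb + ln])
                pa, pb = sa + ln, sb + ln
            if pa < len(a) or pb < len(b):
                ga, gb = _dp_align(a[pa:], b[pb:], scoring)
                parts_a.append(ga)
                parts_b.append(gb)
            ra, rb = "".join(parts_a), "".join(parts_b)
    else:
        raise AlignmentError(f"unknown method {method!r}")
    ra, rb = normalize_gaps(ra, rb)
    if ra.replace(GAP, "") != a or rb.replace(GAP, "") != b:
        raise AlignmentError("internal error: degapped rows do not round-trip")
    return PairAlignment(ref.id, qry.id, ra, rb, scoring.score_columns(ra, rb))


# ---------------------------------------------------------------------------
# Reference projection


@dataclass
class AlignmentMatrix:
    """Multiple alignment formed by projecting pairwise alignments onto one
    reference; the reference row's non-gap columns are in genome order."""

    ref_id: str
    ids: list[str]
    rows: dict[str, str] = field(repr=False)

    def __post_init__(self):
        lens = {len(r) for r in self.rows.values()}
        if len(lens) > 1:
            raise AlignmentError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.ref_id])

    def row(self, taxon: str) -> str:
        return self.rows[taxon]

    def as_array(self) -> np.ndarray:
        """(n_taxa, n_columns) byte array in ``ids`` order."""
        return np.vstack(
            [np.frombuffer(self.rows[t].encode(), dtype=np.uint8) for t in self.ids]
        )

    def pair(self, taxon: str) -> PairAlignment:
        """Re-extract the reference/taxon pairwise alignment (dropping
        columns where both rows are gaps)."""
        r, q = self.rows[self.ref_id], self.rows[taxon]
        keep = [i for i in range(len(r)) if r[i] != GAP or q[i] != GAP]
        ra = "".join(r[i] for i in keep)
        qa = "".join(q[i] for i in keep)
        ra, qa = normalize_gaps(ra, qa)
        return PairAlignment(self.ref_id, taxon, ra, qa, Scoring().score_columns(ra, qa))

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for t in self.ids:
                fh.write(f">{t}\n")
                row = self.rows[t]
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")


def project_to_reference(pairs: list[PairAlignment], ref_id: str) -> AlignmentMatrix:
    """Union the insertion columns of reference-anchored pairwise alignments
    into one matrix.  Every taxon row reproduces its input sequence when
    degapped; matrix length >= reference length."""
    if not pairs:
        raise AlignmentError("no pairwise alignments given")
    for p in pairs:
        if p.ref_id != ref_id:
            raise AlignmentError(f"pair {p.ref_id}/{p.qry_id} does not use reference {ref_id}")
    ref_seq = pairs[0].ref_seq
    for p in pairs[1:]:
        if p.ref_seq != ref_seq:
            raise AlignmentError("reference sequence differs between pairwise alignments")
    L = len(ref_seq)
    # ins_len[p] = columns inserted after the p-th reference base (p=0: before base 1)
    ins_len = np.zeros(L + 1, dtype=np.int64)
    per_pair = []
    for p in pairs:
        ins: dict[int, list[str]] = {}
        consumed = 0
        run: list[str] = []
        for rc, qc in zip(p.ref_row, p.qry_row):
            if rc == GAP:
                run.append(qc)
            else:
                if run:
                    ins[consumed] = run
                    run = []
                consumed += 1
        if run:
            ins[consumed] = run
        per_pair.append(ins)
        for k, v in ins.items():
            if len(v) > ins_len[k]:
                ins_len[k] = len(v)
    ids = [ref_id] + [p.qry_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate taxon ids in projection")
    rows = {}
    chunks = []
    for i in range(L + 1):
        if ins_len[i]:
            chunks.append(GAP * int(ins_len[i]))
        if i < L:
            chunks.append(ref_seq[i])
    rows[ref_id] = "".join(chunks)
    for p, ins in zip(pairs, per_pair):
        # rebuild the query row against the padded reference
        out = []
        qcols = [c for rc, c in zip(p.ref_row, p.qry_row) if rc != GAP]
        for i in range(L + 1):
            pad = int(ins_len[i])
            if pad:
                here = ins.get(i, [])
                out.append("".join(here) + GAP * (pad - len(here)))
            if i < L:
                out.append(qcols[i])
        rows[p.qry_id] = "".join(out)
    mat = AlignmentMatrix(ref_id=ref_id, ids=ids, rows=rows)
    for p in pairs:
        if mat.rows[p.qry_id].replace(GAP, "") != p.qry_seq:
            raise AlignmentError(f"projection broke round-trip for {p.qry_id}")
    return mat


def align_to_reference(
    records: list[PlastomeRecord],
    ref_id: str,
    scoring: Scoring | None = None,
    method: str = "auto",
) -> AlignmentMatrix:
    """Align every record against ``ref_id`` and project onto the reference."""
    by_id = {r.id: r for r in records}
    if ref_id not in by_id:
        raise AlignmentError(f"reference {ref_id!r} not among inputs")
    ref = by_id[ref_id]
    pairs = [
        align_pair(ref, rec, scoring=scoring, method=method)
        for rec in records
        if rec.id != ref_id
    ]
    return project_to_reference(pairs, ref_id)
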