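"""Synthetic plastome evolution with ground truth.

Generates a quadripartite ancestor (LSC + IR_A + SSC + IR_B, IRs exact
reverse complements) with a realistic gene layout, then evolves it along a
tree with SNP, MNV and indel processes.  Mutation is simulated on the
IR-reduced representation (LSC + IR + SSC) and the second repeat copy is
reconstructed from the first, which realises IR concerted evolution: any
event falling in the repeat appears identically in both copies.

Branch lengths are expected substitutions per (rate-averaged) site; MNV and
indel rates are events per site per unit branch length, i.e. their ratio to
the substitution rate.  Event placement is a per-branch Poisson draw of
counts followed by rate-multiplier-weighted positions — adequate at the
sub-percent divergences emulated, where multiple hits are negligible.

Default parameters emulate A-genome *Oryza* plastomes: ~134.5 kb genomes
(LSC 80,604 / IR 20,803 / SSC 12,347), ~58% coding, AT-rich, ingroup
distances of tens of events, an outgroup at ~900 events, SNP-dominated
spectra with minority MNV/indel, and intergenic-biased variant placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .errors import SimulationError
from .structure import GeneFeature, Interval, PlastomeRecord, region_map, revcomp
from .variants import DELETION, INSERTION, MNV, SNP, Variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionGenes:
    """Gene layout for one region of the quadripartite structure."""

    n_protein: int = 0
    protein_mean_len: int = 650  # coding bases, rounded to codons
    n_protein_intron: int = 0
    n_trna: int = 0
    trna_len: int = 75
    n_trna_intron: int = 0
    rrna_lengths: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimulationParams:
    lsc_len: int = 80604
    ir_len: int = 20803
    ssc_len: int = 12347
    at_content: float = 0.61
    lsc_genes: RegionGenes = field(
        default_factory=lambda: RegionGenes(
            n_protein=75, protein_mean_len=650, n_protein_intron=4,
            n_trna=24, n_trna_intron=6,
        )
    )
    ssc_genes: RegionGenes = field(
        default_factory=lambda: RegionGenes(
            n_protein=8, protein_mean_len=700, n_protein_intron=1,
        )
    )
    ir_genes: RegionGenes = field(
        default_factory=lambda: RegionGenes(
            n_protein=10, protein_mean_len=600, n_trna=8,
            rrna_lengths=(1490, 2810, 103, 121),
        )
    )
    intron_mean_len: int = 1000
    tree_newick: str = (
        "((TaxonA:1.0e-4,(TaxonB:1.45e-4,O_meridionalis:2.2e-5):4.5e-5):1.5e-4,"
        "(O_sativa_japonica:2.5e-4,(O_rufipogon:1.8e-4,"
        "(O_sativa_indica:1.2e-4,O_nivara:1.0e-4):6.0e-5):5.0e-5):2.0e-4,"
        "O_australiensis:6.0e-3);"
    )
    kappa: float = 2.0
    mnv_rate: float = 0.06
    indel_rate: float = 0.20
    indel_mean_len: float = 3.0
    mult_coding: float = 1.0
    mult_intron: float = 2.0
    mult_intergenic: float = 4.5
    min_event_spacing: int = 2

    def __post_init__(self):
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise SimulationError("structure lengths must be positive")
        if self.kappa <= 0 or self.mnv_rate < 0 or self.indel_rate < 0:
            raise SimulationError("rates must be non-negative and kappa > 0")
        if min(self.mult_coding, self.mult_intron, self.mult_intergenic) <= 0:
            raise SimulationError("region multipliers must be positive")

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def reduced_len(self) -> int:
        return self.lsc_len + self.ir_len + self.ssc_len


@dataclass
class TruthSet:
    """Ground truth of one simulation.

    ``branch_events[child_label]`` lists the :class:`Variant` events of the
    branch leading to ``child_label``, in the coordinates of the *parent*
    (IR-reduced) sequence; replaying them on the parent reproduces the child
    exactly.  ``root_to_leaf[leaf]`` maps root reduced coordinates (0-based)
    to leaf reduced coordinates (-1 where the base was deleted).
    """

    newick_labelled: str
    branch_events: dict[str, list[Variant]]
    node_reduced: dict[str, str]
    root_to_leaf: dict[str, np.ndarray]
    leaf_ir_bounds: dict[str, tuple[int, int]]


def _random_background(n: int, at: float, rng) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(_BASES, size=n, p=p)


_STOPS = {"TAA", "TAG", "TGA"}


def _protein_seq(n_codons: int, rng, at: float = 0.61) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    out = ["ATG"]
    while len(out) < n_codons - 1:
        codon = "".join(chr(c) for c in rng.choice(_BASES, size=3, p=p))
        if codon not in _STOPS:
            out.append(codon)
    out.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(out)


def _codon_len(mean: int, rng) -> int:
    n = max(6, int(round(rng.normal(mean, mean * 0.1))))
    return n - n % 3


def _layout_region(spec: RegionGenes, length: int, intron_mean: int, rng):
    """Plan gene placements in one region.

    Returns (templates, spacer lengths).  A template is
    (category, [exon_len, ...], [intron_len, ...], strand, name).
    """
    templates = []
    for i in range(spec.n_protein):
        clen = _codon_len(spec.protein_mean_len, rng)
        if i < spec.n_protein_intron:
            cut = 3 * int(rng.integers(1, clen // 3))
            ilen = max(100, int(rng.normal(intron_mean, intron_mean * 0.25)))
            templates.append(("protein_coding", [cut, clen - cut], [ilen]))
        else:
            templates.append(("protein_coding", [clen], []))
    for i in range(spec.n_trna):
        if i < spec.n_trna_intron:
            cut = int(rng.integers(20, spec.trna_len - 20))
            ilen = max(100, int(rng.normal(intron_mean, intron_mean * 0.25)))
            templates.append(("tRNA", [cut, spec.trna_len - cut], [ilen]))
        else:
            templates.append(("tRNA", [spec.trna_len], []))
    for L in spec.rrna_lengths:
        templates.append(("rRNA", [L], []))
    rng.shuffle(templates)
    needed = sum(sum(ex) + sum(intr) for _, ex, intr in templates)
    slack = length - needed
    if slack < len(templates) + 1:
        raise SimulationError(
            f"gene layout needs {needed} bp plus spacing but region is {length} bp"
        )
    # keep at least one intergenic base at both region edges so repeat
    # boundaries stay adjustable
    gaps = rng.multinomial(slack - 2, np.ones(len(templates) + 1) / (len(templates) + 1))
    gaps[0] += 1
    gaps[-1] += 1
    return templates, gaps


def _fill_region(seq: np.ndarray, offset0: int, templates, gaps, rng, name_prefix: str,
                 at: float = 0.61):
    """Write gene sequences into ``seq`` and return features (1-based,
    genome coordinates)."""
    feats = []
    pos = offset0 + int(gaps[0])
    for gi, (cat, exon_lens, intron_lens) in enumerate(templates):
        strand = "+" if rng.random() < 0.5 else "-"
        if cat == "protein_coding":
            coding = _protein_seq(sum(exon_lens) // 3, rng, at)
        else:
            coding = "".join(
                chr(c) for c in _random_background(sum(exon_lens), at, rng)
            )
        # split coding across exons, introns between (transcription order)
        pieces = []
        cursor = 0
        for k, el in enumerate(exon_lens):
            pieces.append(coding[cursor : cursor + el])
            cursor += el
        gene_span = sum(exon_lens) + sum(intron_lens)
        exon_ivs = []
        if strand == "+":
            p = pos
            for k, piece in enumerate(pieces):
                seq[p : p + len(piece)] = np.frombuffer(piece.encode(), dtype=np.uint8)
                exon_ivs.append(Interval(p + 1, p + len(piece)))
                p += len(piece)
                if k < len(intron_lens):
                    p += intron_lens[k]
        else:
            # transcription right-to-left: first exon is rightmost
            p = pos + gene_span
            for k, piece in enumerate(pieces):
                rc = revcomp(piece)
                seq[p - len(piece) : p] = np.frombuffer(rc.encode(), dtype=np.uint8)
                exon_ivs.append(Interval(p - len(piece) + 1, p))
                p -= len(piece)
                if k < len(intron_lens):
                    p -= intron_lens[k]
            exon_ivs = exon_ivs[::-1]
        feats.append(
            GeneFeature(
                name=f"{name_prefix}{gi}",
                category=cat,
                strand=strand,
                exons=tuple(exon_ivs),
            )
        )
        pos += gene_span + int(gaps[gi + 1])
    return feats


def _mirror_feature(f: GeneFeature, ira: Interval, irb: Interval) -> GeneFeature:
    """The IR_B copy of an IR_A-resident gene."""
    exons = []
    for iv in f.exons:
        s = irb.start + (ira.end - iv.end)
        e = irb.start + (ira.end - iv.start)
        exons.append(Interval(s, e))
    return GeneFeature(
        name=f.name,
        category=f.category,
        strand="-" if f.strand == "+" else "+",
        exons=tuple(sorted(exons, key=lambda iv: iv.start)),
        copy="ir_duplicated",
    )


def generate_ancestor(
    params: SimulationParams, seed: int | np.random.Generator = 0
) -> tuple[PlastomeRecord, list[GeneFeature]]:
    """Generate the ancestral plastome and its annotation.

    Genome = LSC + IR_A + SSC + revcomp(IR_A); genes are placed without
    overlap, IR-resident genes are emitted in both copies (the IR_B entries
    tagged ``ir_duplicated``), and protein genes carry an intact ORF
    (start, no internal stop, stop) so translation-based effect calls are
    well defined.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = params.total_len
    seq = _random_background(params.reduced_len, params.at_content, rng)
    feats: list[GeneFeature] = []
    lsc0 = 0
    ira0 = params.lsc_len
    ssc0 = params.lsc_len + params.ir_len
    for region, (offset, length, prefix) in {
        "lsc": (lsc0, params.lsc_len, "lscg"),
        "ir": (ira0, params.ir_len, "irg"),
        "ssc": (ssc0, params.ssc_len, "sscg"),
    }.items():
        spec = getattr(params, f"{region}_genes")
        if (
            spec.n_protein + spec.n_trna + len(spec.rrna_lengths) == 0
        ):
            continue
        templates, gaps = _layout_region(spec, length, params.intron_mean_len, rng)
        feats += _fill_region(
            seq, offset, templates, gaps, rng, prefix, params.at_content
        )
    # the repeat must be maximal at exactly ir_len: its flanking bases may
    # not be reverse complements of each other (LSC last vs SSC first at one
    # junction; SSC last vs LSC first around the circle at the other)
    comp = {65: 84, 84: 65, 67: 71, 71: 67}
    for flank, other in ((params.reduced_len - 1, ssc0), (params.lsc_len - 1, 0)):
        while seq[flank] == comp[int(seq[other])]:
            seq[flank] = rng.choice(_BASES)
    reduced = "".join(chr(c) for c in seq)
    ira = Interval(params.lsc_len + 1, params.lsc_len + params.ir_len)
    irb = Interval(params.reduced_len + 1, L)
    full = reduced + revcomp(reduced[ira.start - 1 : ira.end])
    ir_feats = [f for f in feats if ira.start <= f.span.start and f.span.end <= ira.end]
    for f in ir_feats:
        feats[feats.index(f)] = replace(f, copy="ir_duplicated")
    feats += [_mirror_feature(f, ira, irb) for f in ir_feats]
    feats.sort(key=lambda f: f.span.start)
    record = PlastomeRecord(id="ancestor", sequence=full, circular=True)
    return record, feats


# ---------------------------------------------------------------------------
# Evolution


def apply_variants(seq: str, events: list[Variant]) -> str:
    """Replay events (1-based coordinates of ``seq``) left to right."""
    out = []
    cursor = 0
    for v in sorted(events, key=lambda v: (v.ref_position, v.type == INSERTION)):
        if v.type == INSERTION:
            at = v.ref_position  # insert after this base
            out.append(seq[cursor:at])
            out.append(v.alt_allele)
            cursor = at
        else:
            s = v.ref_position - 1
            out.append(seq[cursor:s])
            if v.type in (SNP, MNV):
                if seq[s : s + len(v.ref_allele)] != v.ref_allele:
                    raise SimulationError("truth replay mismatch")
                out.append(v.alt_allele)
                cursor = s + len(v.ref_allele)
            else:  # deletion
                if seq[s : s + len(v.ref_allele)] != v.ref_allele:
                    raise SimulationError("truth replay mismatch")
                cursor = s + len(v.ref_allele)
    out.append(seq[cursor:])
    return "".join(out)


def _parent_to_child_map(L: int, events: list[Variant]) -> np.ndarray:
    delta = np.zeros(L + 1, dtype=np.int64)
    deleted = np.zeros(L, dtype=bool)
    for v in events:
        if v.type == INSERTION:
            delta[v.ref_position] += len(v.alt_allele)
        elif v.type == DELETION:
            s = v.ref_position - 1
            k = len(v.ref_allele)
            deleted[s : s + k] = True
            delta[s + k] -= k
    p2c = np.arange(L, dtype=np.int64) + np.cumsum(delta)[:L]
    p2c[deleted] = -1
    return p2c


def _mutate_base(base: str, kappa: float, rng) -> str:
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    if rng.random() < kappa / (kappa + 2):
        return ts[base]
    return tv[base][rng.integers(2)]


def _draw_events(seq: str, mult: np.ndarray, t: float, params: SimulationParams, rng):
    """Poisson event draw for one branch; returns sorted non-overlapping
    Variant events in this sequence's coordinates."""
    L = len(seq)
    lam = t * L
    n_snp = rng.poisson(lam)
    n_mnv = rng.poisson(params.mnv_rate * lam)
    n_indel = rng.poisson(params.indel_rate * lam)
    total = n_snp + n_mnv + n_indel
    if total == 0:
        return []
    p = mult / mult.sum()
    positions = rng.choice(L, size=min(total, L), replace=False, p=p)
    kinds = [SNP] * n_snp + [MNV] * n_mnv + ["indel"] * n_indel
    rng.shuffle(kinds)
    proposals = []
    for pos0, kind in zip(positions, kinds):
        if kind == SNP:
            ref = seq[pos0]
            if ref == "N":
                continue
            proposals.append(Variant(SNP, pos0 + 1, ref, _mutate_base(ref, params.kappa, rng)))
        elif kind == MNV:
            k = 2 + int(rng.geometric(0.7)) - 1
            if pos0 + k > L:
                continue
            ref = seq[pos0 : pos0 + k]
            if "N" in ref:
                continue
            alt = "".join(_mutate_base(b, params.kappa, rng) for b in ref)
            proposals.append(Variant(MNV, pos0 + 1, ref, alt))
        else:
            k = int(rng.geometric(1 / params.indel_mean_len))
            if rng.random() < 0.5 and pos0 + k <= L:  # deletion
                ref = seq[pos0 : pos0 + k]
                if "N" in ref:
                    continue
                proposals.append(Variant(DELETION, pos0 + 1, ref, ""))
            else:  # insertion after this base
                alt = "".join(
                    chr(c)
                    for c in _random_background(k, params.at_content, rng)
                )
                proposals.append(Variant(INSERTION, pos0 + 1, "", alt))
    proposals.sort(key=lambda v: v.ref_position)
    kept = []
    spacing = params.min_event_spacing
    last_end = -10**9
    for v in proposals:
        start = v.ref_position
        end = v.ref_position + max(len(v.ref_allele), 1) - 1
        if start - last_end <= spacing:
            continue
        kept.append(v)
        last_end = end
    return kept


def _multiplier_array(labels: np.ndarray, params: SimulationParams) -> np.ndarray:
    from .structure import _REGION_INTERGENIC, _REGION_INTRON

    mult = np.full(labels.shape, params.mult_coding, dtype=np.float64)
    mult[labels == _REGION_INTERGENIC] = params.mult_intergenic
    mult[labels == _REGION_INTRON] = params.mult_intron
    return mult


def evolve(
    ancestor: PlastomeRecord,
    features: list[GeneFeature],
    params: SimulationParams,
    seed: int | np.random.Generator = 0,
) -> tuple[list[PlastomeRecord], TruthSet]:
    """Evolve the ancestor along ``params.tree_newick``.

    Returns leaf records (full quadripartite genomes; IRs remain exact
    reverse complements because mutation acts on the IR-reduced sequence)
    and the :class:`TruthSet`.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = dendropy.Tree.get(
        data=params.tree_newick, schema="newick", preserve_underscores=True
    )
    red_len = params.reduced_len
    root_seq = ancestor.sequence[:red_len]
    labels = region_map(ancestor.length, features)[:red_len]
    root_mult = _multiplier_array(labels, params)
    # label internal nodes deterministically
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and node.label is None:
            node.label = f"N{counter}"
            counter += 1
    branch_events: dict[str, list[Variant]] = {}
    node_reduced: dict[str, str] = {"root": root_seq}
    root_to_leaf: dict[str, np.ndarray] = {}
    ir_bounds: dict[str, tuple[int, int]] = {}
    leaves: list[PlastomeRecord] = []
    root_ir = (params.lsc_len, params.lsc_len + params.ir_len)  # 0-based half-open

    state = {
        id(tree.seed_node): (
            root_seq,
            root_mult,
            root_ir,
            np.arange(red_len, dtype=np.int64),
        )
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        pseq, pmult, pir, pmap = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        events = _draw_events(pseq, pmult, t, params, rng)
        label = node.taxon.label if node.taxon else node.label
        branch_events[label] = events
        cseq = apply_variants(pseq, events)
        p2c = _parent_to_child_map(len(pseq), events)
        # multipliers follow surviving bases; insertions inherit their anchor's
        cmult = np.empty(len(cseq), dtype=np.float64)
        cmult[:] = params.mult_intergenic
        surv = p2c >= 0
        cmult[p2c[surv]] = pmult[surv]
        # fill insertion gaps from the left neighbour
        missing = np.ones(len(cseq), dtype=bool)
        missing[p2c[surv]] = False
        idxs = np.flatnonzero(missing)
        for i in idxs:
            cmult[i] = cmult[i - 1] if i > 0 else cmult[0]
        cir = _shift_bounds(pir, events)
        cmap = np.where(pmap >= 0, p2c[np.clip(pmap, 0, None)], -1)
        cmap[pmap < 0] = -1
        state[id(node)] = (cseq, cmult, cir, cmap)
        node_reduced[label] = cseq
        if node.is_leaf():
            ir0, ir1 = cir
            full = cseq + revcomp(cseq[ir0:ir1])
            leaves.append(PlastomeRecord(id=label, sequence=full, circular=True))
            root_to_leaf[label] = cmap
            ir_bounds[label] = cir
    truth = TruthSet(
        newick_labelled=tree.as_string(
            schema="newick", unquoted_underscores=True
        ).strip(),
        branch_events=branch_events,
        node_reduced=node_reduced,
        root_to_leaf=root_to_leaf,
        leaf_ir_bounds=ir_bounds,
    )
    return leaves, truth


def _shift_bounds(bounds: tuple[int, int], events: list[Variant]) -> tuple[int, int]:
    b0, b1 = bounds
    for v in sorted(events, key=lambda v: v.ref_position):
        if v.type == INSERTION:
            k = len(v.alt_allele)
            if v.ref_position <= b0:
                b0 += k
                b1 += k
            elif v.ref_position < b1:
                b1 += k
        elif v.type == DELETION:
            s, k = v.ref_position - 1, len(v.ref_allele)
            cut_before = max(0, min(b0, s + k) - min(b0, s))
            cut_inside = max(0, min(b1, s + k) - max(b0, s))
            b0 -= cut_before
            b1 -= cut_before + cut_inside
    return b0, b1


def lift_features(
    features: list[GeneFeature],
    root_to_leaf: np.ndarray,
    reduced_len: int,
    leaf_ir: tuple[int, int],
    leaf_len: int,
) -> list[GeneFeature]:
    """Lift the ancestral annotation (full-genome coordinates) through the
    indel history onto one leaf.  IR_B copies are re-mirrored from the lifted
    IR_A coordinates; exons wholly deleted drop their gene."""
    out = []
    ir0, ir1 = leaf_ir
    ira = Interval(ir0 + 1, ir1)
    leaf_reduced_len = leaf_len - (ir1 - ir0)
    irb = Interval(leaf_reduced_len + 1, leaf_len)
    for f in features:
        if f.span.end > reduced_len:
            continue  # IR_B copies are regenerated below
        exons = []
        ok = True
        for iv in f.exons:
            window = root_to_leaf[iv.start - 1 : iv.end]
            surv = window[window >= 0]
            if surv.size == 0:
                ok = False
                break
            exons.append(Interval(int(surv.min()) + 1, int(surv.max()) + 1))
        if not ok:
            continue
        lifted = GeneFeature(
            name=f.name, category=f.category, strand=f.strand,
            exons=tuple(exons), copy=f.copy,
        )
        out.append(lifted)
        if f.copy == "ir_duplicated" and ira.start <= lifted.span.start and lifted.span.end <= ira.end:
            out.append(_mirror_feature(lifted, ira, irb))
    out.sort(key=lambda f: f.span.start)
    return out


# ---------------------------------------------------------------------------
# Parameter recovery


def recover_parameters(
    called_variants: list[Variant],
    features: list[GeneFeature] | None = None,
    genome_length: int | None = None,
) -> dict:
    """Estimate mutation-process parameters from called variants.

    Returns the transition/transversion ratio and the implied kappa
    (kappa = 2 Ts/Tv under equal base usage), event-type fractions, and —
    when an annotation is supplied — per-region variant proportions with
    their length shares and enrichments.  kappa is None (flagged) when no
    SNPs or no transversions were observed.
    """
    from .variants import classify_ts_tv, region_distribution

    n = len(called_variants)
    by_type = {SNP: 0, MNV: 0, INSERTION: 0, DELETION: 0}
    ts = tv = 0
    for v in called_variants:
        by_type[v.type] += 1
        if v.type == SNP:
            if classify_ts_tv(v) == "transition":
                ts += 1
            else:
                tv += 1
    out = {
        "n_variants": n,
        "type_fractions": {k: (c / n if n else 0.0) for k, c in by_type.items()},
        "indel_fraction": ((by_type[INSERTION] + by_type[DELETION]) / n) if n else 0.0,
        "n_transitions": ts,
        "n_transversions": tv,
        "ts_tv_ratio": (ts / tv) if tv else None,
        "kappa_hat": (2 * ts / tv) if tv else None,
        "kappa_flag": None if (ts + tv) and tv else "kappa undefined: no transversions or no SNPs",
    }
    if features is not None and genome_length is not None:
        labels = region_map(genome_length, features)
        share = {
            "coding": float(np.count_nonzero((labels > 0) & (labels < 4))) / genome_length,
            "intron": float(np.count_nonzero(labels == 4)) / genome_length,
            "intergenic": float(np.count_nonzero(labels == 0)) / genome_length,
        }
        props = region_distribution(called_variants, features, genome_length)
        out["region_proportions"] = props
        out["region_length_shares"] = share
        out["region_enrichment"] = {
            k: (props[k] / share[k]) if share[k] else None for k in props
        }
    return out
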