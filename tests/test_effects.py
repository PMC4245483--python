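"""Protein-effect prediction and clade partitioning.

The translation oracle used throughout is "mutate the whole CDS, translate
both versions with the plastid code, and diff the proteins" — independent of
the codon-local path under test.
"""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from plastocmp.effects import (
    EffectRecord,
    allele_table_from_matrix,
    clade_partition,
    effect_summary,
    translate_cds,
    variant_effect,
)
from plastocmp.simulate import _protein_seq
from plastocmp.structure import GeneFeature, Interval, revcomp
from plastocmp.variants import Variant

from conftest import random_seq


def translate11(s):
    return str(Seq(s[: len(s) - len(s) % 3]).translate(table=11, to_stop=True))


def make_gene(rng, n_codons=40, strand="+", start=51, intron_at=None, intron_len=60):
    """Embed an intact protein gene in a random genome; returns
    (genome, feature, cds)."""
    cds = _protein_seq(n_codons, rng)
    flank5 = random_seq(rng, start - 1)
    if intron_at is None:
        body = cds if strand == "+" else revcomp(cds)
        exons = (Interval(start, start + len(cds) - 1),)
    else:
        intron = random_seq(rng, intron_len)
        if strand == "+":
            body = cds[:intron_at] + intron + cds[intron_at:]
            exons = (
                Interval(start, start + intron_at - 1),
                Interval(start + intron_at + intron_len, start + len(cds) + intron_len - 1),
            )
        else:
            plus = revcomp(cds)
            cut = len(cds) - intron_at
            body = plus[:cut] + intron + plus[cut:]
            exons = (
                Interval(start, start + cut - 1),
                Interval(start + cut + intron_len, start + len(cds) + intron_len - 1),
            )
    genome = flank5 + body + random_seq(rng, 80)
    f = GeneFeature("g1", "protein_coding", strand, exons)
    return genome, f, cds


class TestVariantEffect:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_snp_effects_match_whole_cds_oracle(self, strand):
        rng = np.random.default_rng(0)
        genome, f, cds = make_gene(rng, n_codons=30, strand=strand)
        hits = 0
        for gpos in range(f.span.start, f.span.end + 1):
            ref = genome[gpos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = Variant("SNP", gpos, ref, alt)
                e = variant_effect(v, [f], genome)
                mutated = genome[: gpos - 1] + alt + genome[gpos:]
                cds_mut = mutated[f.span.start - 1 : f.span.end]
                if strand == "-":
                    cds_mut = revcomp(cds_mut)
                p_ref, p_mut = translate11(cds), translate11(cds_mut)
                if p_ref == p_mut and len(p_ref) == len(cds) // 3 - 1:
                    assert e.effect == "synonymous", (gpos, alt)
                elif e.effect == "nonsynonymous":
                    # exactly one residue differs, at the reported position
                    diffs = [
                        i
                        for i, (a, b) in enumerate(zip(p_ref, p_mut))
                        if a != b
                    ]
                    if diffs:  # substitution not touching the stop codon
                        assert diffs == [e.aa_position - 1]
                hits += 1
        assert hits > 0

    def test_third_position_degeneracy_synonymous(self):
        rng = np.random.default_rng(1)
        # construct gene containing GGT (Gly); GGT->GGC stays Gly
        cds = "ATG" + "GGT" + "CATTGCAAA" + "TAA"
        genome = random_seq(rng, 50) + cds + random_seq(rng, 50)
        f = GeneFeature("g", "protein_coding", "+", (Interval(51, 50 + len(cds)),))
        v = Variant("SNP", 51 + 5, "T", "C")
        e = variant_effect(v, [f], genome)
        assert e.effect == "synonymous"
        assert e.aa_ref == e.aa_alt == "G"

    def test_mnv_within_codon_evaluated_as_unit(self):
        rng = np.random.default_rng(2)
        cds = "ATG" + "CTG" + "AAA" + "TAA"  # Leu codon
        genome = random_seq(rng, 20) + cds + random_seq(rng, 20)
        f = GeneFeature("g", "protein_coding", "+", (Interval(21, 20 + len(cds)),))
        # CTG -> CTA: both positions change but the codon is still Leu? use
        # TTA: C->T at pos1, G->A at pos3 are non-adjacent; take adjacent
        # pair instead: CTG -> CAC (Leu -> His) via MNV at codon pos 2-3
        v = Variant("MNV", 21 + 4, "TG", "AC")
        e = variant_effect(v, [f], genome)
        assert e.effect == "nonsynonymous"
        assert e.aa_position == 2
        assert (e.aa_ref, e.aa_alt) == ("L", "H")

    def test_frameshift_truncation_matches_translation(self):
        rng = np.random.default_rng(3)
        # 134 codons incl. stop -> intact protein 133 aa
        genome, f, cds = make_gene(rng, n_codons=134, strand="+")
        assert len(translate11(cds)) == 133
        for gpos in range(f.span.start + 30, f.span.start + 60, 7):
            v = Variant("insertion", gpos, "", "G")
            e = variant_effect(v, [f], genome)
            assert e.effect == "frameshift"
            assert e.intact_length == 133
            off = gpos - f.span.start
            mutated_cds = cds[: off + 1] + "G" + cds[off + 1 :]
            assert e.truncated_length == len(translate11(mutated_cds))
            assert e.truncated_length < 133

    def test_inframe_deletion_not_frameshift(self):
        rng = np.random.default_rng(4)
        genome, f, cds = make_gene(rng, n_codons=40)
        start = f.span.start + 6
        v = Variant("deletion", start, genome[start - 1 : start + 2], "")
        e = variant_effect(v, [f], genome)
        assert e.effect == "inframe_indel"

    def test_intron_and_intergenic_have_no_effect(self):
        rng = np.random.default_rng(5)
        genome, f, cds = make_gene(rng, n_codons=30, intron_at=45)
        intron_pos = f.exons[0].end + 5
        e = variant_effect(
            Variant("SNP", intron_pos, genome[intron_pos - 1],
                    "A" if genome[intron_pos - 1] != "A" else "C"),
            [f], genome,
        )
        assert (e.region, e.effect) == ("intron", "none")
        e2 = variant_effect(
            Variant("SNP", 3, genome[2], "A" if genome[2] != "A" else "C"),
            [f], genome,
        )
        assert (e2.region, e2.effect) == ("intergenic", "none")

    def test_exon_boundary_span_flagged_composite(self):
        rng = np.random.default_rng(6)
        genome, f, cds = make_gene(rng, n_codons=30, intron_at=45)
        pos = f.exons[0].end  # MNV spilling into the intron
        v = Variant("MNV", pos, genome[pos - 1 : pos + 1], "AA"
                    if genome[pos - 1 : pos + 1] != "AA" else "CC")
        e = variant_effect(v, [f], genome)
        assert e.effect == "composite"

    def test_reference_translation_sanity_gate(self, small_ancestor):
        """Every intact simulated protein gene translates without internal
        stops."""
        rec, feats = small_ancestor
        from plastocmp.effects import _cds_and_map

        n_checked = 0
        for f in feats:
            if f.category != "protein_coding":
                continue
            cds, _ = _cds_and_map(f, rec.sequence)
            assert len(cds) % 3 == 0
            prot = translate_cds(cds, to_stop=False)
            assert prot.endswith("*") and "*" not in prot[:-1], f.name
            n_checked += 1
        assert n_checked >= 8


class TestEffectSummary:
    def test_empty(self):
        assert effect_summary([]) == (0, 0, 0)

    def test_counts_by_class(self):
        recs = [
            EffectRecord(Variant("SNP", 1, "A", "G"), "g", "coding", "synonymous"),
            EffectRecord(Variant("SNP", 9, "A", "G"), "g", "coding", "nonsynonymous"),
            EffectRecord(Variant("SNP", 9, "A", "G"), "g", "coding", "nonsynonymous"),
            EffectRecord(Variant("insertion", 4, "", "G"), "g", "coding", "frameshift"),
            EffectRecord(Variant("SNP", 30, "A", "G"), None, "intergenic", "none"),
        ]
        assert effect_summary(recs) == (1, 2, 1)


AUS, ASIA = "Australian", "Asian"
CLADES = {
    "A": "TaxonA",
    "B1": AUS, "B2": AUS,
    "C1": ASIA, "C2": ASIA, "C3": ASIA,
}


def table(rows):
    df = pd.DataFrame(rows, columns=["position", "A", "B1", "B2", "C1", "C2", "C3"])
    return df.set_index("position")


class TestCladePartition:
    def test_clade_split_and_unique_sets(self):
        t = table(
            [
                (100, "G", "G", "G", "A", "A", "A"),   # split, A with Australians
                (200, "T", "C", "C", "T", "T", "T"),   # split, A with Asians
                (300, "G", "A", "A", "A", "A", "A"),   # unique to focal taxon
                (400, "A", "A", "A", "A", "A", "A"),   # invariant -> nowhere
                (500, "C", "C", "T", "G", "G", "G"),   # Australian clade not uniform
            ]
        )
        part = clade_partition(t, CLADES)
        assert part.australian_specific == {100}
        assert part.asian_specific == {200}
        assert part.taxon_a_unique == {300}
        assert part.clade_specific == {100, 200}
        # pairwise disjoint
        assert not (part.clade_specific & part.taxon_a_unique)

    def test_indel_alleles_partition(self):
        t = table([(150, "del", "del", "del", "A", "A", "A")])
        part = clade_partition(t, CLADES)
        assert part.australian_specific == {150}

    def test_missing_allele_skipped_and_counted(self):
        t = table([(100, "G", None, "G", "A", "A", "A")])
        part = clade_partition(t, CLADES)
        assert part.n_skipped == 1
        assert not part.clade_specific

    def test_taxon_order_invariance(self):
        rows = [
            (100, "G", "G", "G", "A", "A", "A"),
            (300, "G", "A", "A", "A", "A", "A"),
        ]
        t1 = table(rows)
        t2 = t1[["C3", "B1", "A", "C1", "B2", "C2"]]
        p1, p2 = clade_partition(t1, CLADES), clade_partition(t2, CLADES)
        assert p1.australian_specific == p2.australian_specific
        assert p1.taxon_a_unique == p2.taxon_a_unique


class TestAlleleTable:
    def test_snp_and_indel_events_extracted(self):
        rows = {
            "R":  "ACGTACGTAA",
            "q1": "ACGAACGTAA",   # SNP at ref pos 4
            "q2": "ACGT--GTAA",   # 2-bp deletion at ref pos 5
        }
        from plastocmp.alignment import AlignmentMatrix

        m = AlignmentMatrix(ref_id="R", ids=list(rows), rows=rows)
        t = allele_table_from_matrix(m)
        assert list(t.index) == [4, 5]
        assert t.loc[4].tolist() == ["T", "A", "T"]
        assert t.loc[5].tolist() == ["AC", "AC", "del"]
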