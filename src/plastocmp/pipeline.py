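"""End-to-end comparative-plastome pipeline.

Orchestrates structure detection, IR-reduced alignment, variant calling and
classification, effect annotation, clade partitioning, distance matrices,
and maximum-parsimony + neighbor-joining trees, writing one TSV/Newick/VCF
report bundle plus a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import Scoring, align_pair, project_to_reference
from .effects import (
    allele_table_from_matrix,
    clade_partition,
    effect_summary,
    effects_table,
    variant_effect,
)
from .errors import ConfigError, PlastocmpError
from .phylo import (
    bootstrap_support,
    build_character_matrix,
    exhaustive_search,
    heuristic_search,
    neighbor_joining,
    root_with_outgroup,
    to_nexus,
    to_phylip,
)
from .structure import (
    DEFAULT_MIN_IR,
    composition_summary,
    detect_quadripartite,
    read_gff3,
    read_plastomes,
    reduce_single_ir,
    structure_report,
)
from .variants import (
    call_variants,
    distance_matrices,
    region_distribution,
    summarize_variants,
    summary_table,
    variants_to_tsv,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    reference: str
    outgroup: str
    out_dir: str
    gff3: str | None = None
    clade_map: dict[str, str] = field(default_factory=dict)
    min_ir_length: int = DEFAULT_MIN_IR
    bootstrap_reps: int = 2000
    n_additions: int = 10
    seed: int = 42
    scoring: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config {path}: {exc}") from exc

    def validate(self, taxa: list[str]) -> None:
        for role, name in (("reference", self.reference), ("outgroup", self.outgroup)):
            if name not in taxa:
                raise ConfigError(f"{role} {name!r} not among inputs {taxa}")
        if self.bootstrap_reps < 0:
            raise ConfigError("bootstrap_reps must be >= 0")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).  Any stage
    failure raises with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "plastocmp_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {config.fasta: _sha256(config.fasta)},
        "stages": {},
    }
    if config.gff3:
        manifest["inputs"][config.gff3] = _sha256(config.gff3)
    scoring = Scoring(**config.scoring) if config.scoring else Scoring()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise PlastocmpError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])
            return result

        return deco

    records = read_plastomes(config.fasta)
    taxa = [r.id for r in records]
    config.validate(taxa)
    features = read_gff3(config.gff3) if config.gff3 else None
    ref_full = next(r for r in records if r.id == config.reference)

    @stage("structure")
    def _structure():
        df = structure_report(records, config.min_ir_length)
        df.to_csv(out / "structure.tsv", sep="\t", index=False)
        return df

    structure_df = _structure

    @stage("reduce")
    def _reduce():
        reduced = []
        for rec in records:
            quad = detect_quadripartite(rec, config.min_ir_length)
            reduced.append(reduce_single_ir(rec, quad))
        return reduced

    reduced = _reduce
    ref_reduced = next(r for r in reduced if r.id == config.reference)

    @stage("align")
    def _align():
        pairs = [
            align_pair(ref_reduced, rec, scoring=scoring)
            for rec in reduced
            if rec.id != config.reference
        ]
        matrix = project_to_reference(pairs, config.reference)
        matrix.to_fasta(str(out / "alignment.fasta"))
        (out / "alignment.phy").write_text(to_phylip(matrix.rows))
        (out / "alignment.nex").write_text(to_nexus(matrix.rows))
        return pairs, matrix

    pairs, matrix = _align

    @stage("variants")
    def _variants():
        all_variants = {}
        summaries = []
        for p in pairs:
            vs = call_variants(p)
            all_variants[p.qry_id] = vs
            summaries.append(summarize_variants(p, vs))
        summary_table(summaries).to_csv(out / "variant_summary.tsv", sep="\t", index=False)
        for taxon, vs in all_variants.items():
            write_vcf(vs, ref_reduced, taxon, str(out / f"variants_{taxon}.vcf"))
            variants_to_tsv(vs, str(out / f"variants_{taxon}.tsv"))
        return all_variants

    all_variants = _variants

    @stage("distances")
    def _distances():
        nvar, ndiff = distance_matrices(reduced, scoring=scoring)
        nvar.to_csv(out / "distances_variants.tsv", sep="\t")
        ndiff.to_csv(out / "distances_differences.tsv", sep="\t")
        return nvar, ndiff

    nvar, ndiff = _distances

    effects_by_taxon = {}
    if features is not None:
        red_features = [f for f in features if f.span.end <= ref_reduced.length]

        @stage("composition")
        def _composition():
            comp = composition_summary(ref_full, features)
            pd.DataFrame([comp.rounded()]).to_csv(out / "composition.tsv", sep="\t", index=False)
            rows = []
            for taxon, vs in all_variants.items():
                dist = region_distribution(vs, red_features, ref_reduced.length)
                dist["taxon"] = taxon
                rows.append(dist)
            pd.DataFrame(rows).to_csv(out / "variant_regions.tsv", sep="\t", index=False)
            return comp

        _composition

        @stage("effects")
        def _effects():
            rows = []
            for taxon, vs in all_variants.items():
                effs = [
                    variant_effect(v, red_features, ref_reduced.sequence) for v in vs
                ]
                effects_by_taxon[taxon] = effs
                syn, nonsyn, fs = effect_summary(effs)
                rows.append(
                    {"taxon": taxon, "synonymous": syn, "nonsynonymous": nonsyn,
                     "frameshifts": fs}
                )
                effects_table(effs).to_csv(
                    out / f"effects_{taxon}.tsv", sep="\t", index=False
                )
            pd.DataFrame(rows).to_csv(out / "effect_summary.tsv", sep="\t", index=False)
            return rows

        _effects

    if config.clade_map:

        @stage("clades")
        def _clades():
            table = allele_table_from_matrix(matrix)
            part = clade_partition(table, config.clade_map)
            part.table.to_csv(out / "clade_partition.tsv", sep="\t", index=False)
            return part

        _clades

    @stage("mp")
    def _mp():
        cmatrix = build_character_matrix(matrix)
        classes = cmatrix.class_counts()
        pd.DataFrame([classes]).to_csv(out / "site_classes.tsv", sep="\t", index=False)
        if cmatrix.n_taxa <= 9:
            result = exhaustive_search(cmatrix)
        else:
            result = heuristic_search(cmatrix, config.n_additions, config.seed)
        best = result.best
        if config.bootstrap_reps:
            best = bootstrap_support(
                cmatrix, config.bootstrap_reps, seed=config.seed + 1, best_tree=best
            )
        rooted = root_with_outgroup(best, config.outgroup)
        (out / "mp_tree.nwk").write_text(rooted.newick_with_supports() + "\n")
        stats = {
            "tree_length": result.tree_length,
            "ci": round(result.ci, 4),
            "ri": round(result.ri, 4),
            "ci_excluding_uninformative": round(result.ci_excluding_uninformative, 4),
            "n_best_trees": len(result.best_trees),
            **classes,
        }
        pd.DataFrame([stats]).to_csv(out / "mp_stats.tsv", sep="\t", index=False)
        return result, rooted

    mp_result, mp_tree = _mp

    @stage("nj")
    def _nj():
        tree = neighbor_joining(nvar)
        rooted = root_with_outgroup(tree, config.outgroup)
        (out / "nj_tree.nwk").write_text(rooted.newick + "\n")
        return rooted

    _nj

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Accession download (optional; never exercised by the test suite)

ACCESSIONS = {
    "TaxonA": "KF428978",
    "O_sativa_japonica": "GU592207",
    "O_sativa_indica": "AY522329",
    "O_meridionalis": "JN005831",
    "TaxonB": "JN005833",
    "O_rufipogon": "JN005832",
    "O_nivara": "AP006728",
    "O_australiensis": "GU592209",
}

_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype={rettype}&retmode=text"
)


def fetch_accessions(
    out_fasta: str, accessions: dict[str, str] | None = None, timeout: float = 30.0
) -> str:
    """Download the study accessions from NCBI into one multi-FASTA with
    taxon labels as record ids.  Requires network access."""
    from urllib.request import urlopen

    accessions = accessions or ACCESSIONS
    chunks = []
    for label, acc in accessions.items():
        with urlopen(_EFETCH.format(acc=acc, rettype="fasta"), timeout=timeout) as fh:
            text = fh.read().decode()
        body = "".join(text.split("\n", 1)[1].split())
        chunks.append(f">{label}\n{body}\n")
    Path(out_fasta).write_text("".join(chunks))
    return out_fasta
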