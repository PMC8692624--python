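"""End-to-end orchestration: layout stats -> composition -> codon usage ->
diversity/Ka-Ks/distances -> NJ tree, with TSV/JSON/newick artifacts.

The pipeline runs on either a simulated clade (no inputs needed) or a
directory of annotated genomes plus per-gene aligned FASTA.  Stages degrade
gracefully: without sequences only the layout/summary sections are filled,
and a stage failure marks the report rather than destroying earlier output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotation_model import (MitoGenome, layout_report, read_annotation_table,
                               read_fasta, read_genbank)
from .composition import region_composition
from .codon_usage import (codon_usage_frame, count_codons, detect_start_stop,
                          genetic_code, rscu)
from .divergence import (GeneAlignment, mean_gene_distance, mean_kaks,
                         nucleotide_diversity, sliding_window_pi)
from .annotation_model import extract_feature_sequence
from .phylogeny import (bootstrap_support, concatenate, tree_to_newick,
                        write_newick)
from .simulate import SimulationConfig, SimulatedDataset, simulate_clade

logger = logging.getLogger("mitocompare")

# the concatenated gene set used for the phylogeny: 13 PCGs + 2 rRNAs in
# genome order
PHYLO_GENE_TYPES = ("PCG", "rRNA")


@dataclass
class RunConfig:
    out_dir: str = "mitocompare_out"
    window: int = 500
    step: int = 100
    bootstrap_reps: int = 1000
    seed: int = 0
    genetic_code_id: int = 2
    simulate: bool = False
    genbank_paths: list[str] = field(default_factory=list)
    fasta_path: Optional[str] = None
    table_path: Optional[str] = None
    genes_dir: Optional[str] = None     # per-gene aligned FASTA, name = gene

    def __post_init__(self) -> None:
        if self.step < 1 or self.window < self.step:
            raise ValueError("need window >= step >= 1")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


def load_genomes(config: RunConfig) -> dict[str, MitoGenome]:
    genomes: dict[str, MitoGenome] = {}
    for p in config.genbank_paths:
        g = read_genbank(p)
        genomes[g.accession] = g
    if config.table_path:
        g = read_annotation_table(config.table_path)
        if config.fasta_path:
            seqs = read_fasta(config.fasta_path)
            name, seq = next(iter(seqs.items()))
            g = MitoGenome(accession=name, length=len(seq), circular=True,
                           sequence=seq, features=g.features)
        genomes[g.accession] = g
    return genomes


def load_gene_alignments(genes_dir) -> dict[str, GeneAlignment]:
    alns = {}
    for path in sorted(Path(genes_dir).glob("*.fasta")):
        gene = path.stem.replace("_", " ") if "rRNA" in path.stem else path.stem
        alns[gene] = GeneAlignment(gene, read_fasta(path))
    return alns


def gene_alignments_from_genomes(
        genomes: dict[str, MitoGenome]) -> dict[str, GeneAlignment]:
    """Ungapped per-gene 'alignments' from annotated genomes.

    Only genes present in every genome with identical extracted lengths are
    returned; anything else needs an externally aligned FASTA.
    """
    names = [f.name for f in next(iter(genomes.values())).features]
    out = {}
    for name in names:
        seqs = {}
        for taxon, g in genomes.items():
            try:
                seqs[taxon] = extract_feature_sequence(g, g.feature(name))
            except (KeyError, Exception):
                seqs = {}
                break
        if len(seqs) == len(genomes) and len({len(s) for s in seqs.values()}) == 1:
            out[name] = GeneAlignment(name, seqs)
        else:
            logger.warning("%s: unequal lengths across genomes; supply an "
                           "aligned FASTA for this gene", name)
    return out


def load_clade_from_genbank(directory) -> tuple[dict[str, MitoGenome],
                                                dict[str, GeneAlignment]]:
    """Load every GenBank record in a directory as one clade.

    Returns the genomes plus ungapped per-gene alignments for the genes
    annotated in all records with identical extracted lengths (congeneric
    mitogenomes usually satisfy this for most genes; supply aligned FASTA
    for the rest).
    """
    genomes: dict[str, MitoGenome] = {}
    for path in sorted(Path(directory).glob("*.gb")) + \
            sorted(Path(directory).glob("*.gbk")):
        g = read_genbank(path)
        genomes[g.accession] = g
    if not genomes:
        raise FileNotFoundError(f"no GenBank records under {directory}")
    return genomes, gene_alignments_from_genomes(genomes)


@dataclass
class AnalysisReport:
    provenance: dict
    per_genome: dict
    per_gene: dict
    tree_newick: Optional[str] = None
    failed_stages: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "provenance": self.provenance, "per_genome": self.per_genome,
            "per_gene": self.per_gene, "tree_newick": self.tree_newick,
            "failed_stages": self.failed_stages}, indent=1, default=str)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(vars(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_all(config: RunConfig,
            dataset: Optional[SimulatedDataset] = None) -> AnalysisReport:
    """Execute every stage; write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(
        provenance={"package": f"mitocompare {__version__}",
                    "seed": config.seed, "config_hash": _config_hash(config)},
        per_genome={}, per_gene={})

    if config.simulate and dataset is None:
        dataset = simulate_clade(SimulationConfig(seed=config.seed))
    if dataset is not None:
        genomes = dataset.genomes
        alignments = dict(dataset.alignments)
    else:
        genomes = load_genomes(config)
        alignments = (load_gene_alignments(config.genes_dir)
                      if config.genes_dir else
                      gene_alignments_from_genomes(
                          {k: g for k, g in genomes.items()
                           if g.sequence is not None}) if len(genomes) > 1
                      else {})
    if not genomes and not alignments:
        raise ValueError("no inputs: provide genomes, alignments or --simulate")

    code = genetic_code(config.genetic_code_id)

    # --- per-genome structural + composition + codon stages -----------------
    for name, g in genomes.items():
        entry: dict = {"length": g.length,
                       "n_features": len(g.features)}
        try:
            rep = layout_report(g)
            entry["layout"] = {
                "total_overlap_bp": rep.total_overlap_bp,
                "total_spacer_bp": rep.total_spacer_bp,
                "max_overlap": rep.max_overlap,
                "counts_by_type": rep.counts_by_type}
            pd.DataFrame(rep.gaps, columns=["after", "before", "gap"]).to_csv(
                out / f"{name}.layout.tsv", sep="\t", index=False)
        except Exception as exc:
            logger.error("layout stage failed for %s: %s", name, exc)
            report.failed_stages.append(f"layout:{name}")
        if g.sequence is None:
            entry["composition"] = "skipped: no sequence"
            entry["codon_usage"] = "skipped: no sequence"
            report.per_genome[name] = entry
            continue
        try:
            whole = region_composition(g, "whole").iloc[0]
            entry["composition"] = {
                "at_content": round(float(whole.at_content), 2),
                "at_skew": round(float(whole.at_skew), 3),
                "gc_skew": round(float(whole.gc_skew), 3)}
            region_composition(g, "per-gene").to_csv(
                out / f"{name}.composition.tsv", sep="\t", index=False)
        except Exception as exc:
            logger.error("composition stage failed for %s: %s", name, exc)
            report.failed_stages.append(f"composition:{name}")
        try:
            cds = {f.name: extract_feature_sequence(g, f)
                   for f in g.features_of_type("PCG")}
            counts = count_codons(cds, code)
            table = rscu(counts, code)
            codon_usage_frame(counts, table, code).to_csv(
                out / f"{name}.codon_usage.tsv", sep="\t", index=False)
            entry["codon_usage"] = {"total_codons": counts.total}
            entry["start_stop"] = {
                gene: (r.start_codon, r.stop_codon)
                for gene, r in ((gn, detect_start_stop(s, code, gn))
                                for gn, s in cds.items())}
        except Exception as exc:
            logger.error("codon stage failed for %s: %s", name, exc)
            report.failed_stages.append(f"codon_usage:{name}")
        report.per_genome[name] = entry

    # --- divergence + tree stages -------------------------------------------
    if alignments:
        rows = []
        for gene, aln in alignments.items():
            row = {"gene": gene}
            try:
                row["pi"] = nucleotide_diversity(aln)
                row["mean_k2p"] = mean_gene_distance(aln)
            except Exception as exc:
                logger.error("diversity failed for %s: %s", gene, exc)
                report.failed_stages.append(f"diversity:{gene}")
            template = next(iter(genomes.values())) if genomes else None
            is_pcg = bool(template and gene in
                          {f.name for f in template.features_of_type("PCG")})
            if is_pcg:
                try:
                    kk = mean_kaks(aln, code)
                    row["ka"], row["ks"] = kk.ka, kk.ks
                    row["kaks"] = kk.ratio if kk.ratio_defined else None
                except Exception as exc:
                    logger.error("kaks failed for %s: %s", gene, exc)
                    report.failed_stages.append(f"kaks:{gene}")
            rows.append(row)
            report.per_gene[gene] = {k: v for k, v in row.items() if k != "gene"}
        pd.DataFrame(rows).to_csv(out / "per_gene_stats.tsv", sep="\t",
                                  index=False)

        try:
            template = next(iter(genomes.values())) if genomes else None
            if template is not None:
                order = [f.name for f in template.features
                         if f.ftype in PHYLO_GENE_TYPES and f.name in alignments]
            else:
                order = sorted(alignments)
            concat = concatenate({g: alignments[g] for g in order}, order)
            profile = sliding_window_pi(concat.as_alignment(),
                                        config.window, config.step)
            pd.DataFrame(profile.windows,
                         columns=["start", "end", "midpoint", "pi"]).to_csv(
                out / "sliding_window_pi.tsv", sep="\t", index=False)
            if len(concat.taxa) >= 3 and config.bootstrap_reps:
                tree = bootstrap_support(concat, config.bootstrap_reps,
                                         config.seed)
                report.tree_newick = tree_to_newick(tree)
                write_newick(tree, out / "tree.nwk")
        except Exception as exc:
            logger.error("tree stage failed: %s", exc)
            report.failed_stages.append("tree")

    (out / "report.json").write_text(report.to_json())
    return report
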