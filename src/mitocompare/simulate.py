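"""Synthetic 4-taxon clade of annotated, duck-like circular mitogenomes.

The generator builds a ~16.6 kb ancestral genome on the layout of a real
diving-duck mitogenome annotation (13 PCGs, 22 tRNAs, 2 rRNAs, one control
region, with the real overlap/spacer structure), then evolves it down a
guide tree under a Kimura 2-parameter nucleotide process.  Protein-coding
genes evolve under an acceptance-rejection codon layer: synonymous
proposals are always accepted, amino-acid-changing proposals are accepted
with probability omega (purifying selection, omega << 1), and proposals
creating stop codons are rejected.  Per-gene rate multipliers spread
nucleotide diversity over roughly 0.01-0.08, the range observed across
mitochondrial genes in small waterfowl clades.

Everything is driven by one seeded numpy Generator, so a given
(seed, config) pair reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .annotation_model import (GeneFeature, MitoGenome, extract_feature_sequence,
                               load_reference_annotation, splice_feature_sequence,
                               write_annotation_table, write_fasta)
from .codon_usage import GeneticCode, iter_codons, vertebrate_mito_code
from .divergence import GeneAlignment

logger = logging.getLogger("mitocompare")

NUCS = "ACGT"
_NUC_IDX = {c: i for i, c in enumerate(NUCS)}
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# the paper-scale clade: (T1,T2) vs (T3,T4) with a deep internal split
DEFAULT_GUIDE_TREE = ("((americana:0.012,ferina:0.012):0.006,"
                      "(fuligula:0.016,baeri:0.020):0.006);")

# base composition solved from AT% = 51.95, AT-skew 0.143, GC-skew -0.362
DEFAULT_COMPOSITION = (0.2969, 0.3272, 0.1533, 0.2226)   # A, C, G, T

# Per-gene proposal-rate multipliers.  For protein-coding genes the realized
# nucleotide rate is multiplier x acceptance (see expected_acceptance), with
# acceptance ~ 0.31-0.37 under the default omegas, so these values put the
# realized per-gene Pi in the ~0.01-0.08 band seen across mitochondrial genes
# in shallow waterfowl clades (ND3/ND4L fastest, ATP8 and the rRNAs slowest).
DEFAULT_RATE_MULTIPLIERS = {
    "ND1": 3.4, "ND2": 3.5, "COI": 3.5, "COII": 2.2, "ATP8": 0.93,
    "ATP6": 3.0, "COIII": 2.9, "ND3": 6.2, "ND4L": 5.7, "ND4": 3.5,
    "ND5": 3.2, "ND6": 3.5, "Cytb": 2.9,
    "12S rRNA": 0.40, "16S rRNA": 0.30, "CR": 2.0,
}
DEFAULT_TRNA_MULTIPLIER = 0.4

# purifying selection throughout; ATP8 weakest, COII strongest constraint
DEFAULT_OMEGA = {
    "ND1": 0.040, "ND2": 0.050, "COI": 0.020, "COII": 0.010, "ATP8": 0.105,
    "ATP6": 0.070, "COIII": 0.030, "ND3": 0.065, "ND4L": 0.060, "ND4": 0.050,
    "ND5": 0.045, "ND6": 0.055, "Cytb": 0.025,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    guide_tree: str = DEFAULT_GUIDE_TREE
    kappa: float = 8.0                       # transition/transversion rate ratio
    base_composition: tuple = DEFAULT_COMPOSITION
    rate_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_RATE_MULTIPLIERS))
    trna_multiplier: float = DEFAULT_TRNA_MULTIPLIER
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    template: Optional[MitoGenome] = None    # defaults to the packaged layout

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-6:
            raise ValueError("base composition must sum to 1")
        if not (self.kappa >= 0):
            raise ValueError("kappa must be >= 0")
        for g, w in self.omega.items():
            if not (0 < w <= 1):
                raise ValueError(f"omega[{g}] must be in (0, 1]")
        for g, m in self.rate_multipliers.items():
            if m <= 0:
                raise ValueError(f"rate multiplier for {g} must be > 0")

    def multiplier(self, feature: GeneFeature) -> float:
        if feature.name in self.rate_multipliers:
            return self.rate_multipliers[feature.name]
        if feature.ftype == "tRNA":
            return self.trna_multiplier
        return 1.0


@dataclass
class SimulatedDataset:
    """Four annotated genomes plus the truth behind them."""

    config: SimulationConfig
    genomes: dict[str, MitoGenome]
    alignments: dict[str, GeneAlignment]           # gene -> gapless alignment
    true_distances: dict[str, dict[str, float]]    # gene -> {"a|b": subs/site}
    true_omega: dict[str, float]


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

def _expected_stop(feature: GeneFeature, code: GeneticCode) -> str:
    """Template terminal-stop constraint, derived from coordinates.

    A CDS whose recomputed length is not a multiple of 3 gets the incomplete
    stop implied by its length even if the annotation table printed a full
    one (annotation tables occasionally disagree with their own coordinates
    by one base).
    """
    rem = feature.length() % 3
    if rem == 1:
        return "T-"
    if rem == 2:
        return "TA-"
    stop = feature.stop_codon or "TAA"
    return stop if stop in code.stop_codons else "TAA"


def _pcg_violations(cds: str, start_codon: str, stop_marker: str,
                    code: GeneticCode) -> list[tuple[str, int]]:
    """(kind, codon index) list of constraint violations for one CDS."""
    out = []
    if cds[:3] != start_codon:
        out.append(("start", 0))
    codons = list(iter_codons(cds))
    full_stop = not stop_marker.endswith("-")
    last = len(codons) - 1
    for idx, codon in enumerate(codons):
        if idx == last and full_stop:
            if codon != stop_marker:
                out.append(("stop", idx))
        elif code.is_stop(codon):
            out.append(("internal", idx))
    if not full_stop:
        tail = stop_marker[:-1]
        if cds[len(cds) - len(tail):] != tail:
            out.append(("tail", last + 1))
    return out


def build_ancestor(config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> MitoGenome:
    """Random genome at the target composition satisfying the PCG template.

    Each PCG is rewritten (in annotation order) to carry its template start
    codon, no in-frame internal stops, and its template (possibly
    incomplete) stop.  Overlapping genes are reconciled by iterated repair:
    fixes are re-applied in random positions until every gene's constraints
    hold simultaneously — the later feature wins any genuinely contested
    base, and residual conflicts raise rather than pass silently.
    """
    rng = rng or np.random.default_rng(config.seed)
    code = vertebrate_mito_code()
    template = config.template or load_reference_annotation()
    if any(f.ftype == "PCG" and f.length(template.length) < 6
           for f in template.features):
        raise ValueError("template PCG shorter than 6 nt")
    seq = "".join(rng.choice(list(NUCS), size=template.length,
                             p=config.base_composition))
    genome = MitoGenome(accession="ancestor", length=template.length,
                        circular=template.circular, sequence=seq,
                        features=[GeneFeature(**{k: getattr(f, k) for k in (
                            "name", "ftype", "strand", "start", "end",
                            "anticodon", "start_codon", "stop_codon")})
                            for f in template.features])
    _repair_pcgs(genome, rng, code)
    return genome


def _repair_pcgs(genome: MitoGenome, rng: np.random.Generator,
                 code: GeneticCode) -> None:
    """Iterated stochastic repair until every PCG satisfies its template.

    Overlapping genes constrain shared bases in two reading frames at once;
    fixes are re-applied with randomized positions until all constraints
    hold simultaneously (the joint constraint set is satisfiable for
    layouts whose overlaps leave each violated codon a free base, as
    vertebrate mitogenome layouts do).  Non-convergence raises.
    """
    pcgs = genome.features_of_type("PCG")
    for _ in range(300):
        dirty = False
        for f in pcgs:
            cds = extract_feature_sequence(genome, f)
            start_codon = f.start_codon or "ATG"
            stop_marker = _expected_stop(f, code)
            viol = _pcg_violations(cds, start_codon, stop_marker, code)
            if not viol:
                continue
            dirty = True
            cds = list(cds)
            for kind, idx in viol:
                if kind == "start":
                    cds[0:3] = start_codon
                elif kind == "stop":
                    cds[-3:] = stop_marker
                elif kind == "tail":
                    tail = stop_marker[:-1]
                    cds[len(cds) - len(tail):] = tail
                else:  # internal stop: randomize one position of the codon
                    pos = 3 * idx + int(rng.integers(3))
                    cds[pos] = NUCS[int(rng.integers(4))]
            genome.sequence = splice_feature_sequence(genome.sequence, f,
                                                      "".join(cds))
        if not dirty:
            return
    raise RuntimeError("PCG constraint repair did not converge")


def validate_pcgs(genome: MitoGenome,
                  code: Optional[GeneticCode] = None) -> list[str]:
    """Human-readable list of PCG constraint violations (empty when clean).

    Relative to the ancestor-construction constraints, an evolved genome is
    allowed any start in {ATG, GTG} and any terminal codon from the stop
    set — the codon process legitimately toggles within those sets.
    """
    code = code or vertebrate_mito_code()
    problems = []
    for f in genome.features_of_type("PCG"):
        cds = extract_feature_sequence(genome, f)
        stop_marker = _expected_stop(f, code)
        for kind, idx in _pcg_violations(cds, f.start_codon or "ATG",
                                         stop_marker, code):
            if kind == "start" and cds[:3] in ("ATG", "GTG"):
                continue
            if kind == "stop" and code.is_stop(cds[3 * idx:3 * idx + 3]):
                continue
            problems.append(f"{f.name}: {kind} at codon {idx}")
    return problems


# ---------------------------------------------------------------------------
# substitution processes
# ---------------------------------------------------------------------------

def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) of the K80 chain at distance d."""
    bt = d / (kappa + 2.0)          # beta * t
    at = d * kappa / (kappa + 2.0)  # alpha * t
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * bt)
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    return float(p_ts), float(p_tv)


def evolve_k2p(seq: str, d: float, kappa: float,
               rng: np.random.Generator) -> str:
    """Evolve a sequence for expected ``d`` substitutions/site under K2P.

    Sites are independent; each site is resampled from the exact K80
    transition matrix at distance d, so the realized divergence is unbiased
    for any d.  Non-ACGT symbols are left untouched.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d == 0 or not seq:
        return seq
    p_ts, p_tv = _k2p_site_probs(d, kappa)
    u = rng.random(len(seq))
    out = list(seq)
    for i, ch in enumerate(seq):
        if ch not in _TS_PARTNER:
            continue
        if u[i] < p_ts:
            out[i] = _TS_PARTNER[ch]
        elif u[i] < p_ts + 2 * p_tv:
            tv = _TV_PARTNERS[ch]
            out[i] = tv[0] if u[i] < p_ts + p_tv else tv[1]
    return "".join(out)


def evolve_codon(cds: str, d: float, kappa: float, omega: float,
                 rng: np.random.Generator,
                 code: Optional[GeneticCode] = None,
                 preserve_ends: bool = True) -> str:
    """Evolve an in-frame CDS under K2P proposals filtered by selection.

    Proposal events arrive as a Poisson process with intensity ``d`` per
    site; the target base follows the K2P kernel (transitions kappa times
    each transversion).  Synonymous proposals are always accepted, so
    synonymous-site divergence tracks ``d``; amino-acid-changing proposals
    are accepted with probability ``omega``; proposals creating a stop are
    rejected.  With ``preserve_ends`` the start codon may only toggle within
    {ATG, GTG} and a full terminal stop within the stop set; a trailing
    incomplete stop (1-2 nt) is held fixed.
    """
    if not (0 <= omega <= 1):
        raise ValueError("omega must be in [0, 1]")
    code = code or vertebrate_mito_code()
    rem = len(cds) % 3
    body_len = len(cds) - rem
    out = list(cds)
    n_events = rng.poisson(d * body_len)
    p_ts = kappa / (kappa + 2.0)
    last_codon = body_len // 3 - 1
    for _ in range(n_events):
        pos = int(rng.integers(body_len))
        ch = out[pos]
        if ch not in _TS_PARTNER:
            continue
        u = rng.random()
        if u < p_ts:
            new = _TS_PARTNER[ch]
        else:
            tv = _TV_PARTNERS[ch]
            new = tv[0] if u < (1.0 + p_ts) / 2.0 else tv[1]
        ci = pos // 3
        codon = out[3 * ci:3 * ci + 3]
        old_codon = "".join(codon)
        codon[pos % 3] = new
        new_codon = "".join(codon)
        if preserve_ends and ci == 0 and new_codon not in ("ATG", "GTG"):
            continue
        if preserve_ends and ci == last_codon and code.is_stop(old_codon):
            if new_codon not in code.stop_codons:
                continue
            out[pos] = new
            continue
        if code.is_stop(new_codon):
            continue
        if any(c not in NUCS for c in old_codon):
            out[pos] = new
            continue
        if code.translate(new_codon) != code.translate(old_codon):
            if rng.random() >= omega:
                continue
        out[pos] = new
    return "".join(out)


def expected_acceptance(cds: str, kappa: float, omega: float,
                        code: Optional[GeneticCode] = None) -> float:
    """Expected fraction of codon-process proposals that fix.

    Averages, over all sites of the CDS and the K2P proposal kernel
    (transitions weighted ``kappa``, each transversion 1), the acceptance
    probability: 1 for synonymous, ``omega`` for amino-acid-changing, 0 for
    stop-creating proposals.  The realized nucleotide divergence of
    :func:`evolve_codon` at proposal intensity ``d`` is ~ ``d`` times this.
    """
    code = code or vertebrate_mito_code()
    p_ts = kappa / (kappa + 2.0)
    p_tv = 1.0 / (kappa + 2.0)
    num = den = 0.0
    for codon in iter_codons(cds):
        if code.is_stop(codon) or any(c not in NUCS for c in codon):
            continue
        aa = code.translate(codon)
        for i in range(3):
            ch = codon[i]
            for tgt, w in ((_TS_PARTNER[ch], p_ts),
                           (_TV_PARTNERS[ch][0], p_tv),
                           (_TV_PARTNERS[ch][1], p_tv)):
                mut = codon[:i] + tgt + codon[i + 1:]
                den += w
                if code.is_stop(mut):
                    continue
                num += w if code.translate(mut) == aa else w * omega
    return num / den if den else 1.0


# ---------------------------------------------------------------------------
# clade simulation
# ---------------------------------------------------------------------------

def _evolve_genome(parent: MitoGenome, branch_d: float,
                   config: SimulationConfig, rng: np.random.Generator,
                   code: GeneticCode, label: str) -> MitoGenome:
    seq = parent.sequence
    covered = np.zeros(parent.length + 1, dtype=bool)
    for f in parent.features:
        covered[f.positions(parent.length)] = True
        seg = extract_feature_sequence(parent, f)
        d = branch_d * config.multiplier(f)
        if f.ftype == "PCG":
            omega = config.omega.get(f.name, 0.05)
            new_seg = evolve_codon(seg, d, config.kappa, omega, rng, code)
        else:
            new_seg = evolve_k2p(seg, d, config.kappa, rng)
        seq = splice_feature_sequence(seq, f, new_seg)
    # intergenic spacers evolve like the control region
    free = [i for i in range(1, parent.length + 1) if not covered[i]]
    if free:
        d = branch_d * config.rate_multipliers.get("CR", 1.0)
        evolved = evolve_k2p("".join(seq[i - 1] for i in free), d,
                             config.kappa, rng)
        seq_list = list(seq)
        for i, ch in zip(free, evolved):
            seq_list[i - 1] = ch
        seq = "".join(seq_list)
    child = MitoGenome(accession=label, length=parent.length,
                       circular=parent.circular, sequence=seq,
                       features=parent.features)
    # overlap zones may have broken a neighbour's frame; re-establish the
    # template constraints (touches at most a few bases per branch)
    _repair_pcgs(child, rng, code)
    return child


def simulate_clade(config: SimulationConfig) -> SimulatedDataset:
    """Evolve the ancestor down the guide tree; return genomes + truth.

    Per-gene truth distances are guide-tree path lengths scaled by the
    gene's rate multiplier.  PCGs evolve under the codon process with the
    gene's omega; tRNAs, rRNAs, the control region and spacers under plain
    K2P.
    """
    rng = np.random.default_rng(config.seed)
    code = vertebrate_mito_code()
    tree = dendropy.Tree.get(data=config.guide_tree, schema="newick")
    ancestor = build_ancestor(config, rng)

    genomes: dict[str, MitoGenome] = {}

    def descend(dnode, genome: MitoGenome) -> None:
        for child in dnode.child_nodes():
            d = child.edge.length or 0.0
            label = (child.taxon.label.replace(" ", "_")
                     if child.is_leaf() else "internal")
            g = _evolve_genome(genome, d, config, rng, code, label)
            if child.is_leaf():
                genomes[label] = g
            else:
                descend(child, g)

    descend(tree.seed_node, ancestor)

    alignments: dict[str, GeneAlignment] = {}
    for f in ancestor.features:
        alignments[f.name] = GeneAlignment(
            f.name, {t: extract_feature_sequence(g, g.feature(f.name))
                     for t, g in genomes.items()})

    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(genomes)
    path: dict[str, float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            ta = tree.taxon_namespace.get_taxon(a.replace("_", " ")) or \
                tree.taxon_namespace.get_taxon(a)
            tb = tree.taxon_namespace.get_taxon(b.replace("_", " ")) or \
                tree.taxon_namespace.get_taxon(b)
            path[f"{a}|{b}"] = pdm.patristic_distance(ta, tb)
    # PCG truth is damped by selection: only a fraction of proposals fix
    true_distances = {}
    for f in ancestor.features:
        scale = config.multiplier(f)
        if f.ftype == "PCG":
            scale *= expected_acceptance(
                extract_feature_sequence(ancestor, f), config.kappa,
                config.omega.get(f.name, 0.05), code)
        true_distances[f.name] = {pair: d * scale for pair, d in path.items()}
    return SimulatedDataset(config=config, genomes=genomes,
                            alignments=alignments,
                            true_distances=true_distances,
                            true_omega=dict(config.omega))


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    """FASTA per taxon, shared annotation TSV, per-gene alignments, truth JSON."""
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    for taxon, genome in dataset.genomes.items():
        write_fasta({taxon: genome.sequence}, out / f"{taxon}.fasta")
    any_genome = next(iter(dataset.genomes.values()))
    write_annotation_table(any_genome, out / "annotation.tsv")
    for gene, aln in dataset.alignments.items():
        safe = gene.replace(" ", "_").replace("/", "_")
        write_fasta(aln.sequences, out / "genes" / f"{safe}.fasta")
    truth = {"true_distances": dataset.true_distances,
             "true_omega": dataset.true_omega,
             "guide_tree": dataset.config.guide_tree,
             "kappa": dataset.config.kappa,
             "seed": dataset.config.seed}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
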