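# mitocompare

Comparative statistics for small clades of animal mitochondrial genomes —
built around the kind of question a conservation geneticist asks when a new
mitogenome of a threatened species (here, a ~16.6 kb diving-duck genome
with 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one control region) is
compared against its congeners:

* **Annotation layout arithmetic** — gene overlaps and intergenic spacers
  from a 1-based annotation table (GenBank flat file or TSV), with circular
  wrap-around handled by modular coordinates.
* **Base composition** — A+T content and the strand-asymmetry skews
  AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), whole-genome, per gene
  (coding-strand oriented) or pooled per gene class.
* **Codon usage** — start/stop detection including incomplete stops
  ("T-", "TA-"), pooled codon counts and relative synonymous codon usage
  (RSCU) under the vertebrate mitochondrial code (transl_table 2:
  AGA/AGG stop, ATA=Met, TGA=Trp).
* **Divergence** — nucleotide diversity π (mean pairwise difference
  proportion, pairwise deletion), sliding-window π profiles (default
  500 bp windows every 100 bp), Kimura 2-parameter distances
  d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), and Nei–Gojobori (1986) Ka/Ks with
  minimal-pathway counting and Jukes–Cantor correction.
* **Phylogeny** — neighbor joining on K2P distances over a concatenated
  13-PCG + 2-rRNA gene set, with column-resampling bootstrap support and
  newick I/O.
* **Simulation** — a seeded generator producing a 4-taxon clade of
  annotated circular genomes evolved down a guide tree (K2P nucleotide
  process; codon-level purifying selection with per-gene ω ≪ 1; per-gene
  rate multipliers), with a truth file so every estimator above can be
  checked against known parameters.

## Worked example

```python
import mitocompare as mc

ds = mc.simulate_clade(mc.SimulationConfig(seed=0))   # 4 annotated genomes

genome = next(iter(ds.genomes.values()))
rep = mc.layout_report(genome)
print(rep.total_overlap_bp, rep.max_overlap)          # 35 ('ATP8', 'ATP6', 10)

print(round(mc.nucleotide_diversity(ds.alignments["ND3"]), 4))      # 0.0668
print(round(mc.nucleotide_diversity(ds.alignments["16S rRNA"]), 4)) # 0.0109

print(round(mc.mean_kaks(ds.alignments["ATP8"]).ratio, 4))          # 0.1284
print(round(mc.mean_kaks(ds.alignments["COII"]).ratio, 4))          # 0.0

genes = [f.name for f in genome.features if f.ftype in ("PCG", "rRNA")]
concat = mc.concatenate({g: ds.alignments[g] for g in genes}, genes)
tree = mc.bootstrap_support(concat, 100, seed=1)
print(mc.tree_to_newick(tree, precision=4))
# (baeri:0.0174,fuligula:0.0141,(americana:0.0112,ferina:0.0101)100:0.0097);
```

Reading the output: the genomes share the layout of the annotation template
(35 bp of gene overlap, the largest 10 bp between ATP8 and ATP6); ND3 is
the most variable gene and the rRNAs the most conserved, as set by the
per-gene rate multipliers; Ka/Ks ≪ 1 everywhere reflects the purifying
selection built into the codon process, strongest for COII and weakest for
ATP8; and neighbor joining recovers the guide tree's (americana, ferina)
split with 100 % bootstrap support.

The same analyses run from the shell:

```sh
mitocompare simulate --seed 0 --out sim/
mitocompare annotate-stats --table sim/annotation.tsv --out-dir out/
mitocompare diversity --genes sim/genes --out-dir out/
mitocompare kaks --genes sim/genes --out-dir out/
mitocompare tree --genes sim/genes --bootstrap 1000 --seed 1 --out out/tree.nwk
mitocompare run --simulate --seed 0 --out-dir out/   # everything + report.json
```

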