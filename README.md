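# pheroscan

Rule-based annotation of fungal mating pheromone genes, their mature peptides
and their seven-transmembrane receptors — the gene family that drives partner
recognition in ascomycete sexual reproduction. The package targets the kind
of survey done across families such as the *Ceratocystidaceae*, where
pheromone genes are too short, too fast-evolving and too repeat-laden for
standard gene predictors, and where curators instead apply a small set of
biochemical rules to raw genome sequence. It is written for comparative
genomicists who want those rules as reproducible, testable code rather than
manual annotation.

## What it computes

**a-pheromone genes** are short, intron-free ORFs encoding a hydrophobic
N-terminus with no secretion signal and a C-terminal prenylation motif
*CaaX* / *CpaX* (Cys, aliphatic-or-polar, aliphatic, any residue) immediately
before the stop codon. `scan-a` translates every contig in all six reading
frames, finds stop codons directly preceded by a motif, and evaluates every
in-frame Met within 100 codons upstream as a candidate start. The 6–11
residues preceding each motif Cys, plus that Cys (7–12 aa total), are the
candidate mature peptide; with multiple repeats the reported peptide per
motif maximises mean identity to the other repeats' candidates, and repeat
similarity is reported as a support score.

**α-pheromone precursors** carry an N-terminal secretion signal and 1–13
tandem mature peptides released by Kex2 (cuts after Lys-Arg) and Ste13
(trims X-Ala/X-Pro dipeptides). `scan-alpha` detects the signal with a
hydropathy heuristic, locates both kinds of cleavage site, and reports the
9–15 aa segment upstream of each site that passes a Levitt beta-turn screen,
together with its central residue (typically Gly; Trp in some lineages).

**Receptors**: `classify-receptor` predicts membrane-spanning segments as
maximal runs of 19-residue Kyte–Doolittle windows with mean hydropathy
≥ 1.6, and calls a candidate putatively functional iff exactly seven
segments are found. The C-terminal compartment follows by parity from an
extracellular N-terminus: 7 TM → cytoplasmic (functional topology), 6 →
extracellular, 3 → cytoplasmic.

**Comparative layer**: pairwise percent identity from end-to-end global
alignments (BLOSUM62, gap open 10 / extend 0.5, identity over alignment
length), unique-peptide censuses, Clinker-style locus microsynteny
(mutual-best homolog links at ≥ 30% identity, focal-position conservation),
and a seeded permutation test for association between pheromone/receptor
features and mating strategy (heterothallic, primary homothallic,
mating-type switching, unisexual).

**Synthetic data**: `pheroscan simulate` plants ground-truth genes,
precursors, receptors, locus pairs and strategy cohorts with machine-readable
truth sets, so every caller is validated by recovery against known answers.

## Worked example

Generate a two-contig synthetic genome with planted a-pheromone genes, then
scan it:

```bash
$ pheroscan simulate a-genome --seed 42 --out sim --n 2
wrote a-genome (seed 42) to sim
$ pheroscan scan-a --genome sim/genome.fasta --out out
2 candidate gene(s), 2 putatively functional
```

`out/a_calls.gff3` locates each call (1-based inclusive coordinates,
minus-strand genes on forward coordinates):

```text
contig_s42_g0  pheroscan  pheromone_gene  272  430  .  +  .  ID=contig_s42_g0:+:427;verdict=putatively_functional;n_mature_peptides=4
contig_s42_g1  pheroscan  pheromone_gene  259  336  .  -  .  ID=contig_s42_g1:-:258;verdict=putatively_functional;n_mature_peptides=1
```

and `out/a_peptides.tsv` lists the mature peptides:

```text
contig         gene_id              peptide     length  motif_kind  support
contig_s42_g0  contig_s42_g0:+:427  TRKKVDC     7       CaaX        1.0000
contig_s42_g0  contig_s42_g0:+:427  TRKKVDC     7       CaaX        1.0000
contig_s42_g0  contig_s42_g0:+:427  TRKKVDC     7       CaaX        1.0000
contig_s42_g0  contig_s42_g0:+:427  TRKKVDC     7       CaaX        1.0000
contig_s42_g1  contig_s42_g1:-:258  GFGQNYKGAC  10      CaaX        0.0000
```

The first gene encodes four identical 7-residue repeats, each followed by its
own CaaX motif — hence support 1.0 (a perfect within-protein repeat match);
the second is a single-copy gene on the minus strand, so no repeat support is
available. α-precursors work the same way from protein FASTA:

```bash
$ pheroscan simulate alpha-set --seed 42 --out sim --n 2
$ pheroscan scan-alpha --proteins sim/precursors.fasta --out out
2 precursor(s), 2 putatively functional
```

`out/alpha_calls.tsv` then reports, per precursor, one row per mature
peptide (here 7 identical copies of `RLKVESGGNYSTST`, central Gly, beta-turn
present) with its cleavage-bounded span.

Other subcommands: `classify-receptor`, `compare-peptides`, `synteny`,
`strategy-summary`, and `run-all` (whole pipeline from a YAML manifest, with
a deterministic `summary.json`). All thresholds live in a YAML config
(`--config`); defaults are documented in `docs/methods.md`.

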