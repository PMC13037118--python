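# Methods

This note documents the models and rules pheroscan implements, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions that were genuinely open.

## Sequence primitives

Translation uses the standard nuclear genetic code (NCBI table 1); the fungi
this tool targets use no alternative nuclear code. Stops render as `*`. Any
codon containing `N` renders as `X`, and every downstream scanner treats `X`
as matching nothing — assembly gaps therefore suppress motif and cleavage
calls rather than fabricating them. Ambiguous nucleotides other than `N` are
rejected as invalid input. Coordinates are 0-based half-open internally;
emitted GFF3 is 1-based inclusive, with minus-strand features reported on
forward-strand coordinates.

## Physicochemical profiles

Sliding-window profiles replace interactive profile servers with documented,
configurable heuristics. Two published 20-value scales ship as packaged
TSVs: Kyte–Doolittle (1982) hydropathy and the Levitt (1978) beta-turn
preference scale (sanity property: G, P, N, D score above I, V, L). `X`
scores as the scale mean, i.e. neutrally.

* **Transmembrane segments** (`tm.*`): window 19 (a membrane-spanning helix
  is ~19–21 residues), threshold 1.6 on the window mean (the classical
  cutoff for putative TM segments on this scale), minimum loop 3. Maximal
  runs of qualifying window centers are expanded to full window extent and
  merged when closer than the minimum loop. The count is what matters
  downstream: a receptor is putatively functional iff exactly 7 segments.
* **Topology**: the N-terminus is taken extracellular (GPCR convention) and
  each membrane pass flips the compartment, so the C-terminus is cytoplasmic
  for odd TM counts and extracellular for even counts. This parity rule
  reproduces the three anchored cases the callers rely on (7 → cytoplasmic,
  6 → extracellular, 3 → cytoplasmic).
* **Secretion signal** (`signal.*`): present iff the first 35 residues
  contain an 8-residue window with mean hydropathy ≥ 2.0 (h-region) and a
  Lys/Arg occurs in the first 5 residues (n-region). A signal-peptidase-like
  c-region (small residues at −3/−1 of a candidate cleavage point within 10
  residues after the core) is flagged as corroborating evidence but does not
  gate the call, and the mature region is taken to start at the end of the
  hydrophobic core — the first cleavage site bounds the first peptide, so a
  precise peptidase position is not needed. This heuristic is deliberately
  simpler than an HMM-based predictor; it is dependency-free, reproducible,
  and adequate for rule-grade gating, and all thresholds are exposed in the
  config.
* **Beta turn** (`turn.threshold`): a peptide "has a predicted beta turn"
  iff some 4-residue window (turns are 4-residue motifs) has mean Levitt
  propensity ≥ 1.0, the neutral propensity.

## a-pheromone calling

Six-frame scan: every stop codon whose preceding four residues form a
CaaX/CpaX motif seeds candidates from each in-frame Met within 100 codons
upstream with no intervening stop (the 300-bp window standard for this gene
family). Residue classes: aliphatic `a` ∈ {A,V,L,I}; polar `p` ∈ {N,S,T,Q},
Gln included because curated CpaX motifs with Gln at the polar position are
known in this family. Both sets are config-overridable; whether Met/Phe
should also count as aliphatic is unresolved in the curation literature, so
the default stays conservative (a motif like CVMA is not called unless the
class is extended).

Protein gates: mean Kyte–Doolittle over the first 10 residues ≥ 0.8
(hydrophobic N-terminus; the qualitative published traces do not pin a
number, so this is a repository choice surfaced in `nterm.*`), no secretion
signal, terminal motif present. A candidate whose ORF region contains an
internal stop is reported as `rejected:early_stop` — the pseudogene-style
configuration seen in real genomes — rather than silently dropped.

Start choice: among the Met candidates the reported call uses the most
upstream one whose protein passes all gates, falling back to the most
upstream Met. Real upstream sequence can contribute an in-frame Met whose
longer protein fails the hydrophobic-N gate even though a downstream start
is a textbook pheromone; choosing the most upstream *validating* start is
what a curator does by hand. All candidate offsets are retained on the call.
Calls are deduplicated by (contig, strand, stop position), which is the
natural key since overlapping ORFs in different frames of the same stop
cannot occur.

Mature peptides: one per motif, length 7–12 including the Cys. Candidate
windows never cross the previous motif (repeats abut their upstream
neighbour's motif completion); a motif with fewer than six preceding
residues yields no peptide. With several motifs the reported candidate per
motif maximises mean pairwise identity to the other motifs' candidates
(repeat consensus), ties to the longest; a lone motif reports its longest
candidate, an explicit tie-break since published repeat tables report a
single sequence per repeat without stating the rule. Support is the best
identity fraction against the other reported peptides (or an external
library), 0 when none exist.

## α-pheromone calling

Gates: secretion signal present and at least one mature peptide passing the
beta-turn screen; reject reasons are `no_signal`, `no_cleavage_sites`,
`no_turn_peptide`. Cleavage sites: Kex2 = Lys-Arg dipeptide, cut after the
Arg (Arg-Arg optionally enabled); Ste13 = runs of X-Ala/X-Pro dipeptides.
Ste13 runs are taken anchored at the signal end and at every Kex2 cut (one
dipeptide suffices there), **and de novo anywhere on the precursor when at
least two consecutive dipeptides are present**. The de novo rule is what
makes STE13-only precursors — a configuration that does occur in this gene
family — parseable at all: their interior spacers are never reachable from
an anchored scan. Two dipeptides keep the pattern specific (~1% per position
on random sequence).

Extraction: for each cleavage site, the segment runs from the previous cut
(or the signal end) to the start of the site's motif; leading X-[AP]
dipeptides are trimmed; candidates are segment suffixes of length 9–15; the
longest candidate passing the beta-turn screen is reported, with the central
residue at floor(length/2) (an explicit convention for even lengths). The
tail after the last cut is not a peptide by default — nothing flanks it
downstream — but `alpha.include_terminal_segment` restores it. The
functional gate requires ≥ 1 passing peptide rather than all, with
per-peptide turn flags retained, since requiring every repeat to pass is the
stricter reading and not obviously intended.

## Comparative layer

Percent identity: end-to-end global alignment, BLOSUM62, gap open 10 /
extend 0.5, terminal gaps penalised; identity = identical aligned positions
/ alignment length × 100. Interactive-workbench "default settings" are not
portable, so these parameters are fixed and exposed in `align.*`; defining
identity over alignment length (not shortest sequence) is the second half of
that decision and a known source of small numeric differences from other
tools. The aligner backend accepts integer penalties only, so the matrix and
penalties are doubled internally (−20/−1) and scores halved — exact, not an
approximation. With co-optimal alignments the backend's first optimum is
used; tests assert against the full co-optimal set of a brute-force
enumerator.

Censuses are exact-string deduplications in lexicographic order. The
strategy cross-tab aggregates per-species features (peptide counts and
lengths, gene copies, receptor functionality, locus conservation) into
count/mean/min/max cells per mating strategy, leaving missing data missing.

The permutation test makes the qualitative question "does any feature track
mating strategy?" explicit: statistic = between-group sum of squares of
group means; null by seeded label shuffling; p = (1 + #{perm ≥ obs}) /
(1 + n_perm). It is plumbing around the biology, not a published procedure,
and is labelled as such.

## Microsynteny

Loci are ordered gene lists around a focal gene. Candidate links need ≥ 30%
global identity (config `synteny.min_identity`; ribbon-plot tools in this
space use a comparable floor), links are mutual best pairs, and identity
ties resolve toward the partner closest to the focal gene — paralog
tie-breaking is a repository choice. Gene order and orientation are reported
but not required for a link (real loci contain inversions). A locus pair has
a conserved focal position when both immediate flanks are linked; a flank
missing at a contig edge scores unknown, not mismatch, and the conserved
fraction is computed over pairs with at least one evaluable flank.

## Synthetic data: what it emulates, what it does not

The generator produces the structural grammar the callers assume, at the
copy-number and length ranges observed in real surveys of this family:
a-genes with 1–5 repeats of 7–10 aa mature peptides (the callers accept
7–12), α-precursors with 1–13 copies on KEX-only / STE13-only / mixed site
plans and central Gly or Trp, receptors with 0–8 planted membrane stretches,
locus pairs with ~80%-identity homolog pairs and unrelated decoy genes, and
strategy cohorts where a continuous trait is shifted by a configurable
effect (in SD units) per strategy — effect 0 encodes the no-association
null. Codon choice is uniform over synonyms under the seed; there is no
codon-usage model, no introns, no real base composition, and no assembly
gaps other than the deliberate X spacer below. Passing the recovery suites
therefore shows the rules are implemented correctly, not that the heuristics
match HMM-grade predictors on real proteins — on real data TM counts and
signal calls can differ from Phobius-style output, which is why validation
is against generator truth.

Constructions that make truth exactly recoverable (all documented so the
tests' meaning is clear):

* every planted a-gene is bracketed by `TTAATTAATTAA`, a palindromic
  all-six-frame stop guard, so the 100-codon start window never extends into
  background and the planted Met is the most upstream clean start;
* the a-gene leader ends in one `NNN` codon (an assembly-gap-style `X`
  residue), so mature-peptide candidates cannot extend into the leader and
  single-copy genes are recovered verbatim;
* background and decoy DNA is scrubbed by iterative local resampling until
  no reading frame contains a motif-before-stop (synonymous codon swaps
  inside genes, free base swaps elsewhere) — decoy specificity tests are
  meaningful because the decoys are certified motif-free, by the same rule
  the scanner applies;
* receptor stretches are 21-mers over {I,L,V,F,A} (worst-case window mean
  1.8 ≥ threshold 1.6) separated by 25–40 aa hydrophilic loops. With window
  19, a qualifying window needs ≥ 8 stretch residues even in the best
  hydrophilic background, so expanded segments from adjacent stretches stay
  ≥ 3 apart whenever loops are ≥ 25 — no merging; and because sliding into a
  stretch adds a residue ≥ 1.8 while dropping one ≤ −0.4, window means are
  monotone on entry/exit and fully-interior windows always qualify — no
  splitting. Segment count equals planted count by construction, not by
  luck. (The spec floor of ≥ 8-residue loops is respected as a minimum; the
  default is larger for this guarantee, and 25–40 aa is unremarkable for
  GPCR loops.)
* α mature peptides are rejection-sampled against content that would move
  cleavage boundaries: internal Lys-Arg, X-[AP] dipeptide runs in cleavage
  phase, and Ala/Pro at the second or last position (which would let an
  adjacent Ste13 run eat into the peptide). The generator refuses such
  peptides rather than planting unrecoverable truth.

## Problem sizes and numerics

The validation suites use 200 a-genomes (1–3 genes each) plus 50 decoys, 500
α-precursors, 40 receptors per planted TM count in {3,4,6,7,8}, 50 locus
pairs, 1,000 null cohorts (permutation n_perm = 199 for calibration, 999 for
single tests), and exhaustive motif scans over all ≤ 6-mers of a 6-letter
alphabet plus random longer strings — sizes at which every suite runs in
seconds to a couple of minutes on one core while still exercising every
frame, strand, site plan and degenerate receptor form. Determinism is a
contract: all randomness flows through seeded `numpy` generators, output
ordering is fully specified (GFF3 by contig and start, censuses
lexicographic, matrices in input order), and reruns are byte-identical.

## Known limitations

* TM/signal heuristics are hydropathy-only: no evolutionary information, no
  posterior probabilities, no helix orientation beyond the parity rule.
  Merged adjacent helices in real degenerate receptors are reported as one
  segment; there is no split heuristic.
* Receptor class (a- vs α-receptor orthology) is metadata, not inferred;
  homology search is out of scope by design.
* α-genes are called from protein input only; finding them in unannotated
  DNA requires an external gene model, unlike the intron-free a-genes.
* Identity values can differ from other aligners' output where co-optimal
  alignments exist or where identity is normalised differently.
* The permutation test assumes exchangeability across species; it ignores
  phylogenetic non-independence, so a significant result on real data would
  still need a phylogeny-aware follow-up.
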