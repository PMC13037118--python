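"""Seeded synthetic-data generator with machine-readable truth sets.

Stands in, at desk scale, for real genome assemblies: plants a-pheromone ORFs
(hydrophobic leader, 1-5 mature-peptide repeats each ending in CaaX/CpaX,
terminal motif immediately before the stop) in decoy DNA, builds
alpha-pheromone precursors (signal peptide, 1-13 tandem mature peptides on a
KEX2-only, STE13-only or mixed cleavage plan), receptor proteins with planted
membrane-spanning stretches, homologous locus pairs, and mating-strategy
cohorts. Every output is deterministic under its seed and is accompanied by a
TruthRecord sufficient to verify caller output without re-deriving the rules.

Construction guarantees (see docs/methods.md for the arithmetic):

* planted a-genes are bracketed by all-frame stop guards so the start-codon
  window never escapes into background, and an assembly-gap-style X residue
  terminates the leader so the first mature peptide is exactly recoverable;
* background/decoy DNA is iteratively resampled until no reading frame
  contains a spurious CaaX/CpaX-before-stop (synonymous codon swaps inside
  planted genes, free base swaps elsewhere);
* receptor loops are 25-40 hydrophilic residues, long enough that predicted
  hydrophobic segments can neither merge nor split, so the predicted count
  equals the planted count exactly;
* alpha mature peptides are rejection-checked against patterns that would
  shift cleavage boundaries (internal Lys-Arg, X-[AP] dipeptide runs in
  cleavage phase, A/P at the second or last position).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd

from pheroscan.config import PipelineConfig
from pheroscan.motifs import classify_caax
from pheroscan.profiles import has_beta_turn
from pheroscan.seqio import (CODON_TO_AA, SIX_FRAMES, Frame, SequenceRecord,
                             reverse_complement, translate)
from pheroscan.synteny import LocusGene, LocusNeighborhood
from pheroscan.compare import MATING_STRATEGIES

HYDROPHOBIC = "ILVFA"      # leader / membrane-stretch alphabet
HYDROPHILIC = "DENQSKRG"   # loop / background-protein alphabet
GUARD = "TTAATTAATTAA"     # palindromic; a stop codon in all six frames

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


@dataclass
class TruthRecord:
    """Ground truth for one generated object."""

    kind: str
    seed: int
    data: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "seed": self.seed, "data": self.data},
                          sort_keys=True, default=str)


def _encode(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA, synonymous codons uniform; X becomes NNN."""
    codons = []
    for aa in protein:
        if aa == "X":
            codons.append("NNN")
        else:
            options = _CODONS_BY_AA[aa]
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _spurious_motif_stops(dna: str, allowed: set[tuple[str, int]],
                          cfg: PipelineConfig) -> list[tuple[Frame, int]]:
    """Motif-before-stop occurrences not in the allowed (strand, fwd pos) set."""
    bad = []
    for frame in SIX_FRAMES:
        prot = translate(dna, frame)
        for j in range(4, len(prot)):
            if prot[j] != "*":
                continue
            if classify_caax(prot[j - 4:j], cfg.caax) is None:
                continue
            if frame.strand == "+":
                stop_fwd = frame.offset + 3 * j
            else:
                stop_fwd = len(dna) - (frame.offset + 3 * (j + 1))
            if (frame.strand, stop_fwd) not in allowed:
                bad.append((frame, j))
    return bad


def _violation_window(dna_len: int, frame: Frame, j: int) -> tuple[int, int]:
    """Forward-strand window covering the motif 4-mer before stop codon j."""
    start = frame.offset + 3 * (j - 4)
    end = frame.offset + 3 * j
    if frame.strand == "-":
        start, end = dna_len - end, dna_len - start
    return max(0, start), min(dna_len, end)


def _scrub_dna(dna: str, allowed: set[tuple[str, int]],
               protected: list[tuple[int, int, int, str]],
               rng: np.random.Generator, cfg: PipelineConfig,
               max_iter: int = 200) -> str:
    """Iteratively remove spurious motif-stops from a contig.

    ``protected`` lists (start, end, cds_start, protein) regions whose protein
    must be preserved: bases there are re-encoded synonymously per codon;
    guard regions (protein None-like, marked by empty protein) are immutable;
    everything else is resampled freely.
    """
    seq = list(dna)
    for _ in range(max_iter):
        bad = _spurious_motif_stops("".join(seq), allowed, cfg)
        if not bad:
            return "".join(seq)
        for frame, j in bad[:8]:
            w0, w1 = _violation_window(len(seq), frame, j)
            touched = False
            for pos in range(w0, w1):
                region = next(((s, e, cs, p) for s, e, cs, p in protected
                               if s <= pos < e), None)
                if region is None:
                    seq[pos] = "ACGT"[rng.integers(4)]
                    touched = True
            for s, e, cs, prot in protected:
                if prot and s < w1 and e > w0:
                    lo = max(w0, s) - cs
                    hi = min(w1, e) - cs
                    for codon_idx in range(lo // 3, (hi + 2) // 3):
                        if 0 <= codon_idx < len(prot) and prot[codon_idx] != "X":
                            options = _CODONS_BY_AA[prot[codon_idx]]
                            if len(options) > 1:
                                new = options[rng.integers(len(options))]
                                seq[cs + 3 * codon_idx: cs + 3 * codon_idx + 3] = new
                                touched = True
            if not touched:
                raise RuntimeError("cannot scrub a spurious motif inside an "
                                   "immutable region")
    raise RuntimeError("background scrubbing did not converge")


def _complete_motif(kind: str, rng: np.random.Generator,
                    cfg: PipelineConfig) -> str:
    """The three residues following a mature peptide's terminal Cys."""
    aliphatic, polar = cfg.caax.aliphatic, cfg.caax.polar
    # X position: any residue except Cys, which would seed a second motif
    x_alphabet = "ADEFGHIKLMNQSTVWY"
    tail = x_alphabet[rng.integers(len(x_alphabet))]
    if kind == "CaaX":
        return (aliphatic[rng.integers(len(aliphatic))]
                + aliphatic[rng.integers(len(aliphatic))] + tail)
    if kind == "CpaX":
        return (polar[rng.integers(len(polar))]
                + aliphatic[rng.integers(len(aliphatic))] + tail)
    raise ValueError(f"unknown motif kind {kind!r}")


def random_a_mature(rng: np.random.Generator, length: int | None = None) -> str:
    """A random a-type mature peptide (7-10 aa, Cys-terminal), avoiding Cys
    and Met elsewhere so motif and start-codon structure stay unambiguous."""
    if length is None:
        length = int(rng.integers(7, 11))
    body_alphabet = "ADEFGHIKLNQRSTVWY"
    body = "".join(body_alphabet[rng.integers(len(body_alphabet))]
                   for _ in range(length - 1))
    return body + "C"


def a_protein_layout(mature: str, n_repeats: int, motif_kind: str,
                     rng: np.random.Generator,
                     cfg: PipelineConfig) -> tuple[str, TruthRecord]:
    """Assemble the precursor protein and per-repeat truth spans."""
    if not 7 <= len(mature) <= 12 or not mature.endswith("C"):
        raise ValueError("mature peptide must be 7-12 residues ending in Cys")
    leader = "M" + "".join(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
                           for _ in range(10)) + "X"
    parts = [leader]
    spans = []
    pos = len(leader)
    for _ in range(n_repeats):
        parts.append(mature)
        spans.append([pos, pos + len(mature)])
        pos += len(mature)
        completion = _complete_motif(motif_kind, rng, cfg)
        parts.append(completion)
        pos += len(completion)
    protein = "".join(parts)
    truth = TruthRecord(kind="a_gene", seed=0, data={
        "protein": protein, "mature": mature, "n_repeats": n_repeats,
        "motif_kind": motif_kind, "repeat_spans": spans,
    })
    return protein, truth


def make_a_gene(mature: str, n_repeats: int, frame: Frame, motif_kind: str,
                seed: int,
                cfg: PipelineConfig = PipelineConfig()
                ) -> tuple[SequenceRecord, TruthRecord]:
    """A standalone a-pheromone gene record readable at the requested frame.

    The DNA encodes Met + hydrophobic leader + ``n_repeats`` mature-peptide
    copies, each completed to a CaaX/CpaX motif, with the terminal motif
    immediately before the stop codon. Codon choice is uniform over synonyms
    under the seed; the record is reverse-complemented for minus-strand
    frames and padded so the gene sits at the requested frame offset.
    """
    if not 1 <= n_repeats <= 5:
        raise ValueError("n_repeats must be in 1..5")
    rng = np.random.default_rng(seed)
    protein, truth = a_protein_layout(mature, n_repeats, motif_kind, rng, cfg)
    for attempt in range(20):
        # scrub other-frame artefacts; the gene CDS is re-encoded synonymously.
        # A structurally stuck motif (rare) triggers a rebuild with fresh codons.
        cds = _encode(protein, rng) + "TAA"
        pad = _random_dna(frame.offset, rng)
        forward = pad + cds
        stop_fwd_plus = frame.offset + len(cds) - 3
        try:
            scrubbed = _scrub_dna(forward, {("+", stop_fwd_plus)},
                                  [(frame.offset, len(forward), frame.offset,
                                    protein + "*")], rng, cfg)
            break
        except RuntimeError:
            if attempt == 19:
                raise
    if frame.strand == "+":
        dna = scrubbed
        stop_fwd = stop_fwd_plus
    else:
        dna = reverse_complement(scrubbed)
        stop_fwd = len(dna) - stop_fwd_plus - 3
    truth.seed = seed
    truth.data.update({
        "strand": frame.strand, "frame_offset": frame.offset,
        "stop_fwd": stop_fwd,
        "cds_span": [frame.offset, frame.offset + len(cds)] if frame.strand == "+"
        else [len(dna) - frame.offset - len(cds), len(dna) - frame.offset],
    })
    record = SequenceRecord(id=f"a_gene_s{seed}", seq=dna, alphabet="dna",
                            description="synthetic a-pheromone gene")
    return record, truth


def make_a_genome(seed: int, n_genes: int = 1,
                  cfg: PipelineConfig = PipelineConfig()
                  ) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Contigs with planted a-pheromone genes in decoy background.

    One contig per gene: background, an all-frame stop guard, the gene
    (random strand, 1-5 repeats of a random 7-10 aa mature peptide, CaaX or
    CpaX), a second guard, and more background. Background is scrubbed of
    spurious motif-before-stop signals so the planted gene is the only call.
    """
    rng = np.random.default_rng(seed)
    contigs, truths = [], []
    for g in range(n_genes):
        mature = random_a_mature(rng)
        n_repeats = int(rng.integers(1, 6))
        motif_kind = "CaaX" if rng.integers(2) == 0 else "CpaX"
        strand = "+" if rng.integers(2) == 0 else "-"

        def build() -> tuple[str, int, TruthRecord]:
            protein, truth = a_protein_layout(mature, n_repeats, motif_kind,
                                              rng, cfg)
            cds = _encode(protein, rng) + "TAA"
            gene = cds if strand == "+" else reverse_complement(cds)
            bg_left = _random_dna(int(rng.integers(150, 400)), rng)
            bg_right = _random_dna(int(rng.integers(150, 400)), rng)
            contig = bg_left + GUARD + gene + GUARD + bg_right
            g0 = len(bg_left) + len(GUARD)
            if strand == "+":
                stop_fwd = g0 + len(cds) - 3
                protected = [(g0, g0 + len(cds), g0, protein + "*"),
                             (len(bg_left), g0, 0, ""),
                             (g0 + len(cds), g0 + len(cds) + len(GUARD), 0, "")]
                contig = _scrub_dna(contig, {("+", stop_fwd)}, protected,
                                    rng, cfg)
            else:
                stop_fwd = g0
                # scrub on the forward strand of the reverse-complemented contig
                rc = reverse_complement(contig)
                rc_g0 = len(bg_right) + len(GUARD)
                protected = [(rc_g0, rc_g0 + len(cds), rc_g0, protein + "*"),
                             (len(bg_right), rc_g0, 0, ""),
                             (rc_g0 + len(cds), rc_g0 + len(cds) + len(GUARD),
                              0, "")]
                rc = _scrub_dna(rc, {("+", rc_g0 + len(cds) - 3)}, protected,
                                rng, cfg)
                contig = reverse_complement(rc)
            truth.data.update({"cds_len": len(cds)})
            return contig, g0, truth

        # local scrubbing can hit a structurally stuck motif (every synonymous
        # recoding stays rule-conformant on the other strand); rebuild the
        # contig with fresh codon/background draws in that rare case
        for attempt in range(20):
            try:
                contig, g0, truth = build()
                break
            except RuntimeError:
                if attempt == 19:
                    raise
        cds_len = truth.data.pop("cds_len")
        cds = contig[g0:g0 + cds_len]
        stop_fwd = g0 + cds_len - 3 if strand == "+" else g0
        truth.seed = seed
        truth.data.update({
            "contig": f"contig_s{seed}_g{g}", "strand": strand,
            "stop_fwd": stop_fwd,
            "cds_span": [g0, g0 + len(cds)],
        })
        contigs.append(SequenceRecord(id=f"contig_s{seed}_g{g}", seq=contig,
                                      alphabet="dna",
                                      description="synthetic contig with planted a-pheromone gene"))
        truths.append(truth)
    return contigs, truths


def make_decoy_contig(seed: int, length: int = 1500,
                      cfg: PipelineConfig = PipelineConfig()) -> SequenceRecord:
    """A motif-free decoy contig: no frame contains CaaX/CpaX before a stop."""
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        try:
            dna = _scrub_dna(_random_dna(length, rng), set(), [], rng, cfg)
            break
        except RuntimeError:
            if attempt == 19:
                raise
    return SequenceRecord(id=f"decoy_s{seed}", seq=dna, alphabet="dna",
                          description="synthetic decoy contig")


_ALPHA_SIGNAL_CORE = 7   # hydrophobic residues after Met-Lys


def _alpha_signal(rng: np.random.Generator) -> str:
    core = "".join("LIV"[rng.integers(3)] for _ in range(_ALPHA_SIGNAL_CORE))
    return "MK" + core + "ASA"


def check_alpha_mature(mature: str) -> None:
    """Reject mature peptides whose content would shift cleavage boundaries."""
    if not 9 <= len(mature) <= 15:
        raise ValueError("alpha mature peptide must be 9-15 residues")
    if not has_beta_turn(mature):
        raise ValueError("alpha mature peptide must contain a predicted beta turn")
    if "KR" in mature or "X" in mature:
        raise ValueError("mature peptide must not contain an internal KEX2 site or X")
    if mature[1] in "AP" or mature[-1] in "AP":
        raise ValueError("A/P at the second or last residue would extend an "
                         "adjacent STE13 run into the peptide")
    for i in range(len(mature) - 3):
        if mature[i + 1] in "AP" and mature[i + 3] in "AP":
            raise ValueError("internal X-[AP] dipeptide run would be read as "
                             "an STE13 site")


def random_alpha_mature(rng: np.random.Generator, length: int | None = None,
                        central: str = "G") -> str:
    """A random recoverable alpha mature peptide with the given central residue."""
    if length is None:
        length = int(rng.integers(9, 16))
    alphabet = "DEFGHIKLNQRSTVWY"
    for attempt in range(1000):
        residues = [alphabet[rng.integers(len(alphabet))] for _ in range(length)]
        residues[length // 2] = central
        if attempt % 2 == 1:
            # guarantee a turn-prone patch clear of the centre (length >= 9
            # puts the centre at index >= 4)
            residues[0:4] = list("GNSG")
            residues[length // 2] = central
        peptide = "".join(residues)
        try:
            check_alpha_mature(peptide)
        except ValueError:
            continue
        return peptide
    raise RuntimeError("could not sample a recoverable alpha mature peptide")


def make_alpha_precursor(mature: str, n_copies: int,
                         site_plan: Literal["kex_only", "ste13_only", "mixed"],
                         seed: int) -> tuple[SequenceRecord, TruthRecord]:
    """An alpha-pheromone precursor protein with planted mature peptides.

    Layouts (S = 12-residue signal, P = mature peptide):
    kex_only   S KR (P KR){n} tail
    ste13_only S (EAEA P){n} EAEA tail
    mixed      S KR (EAEA P KR){n} tail
    """
    if not 1 <= n_copies <= 13:
        raise ValueError("n_copies must be in 1..13")
    check_alpha_mature(mature)
    rng = np.random.default_rng(seed)
    signal = _alpha_signal(rng)
    parts = [signal]
    cuts: list[int] = []
    spans: list[list[int]] = []
    pos = len(signal)

    def add(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    if site_plan == "kex_only":
        add("KR"); cuts.append(pos)
        for _ in range(n_copies):
            spans.append([pos, pos + len(mature)])
            add(mature)
            add("KR"); cuts.append(pos)
    elif site_plan == "ste13_only":
        for _ in range(n_copies):
            add("EAEA"); cuts.extend([pos - 2, pos])
            spans.append([pos, pos + len(mature)])
            add(mature)
        add("EAEA"); cuts.extend([pos - 2, pos])
    elif site_plan == "mixed":
        add("KR"); cuts.append(pos)
        for _ in range(n_copies):
            add("EAEA"); cuts.extend([pos - 2, pos])
            spans.append([pos, pos + len(mature)])
            add(mature)
            add("KR"); cuts.append(pos)
    else:
        raise ValueError(f"unknown site plan {site_plan!r}")
    add("DED")
    protein = "".join(parts)
    record = SequenceRecord(id=f"alpha_s{seed}", seq=protein, alphabet="protein",
                            description=f"synthetic alpha-pheromone precursor ({site_plan})")
    truth = TruthRecord(kind="alpha_precursor", seed=seed, data={
        "mature": mature, "n_copies": n_copies, "site_plan": site_plan,
        "signal_end": len(signal), "cut_positions": cuts, "peptide_spans": spans,
        "peptides": [mature] * n_copies,
    })
    return record, truth


def make_receptor_protein(n_tm: int, seed: int
                          ) -> tuple[SequenceRecord, TruthRecord]:
    """A receptor-like protein with ``n_tm`` planted membrane stretches.

    Stretches are 21-mers over {I,L,V,F,A} separated by 25-40 residue
    hydrophilic loops; loop length guarantees the hydropathy detector reports
    exactly one segment per stretch (no merge, no split).
    """
    if not 0 <= n_tm <= 8:
        raise ValueError("n_tm must be in 0..8")
    rng = np.random.default_rng(seed)

    def loop(n: int) -> str:
        return "".join(HYDROPHILIC[rng.integers(len(HYDROPHILIC))] for _ in range(n))

    def stretch() -> str:
        return "".join(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))] for _ in range(21))

    parts = [loop(int(rng.integers(20, 31)))]
    spans = []
    pos = len(parts[0])
    for i in range(n_tm):
        s = stretch()
        spans.append([pos, pos + 21])
        parts.append(s)
        pos += 21
        n_loop = int(rng.integers(25, 41))
        parts.append(loop(n_loop))
        pos += n_loop
    protein = "".join(parts)
    record = SequenceRecord(id=f"receptor_s{seed}_tm{n_tm}", seq=protein,
                            alphabet="protein",
                            description="synthetic pheromone-receptor candidate")
    truth = TruthRecord(kind="receptor", seed=seed,
                        data={"n_tm": n_tm, "tm_spans": spans})
    return record, truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join("ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)] for _ in range(length))


def _mutate(protein: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ~fraction of positions (bounded mutation, no indels)."""
    residues = list(protein)
    n_mut = int(round(fraction * len(residues)))
    for pos in rng.choice(len(residues), size=n_mut, replace=False):
        choices = "ACDEFGHIKLMNPQRSTVWY".replace(residues[pos], "")
        residues[pos] = choices[rng.integers(len(choices))]
    return "".join(residues)


def make_locus_pair(n_shared: int, n_unique: int, invert_focal: bool, seed: int
                    ) -> tuple[LocusNeighborhood, LocusNeighborhood, TruthRecord]:
    """Two locus neighbourhoods sharing ``n_shared`` homolog pairs.

    The focal gene is always shared (so ``n_shared`` >= 1); shared partners
    are ~80%-identity mutated copies, unique genes are unrelated random
    proteins added to each locus. ``invert_focal`` flips the second locus'
    gene order and strands (inversion events do not break homology links).
    """
    if n_shared < 1:
        raise ValueError("the focal gene is always shared: n_shared >= 1")
    rng = np.random.default_rng(seed)
    shared = [_random_protein(rng, int(rng.integers(150, 251)))
              for _ in range(n_shared)]
    partners = [_mutate(p, 0.2, rng) for p in shared]
    focal_idx = n_shared // 2
    genes_a, genes_b, links = [], [], []
    for i, (pa, pb) in enumerate(zip(shared, partners)):
        tag = "focal" if i == focal_idx else f"shared{i}"
        genes_a.append(LocusGene(f"A_{tag}", "+", pa))
        genes_b.append(LocusGene(f"B_{tag}", "+", pb))
        links.append([f"A_{tag}", f"B_{tag}"])
    for u in range(n_unique):
        genes_a.append(LocusGene(f"A_unique{u}", "+",
                                 _random_protein(rng, int(rng.integers(150, 251)))))
        genes_b.append(LocusGene(f"B_unique{u}", "+",
                                 _random_protein(rng, int(rng.integers(150, 251)))))
    # distribute unique genes to the outer edges, keep shared genes central
    half = n_unique // 2
    genes_a = genes_a[n_shared:n_shared + half] + genes_a[:n_shared] + genes_a[n_shared + half:]
    genes_b = genes_b[n_shared:n_shared + half] + genes_b[:n_shared] + genes_b[n_shared + half:]
    if invert_focal:
        genes_b = [LocusGene(g.gene_id, "-" if g.strand == "+" else "+", g.protein)
                   for g in reversed(genes_b)]
    locus_a = LocusNeighborhood("species_A", f"locusA_s{seed}", genes_a, "A_focal")
    locus_b = LocusNeighborhood("species_B", f"locusB_s{seed}", genes_b, "B_focal")
    truth = TruthRecord(kind="locus_pair", seed=seed, data={
        "n_shared": n_shared, "n_unique": n_unique,
        "invert_focal": invert_focal, "links": links,
    })
    return locus_a, locus_b, truth


def make_strategy_cohort(n_per_strategy: int, effect: float, seed: int
                         ) -> tuple[pd.DataFrame, dict[str, str], TruthRecord]:
    """A cohort of species with per-strategy feature tables.

    Discrete pheromone/receptor features are drawn strategy-independently
    from the ranges the callers produce (1-13 alpha copies, 9-15 aa peptides,
    1-3 gene copies); the continuous ``trait`` column is N(idx * effect, 1)
    per strategy, so effect 0 encodes a strategy-independent null and
    ``effect`` is the between-group shift in SD units.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    strategies: dict[str, str] = {}
    for idx, strategy in enumerate(MATING_STRATEGIES):
        for i in range(n_per_strategy):
            species = f"sp_{strategy}_{i}"
            strategies[species] = strategy
            rows.append({
                "species": species,
                "n_mature_peptides": int(rng.integers(1, 14)),
                "mean_peptide_length": float(rng.uniform(9, 15)),
                "n_gene_copies": int(rng.integers(1, 4)),
                "receptor_functional": float(rng.random() < 0.9),
                "locus_conserved": float(rng.random()),
                "trait": float(rng.normal(idx * effect, 1.0)),
            })
    features = pd.DataFrame(rows)
    truth = TruthRecord(kind="strategy_cohort", seed=seed, data={
        "n_per_strategy": n_per_strategy, "effect": effect,
        "strategies": list(MATING_STRATEGIES),
    })
    return features, strategies, truth
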