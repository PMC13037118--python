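"""a-pheromone gene discovery.

The a-pheromone precursor is a short protein with a hydrophobic N-terminus, no
secretion signal, and a C-terminal CaaX/CpaX prenylation motif; multi-repeat
precursors carry an internal motif after every mature peptide. Genes are found
by translating contigs in all six reading frames, locating stop codons whose
preceding four residues form a CaaX/CpaX motif, and considering every in-frame
Met within 100 codons upstream (no intervening stop) as a candidate start.

Mature peptides are the 6-11 residues immediately preceding each motif Cys,
together with that Cys (total length 7-12); when a precursor carries several
motifs the reported peptide per motif is chosen by repeat consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from pheroscan.compare import percent_identity
from pheroscan.config import PipelineConfig
from pheroscan.motifs import MotifHit, classify_caax, find_caax_motifs
from pheroscan.profiles import detect_signal_peptide, n_term_hydrophobicity
from pheroscan.seqio import SIX_FRAMES, Frame, SequenceRecord, translate

logger = logging.getLogger(__name__)


@dataclass
class MaturePeptide:
    """A mature pheromone peptide excised from its precursor."""

    sequence: str
    start: int
    end: int
    motif_kind: str
    support: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class APheromoneCall:
    """A candidate a-pheromone gene with its evidence trail."""

    contig: str
    strand: Literal["+", "-"]
    frame_offset: int
    cds_start: int          # forward-strand, 0-based half-open, includes stop codon
    cds_end: int
    protein: str
    start_candidates: list[int] = field(default_factory=list)  # protein-relative Met offsets
    mature_peptides: list[MaturePeptide] = field(default_factory=list)
    evidence: dict[str, bool] = field(default_factory=dict)
    internal_motifs: int = 0
    verdict: str = "rejected:unvalidated"

    @property
    def functional(self) -> bool:
        return self.verdict == "putatively_functional"


def validate_a_protein(protein: str, cfg: PipelineConfig = PipelineConfig()) -> APheromoneCall:
    """Apply the a-pheromone protein rules to a candidate protein.

    Evidence: terminal CaaX/CpaX motif, hydrophobic N-terminus (mean
    Kyte-Doolittle over the first ``cfg.nterm.k`` residues at or above
    ``cfg.nterm.threshold``) and absence of a secretion signal. The verdict is
    putatively_functional only when all three hold; an internal stop codon is
    reported as rejected:early_stop (pseudogene-style candidates).
    """
    if not protein:
        raise ValueError("cannot validate an empty protein")
    call = APheromoneCall(contig="", strand="+", frame_offset=0,
                          cds_start=0, cds_end=0, protein=protein)
    if "*" in protein:
        call.verdict = "rejected:early_stop"
        return call
    hits = find_caax_motifs(protein, cfg.caax)
    terminal = any(h.terminal for h in hits)
    call.internal_motifs = sum(1 for h in hits if not h.terminal)
    if len(protein) < max(cfg.nterm.k, 4):
        call.verdict = "rejected:too_short"
        return call
    hydrophobic = n_term_hydrophobicity(protein, cfg.nterm.k) >= cfg.nterm.threshold
    no_signal = True
    if len(protein) >= 15:
        no_signal = not detect_signal_peptide(protein, cfg.signal).present
    call.evidence = {
        "terminal_motif": terminal,
        "hydrophobic_nterm": hydrophobic,
        "no_signal_peptide": no_signal,
    }
    if not terminal:
        call.verdict = "rejected:no_terminal_motif"
    elif not hydrophobic:
        call.verdict = "rejected:hydrophilic_nterm"
    elif not no_signal:
        call.verdict = "rejected:has_signal_peptide"
    else:
        call.verdict = "putatively_functional"
    if terminal:
        call.mature_peptides = extract_a_mature_peptides(protein, hits, cfg)
    return call


def _candidate_peptides(protein: str, hit: MotifHit, lower_bound: int,
                        cfg: PipelineConfig) -> list[MaturePeptide]:
    """All admissible peptide windows ending at a motif's Cys."""
    c = hit.cys
    max_preceding = c - lower_bound
    candidates = []
    for n in range(cfg.a_pheromone.mature_min - 1,
                   min(cfg.a_pheromone.mature_max - 1, max_preceding) + 1):
        seq = protein[c - n:c + 1]
        if "X" in seq:
            continue
        candidates.append(MaturePeptide(sequence=seq, start=c - n, end=c + 1,
                                        motif_kind=hit.kind))
    return candidates


def extract_a_mature_peptides(protein: str, hits: Sequence[MotifHit],
                              cfg: PipelineConfig = PipelineConfig()) -> list[MaturePeptide]:
    """One mature peptide per CaaX/CpaX motif, chosen by repeat consensus.

    Candidates for a motif are bounded below by the end of the previous motif
    (repeats abut their upstream neighbour's motif completion); a motif with
    fewer than six preceding residues yields no peptide. With several motifs
    the reported candidate maximises mean identity to the other motifs'
    candidates, ties broken by length; a lone motif reports its longest
    candidate. Support is the best identity fraction to the other reported
    peptides.
    """
    hits = sorted(hits, key=lambda h: h.start)
    per_hit: list[list[MaturePeptide]] = []
    for idx, hit in enumerate(hits):
        lower = hits[idx - 1].end if idx > 0 else 0
        per_hit.append(_candidate_peptides(protein, hit, lower, cfg))
    chosen: list[MaturePeptide] = []
    for idx, candidates in enumerate(per_hit):
        if not candidates:
            continue
        others = [c for j, cands in enumerate(per_hit) if j != idx for c in cands]
        if not others:
            best = max(candidates, key=lambda p: p.length)
        else:
            def consensus_score(pep: MaturePeptide) -> float:
                scores = []
                for j, cands in enumerate(per_hit):
                    if j == idx or not cands:
                        continue
                    scores.append(max(percent_identity(pep.sequence, o.sequence,
                                                       cfg.align) for o in cands))
                return sum(scores) / len(scores)
            best = max(candidates, key=lambda p: (consensus_score(p), p.length))
        chosen.append(best)
    for pep in chosen:
        library = [o for o in chosen if o is not pep]
        pep.support = repeat_support(pep, library, cfg)
    return chosen


def repeat_support(peptide: MaturePeptide, library: Sequence[MaturePeptide],
                   cfg: PipelineConfig = PipelineConfig()) -> float:
    """Best identity fraction between a peptide and any library peptide.

    Similar repeats within the same protein or in related precursors support a
    mature-peptide prediction; an empty library scores 0.
    """
    if not library:
        return 0.0
    return max(percent_identity(peptide.sequence, other.sequence, cfg.align)
               for other in library) / 100.0


def _forward_span(frame: Frame, contig_len: int, codon_start: int,
                  codon_end: int) -> tuple[int, int]:
    """Map a codon range [codon_start, codon_end) to forward-strand DNA coords."""
    start = frame.offset + 3 * codon_start
    end = frame.offset + 3 * codon_end
    if frame.strand == "+":
        return start, end
    return contig_len - end, contig_len - start


def scan_genome_for_a_pheromones(records: Sequence[SequenceRecord],
                                 cfg: PipelineConfig = PipelineConfig()
                                 ) -> list[APheromoneCall]:
    """Six-frame scan of contigs for CaaX/CpaX-terminated ORFs.

    Every stop codon directly preceded by a motif seeds candidate ORFs from
    each in-frame Met within ``cfg.a_pheromone.start_window_codons`` codons
    upstream with no intervening stop. The reported call uses the most
    upstream candidate that validates as putatively functional (falling back
    to the most upstream Met); calls are deduplicated by (contig, strand,
    stop-codon position).
    """
    window = cfg.a_pheromone.start_window_codons
    calls: dict[tuple[str, str, int], APheromoneCall] = {}
    for rec in records:
        if len(rec.seq) < 3:
            logger.warning("contig %s shorter than one codon; skipped", rec.id)
            continue
        for frame in SIX_FRAMES:
            prot = translate(rec.seq, frame)
            for j, aa in enumerate(prot):
                if aa != "*" or j < 4:
                    continue
                if classify_caax(prot[j - 4:j], cfg.caax) is None:
                    continue
                lo = max(0, j - window)
                mets = [m for m in range(lo, j) if prot[m] == "M"]
                if not mets:
                    continue
                clean = [m for m in mets if "*" not in prot[m:j]]
                chosen_call = None
                for m in clean:  # most upstream first
                    cand = validate_a_protein(prot[m:j], cfg)
                    if chosen_call is None or (cand.functional and
                                               not chosen_call.functional):
                        chosen_call, chosen_m = cand, m
                    if cand.functional:
                        break
                if chosen_call is None:
                    # pseudogene-style: motif ORF interrupted by an early stop
                    chosen_m = mets[0]
                    chosen_call = APheromoneCall(
                        contig="", strand="+", frame_offset=0, cds_start=0,
                        cds_end=0, protein=prot[chosen_m:j],
                        verdict="rejected:early_stop")
                start, end = _forward_span(frame, len(rec.seq), chosen_m, j + 1)
                stop_fwd, _ = _forward_span(frame, len(rec.seq), j, j + 1)
                chosen_call.contig = rec.id
                chosen_call.strand = frame.strand
                chosen_call.frame_offset = frame.offset
                chosen_call.cds_start, chosen_call.cds_end = start, end
                chosen_call.start_candidates = [m - chosen_m for m in clean]
                key = (rec.id, frame.strand, stop_fwd)
                if key not in calls or (chosen_call.functional and
                                        not calls[key].functional):
                    calls[key] = chosen_call
    return sorted(calls.values(),
                  key=lambda c: (c.contig, c.cds_start, c.strand))
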