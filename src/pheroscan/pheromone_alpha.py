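"""alpha-pheromone precursor parsing.

An alpha-pheromone precursor carries an N-terminal secretion signal followed
by tandem mature peptides that Kex2 (cuts after Lys-Arg) and Ste13 (trims
X-Ala/X-Pro dipeptides) release during secretion. Mature peptides are the
9-15 residues immediately upstream of a cleavage motif, screened for a
predicted beta turn; precursors may use only KEX2 sites, only STE13 runs, or
both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pheroscan.config import PipelineConfig
from pheroscan.motifs import (CleavageSite, find_kex2_sites, find_ste13_runs,
                              find_ste13_runs_denovo)
from pheroscan.pheromone_a import MaturePeptide
from pheroscan.profiles import SignalCall, detect_signal_peptide, has_beta_turn
from pheroscan.seqio import SequenceRecord


@dataclass
class AlphaPheromoneCall:
    """An alpha-pheromone precursor with its cleavage plan and peptides."""

    protein_id: str
    signal: SignalCall
    sites: list[CleavageSite] = field(default_factory=list)
    mature_peptides: list[MaturePeptide] = field(default_factory=list)
    verdict: str = "rejected:unvalidated"

    @property
    def functional(self) -> bool:
        return self.verdict == "putatively_functional"

    @property
    def central_residues(self) -> list[str]:
        """The residue at floor(length/2) of each mature peptide (0-based);
        conserved Gly family-wide, Trp in Meredithiella-style peptides."""
        return [p.sequence[len(p.sequence) // 2] for p in self.mature_peptides]


def signal_end_position(signal: SignalCall) -> int:
    """Where the mature part of the precursor starts.

    Taken as the end of the hydrophobic core: the c-region cleavage flag is
    evidence only, since its exact position depends on downstream residue
    content and the first cleavage site bounds the first peptide anyway.
    """
    if signal.h_region is not None:
        return signal.h_region[1]
    return 0


def collect_cleavage_sites(protein: str, signal_end: int,
                           cfg: PipelineConfig = PipelineConfig()) -> list[CleavageSite]:
    """All KEX2 and STE13 sites on a precursor, sorted and deduplicated.

    STE13 runs are taken anchored at the signal end and at every KEX2 cut
    (where a single X-[AP] dipeptide suffices) and additionally de novo
    anywhere on the protein (where at least ``cfg.ste13.min_dipeptides``
    consecutive dipeptides are required), so that STE13-only precursors are
    parsed without a KEX2 anchor.
    """
    sites = list(find_kex2_sites(protein, cfg.kex2))
    anchors = [signal_end] + [s.cut for s in sites]
    for anchor in anchors:
        sites.extend(find_ste13_runs(protein, anchor, min_dipeptides=1))
    sites.extend(find_ste13_runs_denovo(protein, cfg.ste13))
    unique: dict[int, CleavageSite] = {}
    for site in sorted(sites, key=lambda s: (s.cut, s.kind)):
        unique.setdefault(site.cut, site)
    return [unique[cut] for cut in sorted(unique)]


def extract_alpha_mature_peptides(protein: str, sites: list[CleavageSite],
                                  cfg: PipelineConfig = PipelineConfig(),
                                  start: int = 0) -> list[MaturePeptide]:
    """Mature peptides upstream of each cleavage site.

    For every site the segment runs from the previous cut (or ``start``, the
    signal end) to the start of the site's motif; leading X-[AP] dipeptides
    are trimmed, candidate peptides are the segment suffixes of length 9-15,
    those without a predicted beta turn are dropped, and the longest passing
    candidate is reported. The tail after the last cut is only considered when
    ``cfg.alpha.include_terminal_segment`` is set.
    """
    peptides: list[MaturePeptide] = []
    prev = start
    boundaries = [(s.motif_start, s.cut, s.kind) for s in sites]
    if cfg.alpha.include_terminal_segment and protein:
        boundaries.append((len(protein), len(protein), "terminal"))
    for motif_start, cut, kind in boundaries:
        seg_start, seg_end = prev, max(motif_start, prev)
        prev = max(cut, prev)
        while seg_end - seg_start >= 2 and protein[seg_start + 1] in "AP":
            seg_start += 2
        segment = protein[seg_start:seg_end]
        best = None
        for length in range(cfg.alpha.min_len, cfg.alpha.max_len + 1):
            if length > len(segment):
                break
            candidate = segment[len(segment) - length:]
            if "X" in candidate or not has_beta_turn(candidate, cfg.turn):
                continue
            best = MaturePeptide(sequence=candidate,
                                 start=seg_end - length, end=seg_end,
                                 motif_kind=kind)
        if best is not None:
            peptides.append(best)
    return peptides


def call_alpha_pheromone(protein: SequenceRecord,
                         cfg: PipelineConfig = PipelineConfig()) -> AlphaPheromoneCall:
    """Apply the alpha-pheromone rules to a candidate precursor protein.

    Putatively functional iff a secretion signal is present and at least one
    mature peptide passes the beta-turn screen; otherwise the verdict records
    the first failing gate (no_signal, no_cleavage_sites, no_turn_peptide).
    """
    if not protein.seq:
        raise ValueError(f"protein {protein.id!r} is empty")
    seq = protein.seq
    signal = detect_signal_peptide(seq, cfg.signal)
    call = AlphaPheromoneCall(protein_id=protein.id, signal=signal)
    start = signal_end_position(signal)
    call.sites = collect_cleavage_sites(seq, start, cfg)
    call.mature_peptides = extract_alpha_mature_peptides(seq, call.sites, cfg, start=start)
    if not signal.present:
        call.verdict = "rejected:no_signal"
    elif not call.sites:
        call.verdict = "rejected:no_cleavage_sites"
    elif not call.mature_peptides:
        call.verdict = "rejected:no_turn_peptide"
    else:
        call.verdict = "putatively_functional"
    return call


def count_mature_peptides(call: AlphaPheromoneCall) -> int:
    """Number of mature peptides a precursor encodes; 0 for rejected calls."""
    return len(call.mature_peptides) if call.functional else 0
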