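"""CaaX/CpaX prenylation motifs and KEX2/STE13 cleavage-site scanning.

CaaX = Cys, two aliphatic residues, any residue; CpaX = Cys, polar residue,
aliphatic residue, any residue (glutamine is accepted in the polar class, as
observed in Catunica and Meredithiella pheromones). KEX2 cuts after a
Lys-Arg dipeptide; STE13 iteratively removes X-Ala / X-Pro dipeptides from a
peptide N-terminus. A motif or site never overlaps an unknown residue (X).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from pheroscan.config import CaaxConfig, Kex2Config, Ste13Config


@dataclass(frozen=True)
class MotifHit:
    """A located CaaX/CpaX motif (span is 0-based half-open, length 4)."""

    kind: Literal["CaaX", "CpaX"]
    start: int
    cys: int
    terminal: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.start + 4)

    @property
    def end(self) -> int:
        return self.start + 4


@dataclass(frozen=True)
class CleavageSite:
    """A proteolytic cleavage point; cleavage occurs before index ``cut``."""

    kind: Literal["KEX2", "STE13"]
    cut: int
    motif_start: int
    motif_end: int


def classify_caax(fourmer: str, cfg: CaaxConfig = CaaxConfig()) -> str | None:
    """Return 'CaaX', 'CpaX' or None for a 4-residue window."""
    if len(fourmer) != 4 or "X" in fourmer or "*" in fourmer:
        return None
    if fourmer[0] != "C":
        return None
    a1, a2 = fourmer[1], fourmer[2]
    if a1 in cfg.aliphatic and a2 in cfg.aliphatic:
        return "CaaX"
    if a1 in cfg.polar and a2 in cfg.aliphatic:
        return "CpaX"
    return None


def find_caax_motifs(protein: str, cfg: CaaxConfig = CaaxConfig()) -> list[MotifHit]:
    """All CaaX/CpaX motifs on a protein, sorted by position.

    The terminal flag marks motifs ending at the protein's last residue (the
    biologically prenylatable configuration).
    """
    hits = []
    for i in range(len(protein) - 3):
        kind = classify_caax(protein[i:i + 4], cfg)
        if kind is not None:
            hits.append(MotifHit(kind=kind, start=i, cys=i,
                                 terminal=(i + 4 == len(protein))))
    return hits


def find_kex2_sites(protein: str, cfg: Kex2Config = Kex2Config()) -> list[CleavageSite]:
    """KEX2 endoprotease sites: one per K-R dipeptide (R-R optional), cut
    immediately after the Arg."""
    motifs = {"KR"} | ({"RR"} if cfg.allow_rr else set())
    sites = []
    for i in range(len(protein) - 1):
        if protein[i:i + 2] in motifs:
            sites.append(CleavageSite(kind="KEX2", cut=i + 2, motif_start=i, motif_end=i + 2))
    return sites


def find_ste13_runs(protein: str, anchor: int,
                    min_dipeptides: int = 1) -> list[CleavageSite]:
    """STE13 dipeptidyl-aminopeptidase sites anchored at ``anchor``.

    Emits one site per dipeptide of the maximal run of consecutive X-Ala/X-Pro
    dipeptides starting at ``anchor``; an empty list when the run is shorter
    than ``min_dipeptides``.
    """
    if not 0 <= anchor <= len(protein):
        raise ValueError(f"anchor {anchor} out of range for protein of length {len(protein)}")
    sites = []
    pos = anchor
    while pos + 2 <= len(protein) and protein[pos + 1] in "AP" and "X" not in protein[pos:pos + 2]:
        sites.append(CleavageSite(kind="STE13", cut=pos + 2, motif_start=pos, motif_end=pos + 2))
        pos += 2
    return sites if len(sites) >= min_dipeptides else []


def find_ste13_runs_denovo(protein: str,
                           cfg: Ste13Config = Ste13Config()) -> list[CleavageSite]:
    """Scan the whole protein for unanchored STE13 runs.

    A run qualifies when at least ``cfg.min_dipeptides`` consecutive X-[AP]
    dipeptides start at its first position; scanning is greedy left-to-right so
    overlapping phases resolve deterministically.
    """
    sites: list[CleavageSite] = []
    pos = 0
    while pos + 2 <= len(protein):
        run = find_ste13_runs(protein, pos, min_dipeptides=cfg.min_dipeptides)
        if run:
            sites.extend(run)
            pos = run[-1].cut
        else:
            pos += 1
    return sites
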