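"""Pairwise locus microsynteny: homolog linking and positional conservation.

A locus neighbourhood is the focal pheromone/receptor gene plus its ordered
flanking genes. Two neighbourhoods are compared by all-vs-all global percent
identity; genes above a minimum identity are linked as mutual best pairs
(ties broken by proximity to the focal gene). A pair of loci shows a
conserved focal position when the immediate flanking genes on both sides are
linked; a flank missing because the focal gene sits at a contig edge scores
as unknown, not as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from pheroscan.compare import percent_identity
from pheroscan.config import PipelineConfig


@dataclass
class LocusGene:
    gene_id: str
    strand: str
    protein: str


@dataclass
class LocusNeighborhood:
    """Ordered gene context around a focal pheromone/receptor gene."""

    species: str
    locus_id: str
    genes: list[LocusGene]
    focal_gene_id: str

    def __post_init__(self) -> None:
        if self.focal_index is None:
            raise ValueError(
                f"focal gene {self.focal_gene_id!r} absent from locus {self.locus_id!r}")

    @property
    def focal_index(self) -> int | None:
        for i, g in enumerate(self.genes):
            if g.gene_id == self.focal_gene_id:
                return i
        return None


@dataclass
class SyntenyLink:
    """A mutual-best homology link between genes of two loci."""

    gene_a: str
    gene_b: str
    identity: float


@dataclass
class ConservationReport:
    """Fraction of locus pairs with a positionally conserved focal gene."""

    pair_status: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def fraction_conserved(self) -> float:
        known = [s for s in self.pair_status.values() if s != "unknown"]
        if not known:
            return float("nan")
        return sum(s == "conserved" for s in known) / len(known)


def link_homologs(a: LocusNeighborhood, b: LocusNeighborhood,
                  cfg: PipelineConfig = PipelineConfig()) -> list[SyntenyLink]:
    """Mutual-best homolog links between two loci.

    All gene pairs with global percent identity at or above
    ``cfg.synteny.min_identity`` are candidates; a link is kept when each gene
    is the other's best match, with identity ties resolved towards the partner
    closest to the focal gene. Every gene appears in at most one link.
    """
    if not a.genes or not b.genes:
        raise ValueError("cannot link empty loci")
    na, nb = len(a.genes), len(b.genes)
    ident = np.full((na, nb), -1.0)
    for i, ga in enumerate(a.genes):
        for j, gb in enumerate(b.genes):
            value = percent_identity(ga.protein, gb.protein, cfg.align)
            if value >= cfg.synteny.min_identity:
                ident[i, j] = value
    fa, fb = a.focal_index, b.focal_index

    def best_in_row(i: int) -> int | None:
        row = ident[i]
        if row.max() < 0:
            return None
        top = np.flatnonzero(row == row.max())
        return int(min(top, key=lambda j: (abs(j - fb), j)))

    def best_in_col(j: int) -> int | None:
        col = ident[:, j]
        if col.max() < 0:
            return None
        top = np.flatnonzero(col == col.max())
        return int(min(top, key=lambda i: (abs(i - fa), i)))

    links = []
    for i in range(na):
        j = best_in_row(i)
        if j is not None and best_in_col(j) == i:
            links.append(SyntenyLink(gene_a=a.genes[i].gene_id,
                                     gene_b=b.genes[j].gene_id,
                                     identity=float(ident[i, j])))
    return links


def _flank_conserved(a: LocusNeighborhood, b: LocusNeighborhood,
                     links: Sequence[SyntenyLink], side: int) -> str:
    """'linked', 'unlinked' or 'unknown' for one flank (side -1/+1)."""
    ia, ib = a.focal_index + side, b.focal_index + side
    if not (0 <= ia < len(a.genes)) or not (0 <= ib < len(b.genes)):
        return "unknown"
    linked = {(l.gene_a, l.gene_b) for l in links}
    want = (a.genes[ia].gene_id, b.genes[ib].gene_id)
    return "linked" if want in linked else "unlinked"


def locus_conservation(loci: Sequence[LocusNeighborhood],
                       cfg: PipelineConfig = PipelineConfig(),
                       links_by_pair: dict[tuple[str, str],
                                           list[SyntenyLink]] | None = None
                       ) -> ConservationReport:
    """Positional conservation of the focal gene across every locus pair.

    A pair is conserved when both immediate flanks are linked, unknown when
    every evaluable flank sits at a contig edge, otherwise not conserved.
    Precomputed pairwise links may be passed in; missing pairs are computed.
    """
    report = ConservationReport()
    for a, b in combinations(loci, 2):
        key = (a.locus_id, b.locus_id)
        if links_by_pair is not None and key in links_by_pair:
            links = links_by_pair[key]
        else:
            links = link_homologs(a, b, cfg)
        statuses = [_flank_conserved(a, b, links, side) for side in (-1, +1)]
        known = [s for s in statuses if s != "unknown"]
        if not known:
            status = "unknown"
        elif all(s == "linked" for s in known):
            status = "conserved"
        else:
            status = "not_conserved"
        report.pair_status[key] = status
    return report


def read_loci(table_path, fasta_path) -> list[LocusNeighborhood]:
    """Load locus neighbourhoods from a TSV plus a protein FASTA.

    TSV columns: species, locus, gene_id, order_index, strand, protein_id,
    focal (yes/no); protein_id references a record in the FASTA file.
    """
    import pandas as pd
    from pheroscan.seqio import read_fasta

    proteins = {r.id: r.seq for r in read_fasta(fasta_path, "protein")}
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    required = {"species", "locus", "gene_id", "order_index", "strand",
                "protein_id", "focal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table is missing column(s): {sorted(missing)}")
    loci = []
    for (species, locus_id), group in df.groupby(["species", "locus"], sort=True):
        group = group.sort_values("order_index", key=lambda s: s.astype(int))
        genes, focal = [], None
        for row in group.itertuples():
            if row.protein_id not in proteins:
                raise ValueError(f"protein {row.protein_id!r} not in FASTA")
            genes.append(LocusGene(row.gene_id, row.strand, proteins[row.protein_id]))
            if row.focal.lower() in ("yes", "true", "1"):
                focal = row.gene_id
        if focal is None:
            raise ValueError(f"locus {locus_id!r} has no focal gene")
        loci.append(LocusNeighborhood(species, locus_id, genes, focal))
    return loci


def plot_locus_pair(a: LocusNeighborhood, b: LocusNeighborhood,
                    links: Sequence[SyntenyLink], path) -> None:
    """Ribbon-style SVG of two loci and their homology links (presentation
    only; the numeric contract lives in link_homologs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(a.genes)), 2.4))
    positions = {}
    for y, locus in ((1.0, a), (0.0, b)):
        x = 0.0
        for gene in locus.genes:
            width = max(0.5, len(gene.protein) / 200)
            color = "tab:red" if gene.gene_id == locus.focal_gene_id else "tab:blue"
            marker = dict(head_width=0.18, head_length=0.12, length_includes_head=True)
            if gene.strand == "-":
                ax.arrow(x + width, y, -width, 0, color=color, **marker)
            else:
                ax.arrow(x, y, width, 0, color=color, **marker)
            positions[gene.gene_id] = (x + width / 2, y)
            ax.text(x + width / 2, y + 0.22, gene.gene_id, ha="center", fontsize=6)
            x += width + 0.3
    for link in links:
        (xa, ya), (xb, yb) = positions[link.gene_a], positions[link.gene_b]
        ax.plot([xa, xb], [ya - 0.05, yb + 0.05], color="grey",
                alpha=min(1.0, link.identity / 100), lw=1.5)
    ax.set_ylim(-0.5, 1.6)
    ax.axis("off")
    fig.savefig(path, format="svg")
    plt.close(fig)
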