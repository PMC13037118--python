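"""Comparative analyses: pairwise percent identity, unique-peptide censuses,
mating-strategy cross-tabulation and a seeded permutation association test.

Percent identity is computed from an end-to-end global alignment (BLOSUM62,
gap open 10, gap extend 0.5, terminal gaps penalised) as identical aligned
positions over alignment length, times 100. These parameters are explicit
configuration because interactive workbench "defaults" are not portable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

from pheroscan.config import AlignConfig
from pheroscan.seqio import SequenceRecord

MATING_STRATEGIES = ("heterothallic", "primary_homothallic", "mating_type_switching",
                     "unisexual")

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()
# the aligner takes integer penalties only; doubling matrix and penalties
# expresses the half-point gap extension exactly (scores are halved back)
_BLOSUM62_X2 = balign.SubstitutionMatrix(
    _BLOSUM62.get_alphabet1(), _BLOSUM62.get_alphabet2(),
    _BLOSUM62.score_matrix() * 2)


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity table over labelled sequences."""

    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def align_global(a: str, b: str, cfg: AlignConfig = AlignConfig()):
    """Optimal end-to-end global alignment of two protein sequences.

    The returned alignment's ``score`` is on the doubled-matrix scale; divide
    by two for the BLOSUM62 scale.
    """
    if cfg.matrix != "BLOSUM62":
        raise ValueError(f"unsupported substitution matrix {cfg.matrix!r}")
    open2, ext2 = 2 * cfg.gap_open, 2 * cfg.gap_extend
    if open2 != int(open2) or ext2 != int(ext2):
        raise ValueError("gap penalties must be multiples of 0.5")
    seq_a, seq_b = bseq.ProteinSequence(a), bseq.ProteinSequence(b)
    alignments = balign.align_optimal(
        seq_a, seq_b, _BLOSUM62_X2,
        gap_penalty=(-int(open2), -int(ext2)),
        terminal_penalty=True,
    )
    return alignments[0]


def percent_identity(a: str, b: str, cfg: AlignConfig = AlignConfig()) -> float:
    """Percent identity of the optimal global alignment, over alignment length."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = align_global(a, b, cfg)
    return 100.0 * balign.get_sequence_identity(alignment, mode="all")


def pairwise_identity(seqs: Sequence[SequenceRecord],
                      cfg: AlignConfig = AlignConfig()) -> IdentityMatrix:
    """All-vs-all percent identity; symmetric with a diagonal of 100."""
    if len(seqs) < 2:
        raise ValueError("pairwise identity needs at least two sequences")
    for rec in seqs:
        if not rec.seq:
            raise ValueError(f"sequence {rec.id!r} is empty")
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(seqs[i].seq, seqs[j].seq, cfg)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=[r.id for r in seqs], values=values)


def unique_peptides(sequences: Sequence[str]) -> tuple[dict[str, int], int]:
    """Exact-string census: (sequence -> count in lexicographic order, n distinct)."""
    counts = Counter(sequences)
    census = {seq: counts[seq] for seq in sorted(counts)}
    return census, len(census)


def read_strategy_table(path: str | Path) -> dict[str, str]:
    """Read a two-column species/strategy TSV into a validated mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "strategy"],
                     comment="#", dtype=str)
    table: dict[str, str] = {}
    for species, strategy in zip(df["species"], df["strategy"]):
        if species in table:
            raise ValueError(f"species {species!r} appears twice in {path}")
        if strategy not in MATING_STRATEGIES:
            raise ValueError(
                f"unknown mating strategy {strategy!r} for {species!r}; "
                f"expected one of {MATING_STRATEGIES}"
            )
        table[species] = strategy
    return table


def summarize_by_strategy(features: pd.DataFrame,
                          strategies: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate per-species features per mating strategy.

    ``features`` holds one row per species (column ``species``) plus numeric
    feature columns; the result carries count/mean/min/max per (strategy,
    feature) cell. Missing values stay missing rather than being coerced to
    zero. A species absent from ``strategies`` is an error.
    """
    unknown = set(features["species"]) - set(strategies)
    if unknown:
        raise ValueError(f"species without a mating strategy: {sorted(unknown)}")
    df = features.copy()
    df["strategy"] = df["species"].map(strategies)
    feature_cols = [c for c in df.columns if c not in ("species", "strategy")]
    summary = df.groupby("strategy", sort=True)[feature_cols].agg(
        ["count", "mean", "min", "max"])
    return summary


def _between_group_ss(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss = 0.0
    for g in range(n_groups):
        member = values[codes == g]
        if member.size:
            ss += member.size * (member.mean() - grand) ** 2
    return ss


def permutation_association(feature: Sequence[float],
                            strategies: Sequence[str],
                            n_perm: int = 999,
                            seed: int = 0) -> tuple[float, float]:
    """Seeded label-shuffling test of feature/strategy association.

    The statistic is the between-group sum of squares of group means; the
    p-value is (1 + #{permuted >= observed}) / (1 + n_perm). Needs at least
    two groups with two or more members each.

    Returns (p_value, observed_statistic).
    """
    values = np.asarray(feature, dtype=float)
    labels = pd.Categorical(list(strategies))
    codes = np.asarray(labels.codes)
    if values.shape[0] != codes.shape[0]:
        raise ValueError("feature and strategy lists differ in length")
    sizes = np.bincount(codes, minlength=len(labels.categories))
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two strategy groups with >= 2 members")
    n_groups = len(labels.categories)
    observed = _between_group_ss(values, codes, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _between_group_ss(values, perm, n_groups) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return p, float(observed)
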