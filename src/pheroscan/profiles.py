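"""Sliding-window physicochemical profiles: hydropathy, beta-turn propensity,
transmembrane-segment prediction, membrane topology, and a secretion-signal
heuristic.

These replace interactive profile servers with documented, configurable
in-repo heuristics. The Kyte-Doolittle (1982) hydropathy and Levitt (1978)
beta-turn propensity tables ship as packaged TSVs. Unknown residues (X) score
as the scale mean, i.e. neutrally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from pheroscan.config import NTermConfig, SignalConfig, TMConfig, TurnConfig
from pheroscan.seqio import AMINO_ACIDS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleTable:
    """A 20-entry per-residue propensity scale."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard residues "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    def score(self, residue: str) -> float:
        """Per-residue value; X (and any non-standard letter) is scale-neutral."""
        return self.values.get(residue, self.mean)

    def map(self, seq: str) -> np.ndarray:
        mean = self.mean
        return np.array([self.values.get(r, mean) for r in seq], dtype=float)


def _load_scale(filename: str, name: str) -> ScaleTable:
    text = resources.files("pheroscan.data").joinpath(filename).read_text()
    values = {}
    for line in text.strip().splitlines():
        residue, value = line.split("\t")
        values[residue] = float(value)
    return ScaleTable(name=name, values=values)


KYTE_DOOLITTLE = _load_scale("kyte_doolittle.tsv", "kyte_doolittle")
LEVITT_BETA_TURN = _load_scale("levitt_beta_turn.tsv", "levitt_beta_turn")


@dataclass
class Profile:
    """Windowed mean scores along a protein; positions are window centers."""

    window: int
    scores: list[tuple[int, float]]


@dataclass
class TMSegment:
    """A predicted membrane-spanning stretch (0-based half-open span)."""

    start: int
    end: int
    peak_score: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SignalCall:
    """Secretion-signal verdict with the evidence flags that produced it."""

    present: bool
    h_region: tuple[int, int] | None = None
    cleavage_end: int | None = None
    flags: set[str] = field(default_factory=set)


def _window_means(seq: str, scale: ScaleTable, window: int) -> np.ndarray:
    values = scale.map(seq)
    if window > len(values):
        return np.array([], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def sliding_window_score(seq: str, scale: ScaleTable, window: int) -> Profile:
    """Mean scale value over every length-``window`` window of ``seq``.

    The window must be odd and positive and the sequence at least one window
    long; scores are reported at window-center positions.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} is shorter than window {window}")
    means = _window_means(seq, scale, window)
    half = window // 2
    return Profile(window=window,
                   scores=[(half + i, float(m)) for i, m in enumerate(means)])


def predict_tm_segments(protein: str, cfg: TMConfig = TMConfig()) -> list[TMSegment]:
    """Predict transmembrane helices as maximal hydrophobic window runs.

    Window centers whose Kyte-Doolittle window mean reaches ``cfg.threshold``
    are grouped into maximal runs, each run is expanded to full window extent,
    and expanded segments separated by less than ``cfg.min_loop`` residues are
    merged. A protein shorter than the window yields an empty list (with a
    warning), not an error.
    """
    if len(protein) < cfg.window:
        logger.warning(
            "protein of length %d is shorter than the TM window %d; no segments",
            len(protein), cfg.window,
        )
        return []
    means = _window_means(protein, KYTE_DOOLITTLE, cfg.window)
    half = cfg.window // 2
    above = means >= cfg.threshold
    segments: list[TMSegment] = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        start = (i + half) - half           # first center minus half-window
        end = (j + half) + half + 1         # last center plus half-window, exclusive
        peak = float(means[i:j + 1].max())
        segments.append(TMSegment(start, end, peak))
        i = j + 1
    merged: list[TMSegment] = []
    for seg in segments:
        if merged and seg.start - merged[-1].end < cfg.min_loop:
            prev = merged[-1]
            merged[-1] = TMSegment(prev.start, seg.end, max(prev.peak_score, seg.peak_score))
        else:
            merged.append(seg)
    return merged


def infer_topology(n_tm: int) -> Literal["cytoplasmic", "extracellular"]:
    """C-terminal compartment from the transmembrane count.

    The N-terminus is taken as extracellular (GPCR convention) and each
    membrane pass flips the compartment: seven passes put the C-terminus in
    the cytoplasm, six leave it extracellular.
    """
    if n_tm < 0:
        raise ValueError(f"n_tm must be non-negative, got {n_tm}")
    return "cytoplasmic" if n_tm % 2 == 1 else "extracellular"


def detect_signal_peptide(protein: str, cfg: SignalConfig = SignalConfig()) -> SignalCall:
    """Heuristic N-terminal secretion-signal call.

    Present iff the first ``cfg.first_n`` residues contain a hydrophobic core
    (window-``cfg.window`` Kyte-Doolittle mean >= ``cfg.threshold``) AND a
    basic residue (K/R) occurs within the first ``cfg.n_region_len`` residues.
    A signal-peptidase-like c-region (small residues at -3/-1 of a cleavage
    point within ``cfg.c_region_scan`` residues after the core) is flagged but
    does not gate presence.
    """
    flags: set[str] = set()
    h_region: tuple[int, int] | None = None
    cleavage_end: int | None = None

    if any(r in "KR" for r in protein[:cfg.n_region_len]):
        flags.add("charged_n_region")

    head = protein[:cfg.first_n]
    if len(head) >= cfg.window:
        means = _window_means(head, KYTE_DOOLITTLE, cfg.window)
        above = np.flatnonzero(means >= cfg.threshold)
        if above.size:
            flags.add("hydrophobic_core")
            # maximal run containing the first qualifying window
            first = int(above[0])
            last = first
            while last + 1 < len(means) and means[last + 1] >= cfg.threshold:
                last += 1
            h_region = (first, last + cfg.window)

    if h_region is not None:
        core_end = h_region[1]
        small = set("AGSCT")
        for cut in range(core_end + 1, min(core_end + cfg.c_region_scan, len(protein)) + 1):
            if cut - 3 >= 0 and protein[cut - 3] in small and protein[cut - 1] in small:
                flags.add("cleavage_like_c_region")
                cleavage_end = cut
                break

    present = "hydrophobic_core" in flags and "charged_n_region" in flags
    return SignalCall(present=present, h_region=h_region,
                      cleavage_end=cleavage_end, flags=flags)


def has_beta_turn(peptide: str, cfg: TurnConfig = TurnConfig()) -> bool:
    """True iff any 4-residue window's mean Levitt turn propensity reaches the
    threshold (default 1.0, the neutral propensity)."""
    if len(peptide) < 4:
        raise ValueError(f"peptide of length {len(peptide)} is too short for a beta turn")
    means = _window_means(peptide, LEVITT_BETA_TURN, 4)
    return bool((means >= cfg.threshold).any())


def n_term_hydrophobicity(protein: str, k: int = NTermConfig.k) -> float:
    """Mean Kyte-Doolittle hydropathy over the first ``k`` residues."""
    if len(protein) < k:
        raise ValueError(f"protein of length {len(protein)} is shorter than k={k}")
    return float(KYTE_DOOLITTLE.map(protein[:k]).mean())
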