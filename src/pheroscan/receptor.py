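"""Pheromone-receptor classification.

Pheromone receptors are G-protein-coupled proteins with seven transmembrane
helices and a cytoplasmic C-terminus. A candidate is putatively functional
iff exactly seven membrane-spanning segments are predicted; the C-terminal
compartment follows from the segment count by parity (extracellular
N-terminus), so six-TM degenerates end extracellular while three-TM
degenerates still end cytoplasmic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from pheroscan.config import PipelineConfig
from pheroscan.profiles import TMSegment, infer_topology, predict_tm_segments
from pheroscan.seqio import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class ReceptorCall:
    """Transmembrane count, topology and functional verdict for a candidate."""

    protein_id: str
    length: int
    tm_segments: list[TMSegment] = field(default_factory=list)
    c_terminus: Literal["cytoplasmic", "extracellular"] = "extracellular"

    @property
    def n_tm(self) -> int:
        return len(self.tm_segments)

    @property
    def functional(self) -> bool:
        return self.n_tm == 7


def classify_receptor(protein: SequenceRecord,
                      cfg: PipelineConfig = PipelineConfig()) -> ReceptorCall:
    """Predict TM segments and the functional verdict for one protein.

    A protein shorter than the hydropathy window yields a zero-TM,
    non-functional call with a warning rather than an error.
    """
    if len(protein.seq) < cfg.tm.window:
        logger.warning("receptor candidate %s shorter than the TM window; "
                       "classified with 0 segments", protein.id)
        segments: list[TMSegment] = []
    else:
        segments = predict_tm_segments(protein.seq, cfg.tm)
    return ReceptorCall(
        protein_id=protein.id,
        length=len(protein.seq),
        tm_segments=segments,
        c_terminus=infer_topology(len(segments)),
    )
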