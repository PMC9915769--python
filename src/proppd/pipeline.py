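"""End-to-end synthetic pipeline: simulate -> process reads -> confidence
-> motif discovery.

Convenience orchestration used by the examples, the CLI and the
reproduction script; each stage is the corresponding library function, so
results are identical to running the stages by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .confidence import ConfidenceCall, call_confidence, select_confident
from .discovery import discover
from .motif import DegenerateMotif
from .reads import CountTable, count_peptides, process_read
from .simulate import (
    PeptideRecord,
    SelectionDesign,
    SynthProteomeSpec,
    generate_library,
    generate_proteome,
    generate_reads,
)


@dataclass
class PipelineResult:
    proteome: list
    library: list[PeptideRecord]
    counts: CountTable
    calls: list[ConfidenceCall]
    selected: list[ConfidenceCall]
    ranked: pd.DataFrame
    top_motif: DegenerateMotif

    @property
    def selected_peptides(self) -> list[str]:
        return list(dict.fromkeys(c.peptide for c in self.selected))


def run_discovery_pipeline(
    spec: SynthProteomeSpec,
    design: SelectionDesign,
    tile_length: int = 16,
    step: int = 8,
    count_quantile: float = 0.75,
    L_range: tuple[int, int] = (4, 6),
    max_ambiguous: int = 1,
    min_support: int = 5,
) -> PipelineResult:
    """Simulate selections and rediscover the enriched motif.

    Confidence is called without a consensus (first pass: at most three
    criteria can hold, and the >= 3 working set therefore requires all of
    replication, overlap and high counts); discovery then runs on the
    unique selected peptides.
    """
    proteome = generate_proteome(spec)
    library = generate_library(proteome, tile_length=tile_length, step=step)
    runs = generate_reads(library, design)
    assignments = {
        key: [process_read(read, design) for read in reads]
        for key, reads in runs.items()
    }
    counts = count_peptides(assignments, library)
    calls = call_confidence(counts, consensus=None, count_quantile=count_quantile)
    selected = select_confident(calls)
    peptides = list(dict.fromkeys(c.peptide for c in selected))
    ranked, top = discover(
        peptides,
        L_range=L_range,
        max_ambiguous=max_ambiguous,
        min_support=min_support,
    )
    return PipelineResult(
        proteome=proteome,
        library=library,
        counts=counts,
        calls=calls,
        selected=selected,
        ranked=ranked,
        top_motif=top,
    )
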