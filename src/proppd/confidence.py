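"""Peptide confidence classification from four enrichment criteria.

An enriched peptide is scored per bait on four booleans — observed in at
least two replicate selections; supported by an overlapping peptide from
the same source protein (>= 8 identical consecutive residues, half a
16-mer tile); total count at or above a high-count threshold; and a match
to the consensus motif when one is supplied.  Peptides meeting all four
are high confidence, exactly three medium, otherwise low; the stringent
working set keeps peptides meeting at least three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif import DegenerateMotif
from .reads import CountTable

OVERLAP_K = 8


@dataclass
class ConfidenceCall:
    peptide: str
    protein_id: str
    start: int
    bait: str
    replicated: bool
    overlapping: bool
    high_count: bool
    motif_match: bool
    shared_between_baits: bool = False

    @property
    def n_met(self) -> int:
        return sum(
            (self.replicated, self.overlapping, self.high_count, self.motif_match)
        )

    @property
    def tier(self) -> str:
        n = self.n_met
        return "high" if n == 4 else ("medium" if n == 3 else "low")


def _kmers(seq: str, k: int = OVERLAP_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def call_confidence(
    table: CountTable,
    consensus: DegenerateMotif | str | None = None,
    count_quantile: float = 0.75,
) -> list[ConfidenceCall]:
    """Score every observed (peptide, bait) pair on the four criteria.

    The high-count threshold is the ``count_quantile`` order statistic of
    the nonzero per-peptide totals within the bait (an order statistic, not
    an interpolated quantile, so that adding reads to a peptide can never
    drop it below a threshold it already met).  Without a consensus motif
    the motif criterion is false for every peptide, so the attainable
    maximum is three criteria.
    """
    if isinstance(consensus, str):
        consensus = DegenerateMotif.parse(consensus)
    counts = table.counts
    if counts.empty:
        return []
    baits = counts.columns.get_level_values("bait").unique()

    observed_in: dict[str, set[str]] = {}  # peptide -> set of baits
    for bait in baits:
        totals = counts[bait].sum(axis=1)
        for pep in totals.index[totals > 0]:
            observed_in.setdefault(pep, set()).add(bait)

    calls: list[ConfidenceCall] = []
    for bait in baits:
        sub = counts[bait]
        totals = sub.sum(axis=1)
        observed = totals.index[totals > 0]
        nonzero = totals[totals > 0].to_numpy()
        threshold = float(np.quantile(nonzero, count_quantile, method="lower"))

        # 8-mer index per protein over observed peptides of this bait
        by_protein: dict[str, list[str]] = {}
        for pep in observed:
            by_protein.setdefault(table.peptide_info.loc[pep, "protein_id"], []).append(pep)
        kmer_owner: dict[str, dict[str, set[str]]] = {}
        for pid, peps in by_protein.items():
            idx: dict[str, set[str]] = {}
            for pep in peps:
                for km in _kmers(pep):
                    idx.setdefault(km, set()).add(pep)
            kmer_owner[pid] = idx

        for pep in observed:
            info = table.peptide_info.loc[pep]
            pid = info["protein_id"]
            replicated = int((sub.loc[pep] > 0).sum()) >= 2
            overlapping = any(
                kmer_owner[pid][km] - {pep} for km in _kmers(pep)
            )
            high_count = totals.loc[pep] >= threshold
            motif = consensus is not None and consensus.matches(pep)
            calls.append(
                ConfidenceCall(
                    peptide=pep,
                    protein_id=pid,
                    start=int(info["start"]),
                    bait=bait,
                    replicated=replicated,
                    overlapping=overlapping,
                    high_count=bool(high_count),
                    motif_match=motif,
                    shared_between_baits=len(observed_in[pep]) > 1,
                )
            )
    return calls


def select_confident(calls: list[ConfidenceCall], min_met: int = 3) -> list[ConfidenceCall]:
    """The stringent medium/high set: calls meeting >= ``min_met`` criteria."""
    return [c for c in calls if c.n_met >= min_met]


def calls_to_frame(calls: list[ConfidenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [c.peptide for c in calls],
            "protein_id": [c.protein_id for c in calls],
            "start": [c.start for c in calls],
            "bait": [c.bait for c in calls],
            "replicated": [c.replicated for c in calls],
            "overlapping": [c.overlapping for c in calls],
            "high_count": [c.high_count for c in calls],
            "motif_match": [c.motif_match for c in calls],
            "n_met": [c.n_met for c in calls],
            "tier": [c.tier for c in calls],
            "shared_between_baits": [c.shared_between_baits for c in calls],
        }
    )
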