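"""Selection-read processing: demultiplex, trim, translate, count.

Reads have a fixed architecture — sample barcode, 5' adapter, coding
insert, 3' adapter — so adapters are located by exact anchor matching at
fixed offsets rather than alignment.  Every read receives exactly one
outcome: a translated peptide, or one of five failure classes
(barcode_mismatch, adapter_mismatch, length_error, stop_codon, unmapped).
Quality scores are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from . import io as pio
from .simulate import PeptideRecord, SelectionDesign

BARCODE_MISMATCH = "barcode_mismatch"
ADAPTER_MISMATCH = "adapter_mismatch"
LENGTH_ERROR = "length_error"
STOP_CODON = "stop_codon"
UNMAPPED = "unmapped"
ASSIGNED = "assigned"

FAILURE_CLASSES = (BARCODE_MISMATCH, ADAPTER_MISMATCH, LENGTH_ERROR, STOP_CODON)


@dataclass
class ReadAssignment:
    """Outcome of processing one read."""

    sample: str | None
    insert: str | None
    peptide: str | None
    failure: str | None

    @property
    def ok(self) -> bool:
        return self.failure is None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    read: str, barcodes: Mapping[str, str], max_mismatch: int = 0
) -> str | None:
    """Assign a read to a sample by its barcode prefix.

    Exact prefix match by default; with ``max_mismatch=1`` the nearest
    barcode wins provided it is unique and within distance 1.  Returns the
    sample label or ``None`` for a barcode mismatch.
    """
    labels = list(barcodes.values())
    if len(set(barcodes)) != len(labels):
        raise ValueError("duplicate barcodes")
    bc_len = len(next(iter(barcodes)))
    if any(len(bc) != bc_len for bc in barcodes):
        raise ValueError("barcodes must be equal length")
    prefix = read[:bc_len]
    if len(prefix) < bc_len:
        return None
    if max_mismatch == 0:
        return barcodes.get(prefix)
    distances = {bc: _hamming(prefix, bc) for bc in barcodes}
    best = min(distances.values())
    if best > max_mismatch:
        return None
    winners = [bc for bc, d in distances.items() if d == best]
    if len(winners) != 1:
        return None  # ambiguous
    return barcodes[winners[0]]


def trim_and_translate(
    read: str,
    adapter_5p: str,
    adapter_3p: str,
    insert_length_nt: int,
    barcode_length: int = 0,
) -> tuple[str | None, str | None, str | None]:
    """Locate the insert between adapter anchors and translate it.

    Returns ``(insert, peptide, failure)``.  The 5' adapter must sit
    immediately after the barcode; the insert runs to the first occurrence
    of the 3' adapter.  Exact insert length is enforced and translation is
    frame 1 of the standard genetic code; any stop codon fails the read.
    """
    body = read[barcode_length:]
    if len(body) < len(adapter_5p) + insert_length_nt + len(adapter_3p):
        return None, None, LENGTH_ERROR
    if not body.startswith(adapter_5p):
        return None, None, ADAPTER_MISMATCH
    # fixed-architecture check first: the 3' anchor at its designed offset
    # (an adapter-like sequence inside the insert must not truncate it)
    end = len(adapter_5p) + insert_length_nt
    if body[end : end + len(adapter_3p)] != adapter_3p:
        idx = body.find(adapter_3p, len(adapter_5p))
        if idx < 0:
            return None, None, ADAPTER_MISMATCH
        return body[len(adapter_5p) : idx], None, LENGTH_ERROR
    insert = body[len(adapter_5p) : end]
    peptide = str(Seq(insert).translate())
    if "*" in peptide:
        return insert, None, STOP_CODON
    return insert, peptide, None


def process_read(
    read: str, design: SelectionDesign, max_barcode_mismatch: int = 0
) -> ReadAssignment:
    sample = demultiplex(read, design.barcodes, max_barcode_mismatch)
    if sample is None:
        return ReadAssignment(None, None, None, BARCODE_MISMATCH)
    insert, peptide, failure = trim_and_translate(
        read,
        design.adapter_5p,
        design.adapter_3p,
        design.insert_length_nt,
        barcode_length=design.barcode_length,
    )
    return ReadAssignment(sample, insert, peptide, failure)


@dataclass
class CountTable:
    """Per-peptide counts with (bait, replicate) columns and read margins.

    ``counts`` is indexed by peptide sequence with a two-level column index
    (bait, replicate).  ``peptide_info`` maps library peptides to their
    source protein and 1-based start.  ``margins`` records, per replicate
    file, the total reads and the size of every failure class; column sums
    of ``counts`` equal the mapped-read margins (read conservation).
    """

    counts: pd.DataFrame
    peptide_info: pd.DataFrame
    margins: pd.DataFrame

    def bait_totals(self, bait: str) -> pd.Series:
        return self.counts[bait].sum(axis=1)


def count_peptides(
    assignments: Mapping[tuple[str, str], Iterable[ReadAssignment]],
    library: list[PeptideRecord],
) -> CountTable:
    """Aggregate assignments into a count table against the library.

    ``assignments`` maps (bait, replicate) to that replicate's read
    assignments (the bait key is ignored in favour of each read's own
    demultiplexed sample, so pooled files are handled naturally).
    Peptides absent from the library count toward the ``unmapped`` margin
    and create no row.
    """
    index: dict[str, PeptideRecord] = {}
    for rec in library:
        index.setdefault(rec.peptide, rec)

    cells: dict[tuple[str, str], dict[str, int]] = {}
    margin_rows = []
    for (bait, rep), reps in assignments.items():
        tally = {cls: 0 for cls in FAILURE_CLASSES}
        tally[UNMAPPED] = 0
        tally[ASSIGNED] = 0
        total = 0
        for asn in reps:
            total += 1
            if not asn.ok:
                tally[asn.failure] += 1
                continue
            if asn.peptide not in index:
                tally[UNMAPPED] += 1
                continue
            tally[ASSIGNED] += 1
            col = cells.setdefault((asn.sample, rep), {})
            col[asn.peptide] = col.get(asn.peptide, 0) + 1
        margin_rows.append({"bait": bait, "replicate": rep, "total_reads": total, **tally})

    margins = pd.DataFrame(margin_rows).set_index(["bait", "replicate"]).sort_index()
    counts = pd.DataFrame(cells).fillna(0).astype(int)
    if counts.empty:
        counts = pd.DataFrame(
            index=pd.Index([], name="peptide"),
            columns=pd.MultiIndex.from_tuples([], names=["bait", "replicate"]),
        )
    else:
        counts.columns = pd.MultiIndex.from_tuples(
            counts.columns, names=["bait", "replicate"]
        )
        counts = counts.sort_index().sort_index(axis=1)
        counts.index.name = "peptide"

    info = pd.DataFrame(
        {
            "peptide": list(counts.index),
            "protein_id": [index[p].protein_id for p in counts.index],
            "start": [index[p].start for p in counts.index],
        }
    ).set_index("peptide")
    return CountTable(counts=counts, peptide_info=info, margins=margins)


def process_fastq_files(
    files: Mapping[tuple[str, str], str | Path],
    design: SelectionDesign,
    library: list[PeptideRecord],
    max_barcode_mismatch: int = 0,
) -> CountTable:
    """FASTQ files (keyed by (bait, replicate)) -> :class:`CountTable`."""
    assignments = {
        key: [
            process_read(read, design, max_barcode_mismatch)
            for read in pio.read_fastq(path)
        ]
        for key, path in files.items()
    }
    return count_peptides(assignments, library)
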