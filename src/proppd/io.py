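"""Serialisation of proteomes, annotation tables, reads and result tables.

Formats are deliberately plain: FASTA for sequences, Phred+33 FASTQ with
constant quality for simulated reads, and tab-separated tables (1-based
coordinates) for disorder scores, PTM sites, topology flags, counts and
hits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scan import INTRACELLULAR, MotifHit, ProteinAnnotation

PTM_OGLCNAC = "OGlcNAc"
PTM_PTYR = "pTyr"


# ---------------------------------------------------------------------------
# proteome + annotations


def write_proteome(proteome: list[ProteinAnnotation], outdir: str | Path) -> dict:
    """Write FASTA + disorder/PTM/topology TSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "disorder": outdir / "disorder.tsv",
        "ptm": outdir / "ptm_sites.tsv",
        "topology": outdir / "topology.tsv",
    }
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteome
    ]
    SeqIO.write(records, paths["fasta"], "fasta")

    with open(paths["disorder"], "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for p in proteome:
            for i, score in enumerate(p.disorder, start=1):
                fh.write(f"{p.protein_id}\t{i}\t{score:.3f}\n")

    with open(paths["ptm"], "w") as fh:
        fh.write("protein_id\tsite_position\tptm_type\n")
        for p in proteome:
            for pos in p.oglcnac_sites:
                fh.write(f"{p.protein_id}\t{pos}\t{PTM_OGLCNAC}\n")
            for pos in p.ptyr_sites:
                fh.write(f"{p.protein_id}\t{pos}\t{PTM_PTYR}\n")

    with open(paths["topology"], "w") as fh:
        fh.write("protein_id\tflag\n")
        for p in proteome:
            fh.write(f"{p.protein_id}\t{p.topology}\n")
    return paths


def read_proteome(
    fasta: str | Path,
    disorder_tsv: str | Path | None = None,
    ptm_tsv: str | Path | None = None,
    topology_tsv: str | Path | None = None,
    default_disorder: float = 1.0,
) -> list[ProteinAnnotation]:
    """Assemble annotations from FASTA plus optional TSV tables.

    Without a disorder table every residue defaults to ``default_disorder``
    (fully disordered, i.e. the disorder filter is a no-op).
    """
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}

    disorder: dict[str, np.ndarray] = {}
    if disorder_tsv is not None:
        table = pd.read_csv(disorder_tsv, sep="\t")
        for pid, sub in table.groupby("protein_id"):
            arr = np.full(len(sequences[pid]), default_disorder)
            arr[sub["position"].to_numpy() - 1] = sub["score"].to_numpy()
            disorder[pid] = arr

    ptm: dict[str, dict[str, list[int]]] = {}
    if ptm_tsv is not None:
        table = pd.read_csv(ptm_tsv, sep="\t")
        for _, row in table.iterrows():
            slot = ptm.setdefault(row["protein_id"], {PTM_OGLCNAC: [], PTM_PTYR: []})
            slot[row["ptm_type"]].append(int(row["site_position"]))

    topology: dict[str, str] = {}
    if topology_tsv is not None:
        table = pd.read_csv(topology_tsv, sep="\t")
        topology = dict(zip(table["protein_id"], table["flag"]))

    proteome = []
    for pid, seq in sequences.items():
        sites = ptm.get(pid, {PTM_OGLCNAC: [], PTM_PTYR: []})
        ann = ProteinAnnotation(
            protein_id=pid,
            sequence=seq,
            disorder=disorder.get(pid, np.full(len(seq), default_disorder)),
            topology=topology.get(pid, INTRACELLULAR),
            oglcnac_sites=sorted(sites[PTM_OGLCNAC]),
            ptyr_sites=sorted(sites[PTM_PTYR]),
        )
        ann.validate()
        proteome.append(ann)
    return proteome


# ---------------------------------------------------------------------------
# reads


def write_fastq_runs(
    runs: dict[tuple[str, str], list[str]], outdir: str | Path
) -> dict[tuple[str, str], Path]:
    """One FASTQ per (bait, replicate); constant quality 'I' (Q40)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (bait, rep), reads in sorted(runs.items()):
        safe_bait = bait.replace("/", "-").replace(".", "_")
        path = outdir / f"{safe_bait}_{rep}.fastq"
        with open(path, "w") as fh:
            for i, read in enumerate(reads, start=1):
                fh.write(f"@{safe_bait}_{rep}_{i}\n{read}\n+\n{'I' * len(read)}\n")
        paths[(bait, rep)] = path
    return paths


def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# result tables


def write_library_tsv(library, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tprotein_id\tstart\n")
        for rec in library:
            fh.write(f"{rec.peptide}\t{rec.protein_id}\t{rec.start}\n")


def read_library_tsv(path: str | Path):
    from .simulate import PeptideRecord

    table = pd.read_csv(path, sep="\t")
    return [
        PeptideRecord(row.peptide, row.protein_id, int(row.start))
        for row in table.itertuples()
    ]


def write_counts_tsv(table, path: str | Path) -> None:
    """Count table in long format: peptide, protein_id, start, bait, replicate, count."""
    long = (
        table.counts.stack(["bait", "replicate"], future_stack=True)
        .rename("count")
        .reset_index()
    )
    long = long.merge(table.peptide_info.reset_index(), on="peptide")
    long = long[["peptide", "protein_id", "start", "bait", "replicate", "count"]]
    long.sort_values(["peptide", "bait", "replicate"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(path: str | Path):
    from .reads import CountTable

    long = pd.read_csv(path, sep="\t")
    counts = long.pivot_table(
        index="peptide", columns=["bait", "replicate"], values="count", fill_value=0
    ).astype(int)
    info = long[["peptide", "protein_id", "start"]].drop_duplicates().set_index("peptide")
    margins = (
        long.groupby(["bait", "replicate"])["count"].sum().rename("assigned").to_frame()
    )
    return CountTable(counts=counts, peptide_info=info, margins=margins)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "sequence": [h.sequence for h in hits],
            "motif_tyr_position": [h.motif_tyr_position for h in hits],
            "passed_disorder": [h.passed_disorder for h in hits],
            "passed_proline_exclusion": [h.passed_proline_exclusion for h in hits],
            "passed_topology": [h.passed_topology for h in hits],
        }
    )
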