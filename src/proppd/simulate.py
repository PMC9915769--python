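"""Synthetic study generator: proteome, tiled phage library, selection reads.

The generator emulates the statistical structure of a proteomic peptide
phage display (ProP-PD) experiment against a motif-binding bait:

* a toy proteome whose disorder profile is block-wise (ordered blocks at
  score 0.1, disordered blocks at 0.8 — only the >0.4 threshold matters
  downstream), with a degenerate motif planted inside disordered regions of
  a chosen fraction of proteins;
* O-GlcNAc and phosphotyrosine site tables whose placement encodes the
  crosstalk hypotheses under test (a controlled fraction of O-GlcNAc sites
  within a proximity window of the motif; a controlled fraction of motif
  tyrosines phosphorylated);
* a phage library of 16-mer peptides tiled across disordered regions; and
* per-replicate FASTQ selection reads in a fixed architecture
  (barcode + 5' adapter + 48-nt insert + 3' adapter) in which motif-bearing
  peptides are sampled with a configurable enrichment weight.

Everything is deterministic given the seed: identical spec + seed produces
byte-identical FASTA/FASTQ/TSV output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .motif import AMINO_ACIDS, DegenerateMotif
from .scan import (
    INTRACELLULAR,
    SECRETED,
    ProteinAnnotation,
)

ORDERED_SCORE = 0.1
DISORDERED_SCORE = 0.8

#: One codon per amino acid (the most frequent human codon); fixed so that
#: reverse translation is deterministic.
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def reverse_translate(peptide: str) -> str:
    """Deterministic reverse translation with the preferred-codon table."""
    try:
        return "".join(PREFERRED_CODON[a] for a in peptide)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc}") from exc


@dataclass
class SynthProteomeSpec:
    """Parameters of the synthetic proteome and its PTM annotation tables.

    ``oglcnac_near_motif_fraction`` is the probability that an O-GlcNAc site
    in a motif-carrying protein is placed within ``proximity_window``
    residues (gap convention) of the planted motif; the observed study-scale
    value for the OGT motif is 17.1%, which is the default here.
    ``ptyr_on_motif_fraction`` is the probability that a carrier protein is
    phosphorylated exactly on the motif tyrosine (observed 32.3%).
    ``oglcnac_near_fraction_motif_ptyr``, when set, replaces the near
    fraction for carriers that received a motif pTyr, modelling the
    enrichment of proximal O-GlcNAcylation on motif-phosphorylated proteins.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (250, 400)
    disorder_block_fraction: float = 0.5
    planted_motif: str = "PxYx[IL]"
    motif_carrier_fraction: float = 0.3
    oglcnac_near_motif_fraction: float = 0.171
    proximity_window: int = 100
    ptyr_on_motif_fraction: float = 0.323
    oglcnac_sites_per_carrier: float = 4.0
    oglcnac_sites_per_noncarrier: float = 1.0
    ptyr_background_per_protein: float = 1.0
    secreted_fraction: float = 0.1
    oglcnac_near_fraction_motif_ptyr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "disorder_block_fraction": self.disorder_block_fraction,
            "motif_carrier_fraction": self.motif_carrier_fraction,
            "oglcnac_near_motif_fraction": self.oglcnac_near_motif_fraction,
            "ptyr_on_motif_fraction": self.ptyr_on_motif_fraction,
            "secreted_fraction": self.secreted_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.oglcnac_near_fraction_motif_ptyr is not None and not (
            0.0 <= self.oglcnac_near_fraction_motif_ptyr <= 1.0
        ):
            raise ValueError("oglcnac_near_fraction_motif_ptyr outside [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range lower bound must be >= 30 and <= upper")
        motif = DegenerateMotif.parse(self.planted_motif)
        if len(motif) > lo:
            raise ValueError(
                f"planted motif length {len(motif)} exceeds minimum protein "
                f"length {lo}: impossible geometry"
            )


@dataclass
class SelectionDesign:
    """Architecture and sampling design of the phage selection reads."""

    samples: list[tuple[str, str]] = field(
        default_factory=lambda: [("ACGTAC", "OGT"), ("TGCATG", "OGT4.5")]
    )
    replicates_per_bait: int = 3
    adapter_5p: str = "GGATCCGG"
    adapter_3p: str = "GGTACCGG"
    insert_length_nt: int = 48
    enrichment_factor: float = 50.0
    background_depth: int = 5000
    enriched_motif: str = "PxYx[IL]"
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        barcodes = [bc for bc, _ in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        if len({len(bc) for bc in barcodes}) != 1:
            raise ValueError("barcodes must be equal length")
        if self.insert_length_nt % 3 != 0:
            raise ValueError("insert_length_nt must be divisible by 3")
        if not (self.enrichment_factor >= 1.0 or math.isinf(self.enrichment_factor)):
            raise ValueError("enrichment_factor must be >= 1 (or inf)")
        if self.background_depth < 1 or self.replicates_per_bait < 1:
            raise ValueError("background_depth and replicates_per_bait must be >= 1")

    @property
    def barcode_length(self) -> int:
        return len(self.samples[0][0])

    @property
    def barcodes(self) -> dict[str, str]:
        return {bc: bait for bc, bait in self.samples}


@dataclass(frozen=True)
class PeptideRecord:
    """A library peptide tiled from a disordered region (1-based start)."""

    peptide: str
    protein_id: str
    start: int


# ---------------------------------------------------------------------------
# proteome generation


def _build_blocks(rng: np.random.Generator, length: int, frac: float):
    """Alternating ordered/disordered blocks covering [0, length)."""
    blocks = []
    pos = 0
    while pos < length:
        size = int(rng.integers(25, 61))
        size = min(size, length - pos)
        disordered = bool(rng.random() < frac)
        blocks.append([pos, pos + size, disordered])
        pos += size
    return blocks


def _gap(pos: int, lo: int, hi: int) -> int:
    """Residues strictly between 1-based position ``pos`` and span [lo, hi]."""
    if lo <= pos <= hi:
        return 0
    return lo - pos - 1 if pos < lo else pos - hi - 1


def generate_proteome(spec: SynthProteomeSpec) -> list[ProteinAnnotation]:
    """Generate the annotated toy proteome.

    Planted motif instances sit wholly inside disordered blocks, with no
    proline at wildcard positions, so they survive the downstream scan
    filters (topology permitting).  O-GlcNAc site placement is validated
    against *all* motif matches in the finished sequence, not just the
    planted one, so the near/far label is exact by construction; S/T
    substitution at a site cannot create a new match because neither
    residue belongs to a fixed position of the planted pattern.
    """
    rng = np.random.default_rng(spec.seed)
    motif = DegenerateMotif.parse(spec.planted_motif)
    mlen = len(motif)
    aa = np.array(list(AMINO_ACIDS))
    proteome: list[ProteinAnnotation] = []

    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        blocks = _build_blocks(rng, length, spec.disorder_block_fraction)
        carrier = bool(rng.random() < spec.motif_carrier_fraction)
        if carrier and not any(b[1] - b[0] >= mlen + 4 and b[2] for b in blocks):
            # force one block disordered so the planted instance fits
            longest = max(blocks, key=lambda b: b[1] - b[0])
            longest[2] = True

        seq = rng.choice(aa, size=length)
        disorder = np.full(length, ORDERED_SCORE)
        for lo, hi, dis in blocks:
            if dis:
                disorder[lo:hi] = DISORDERED_SCORE

        planted_span: tuple[int, int] | None = None
        if carrier:
            candidates = [b for b in blocks if b[2] and b[1] - b[0] >= mlen + 4]
            lo, hi, _ = candidates[int(rng.integers(len(candidates)))]
            start0 = int(rng.integers(lo, hi - mlen + 1))
            for off, pos_spec in enumerate(motif.positions):
                if pos_spec is None:
                    choices = [a for a in AMINO_ACIDS if a != "P"]
                else:
                    choices = sorted(pos_spec)
                seq[start0 + off] = choices[int(rng.integers(len(choices)))]
            planted_span = (start0 + 1, start0 + mlen)

        sequence = "".join(seq)
        topology = SECRETED if rng.random() < spec.secreted_fraction else INTRACELLULAR

        # raw matches in the finished sequence (planted + incidental)
        spans = [(s + 1, s + mlen) for s in motif.finditer(sequence)]
        in_span = np.zeros(length + 1, dtype=bool)  # 1-based mask
        for lo1, hi1 in spans:
            in_span[lo1 : hi1 + 1] = True

        has_motif_ptyr = carrier and bool(rng.random() < spec.ptyr_on_motif_fraction)
        near_frac = spec.oglcnac_near_motif_fraction
        if has_motif_ptyr and spec.oglcnac_near_fraction_motif_ptyr is not None:
            near_frac = spec.oglcnac_near_fraction_motif_ptyr

        seq_list = list(sequence)
        oglcnac: list[int] = []
        mean_sites = (
            spec.oglcnac_sites_per_carrier
            if carrier
            else spec.oglcnac_sites_per_noncarrier
        )
        n_sites = int(rng.poisson(mean_sites))
        all_pos = np.arange(1, length + 1)
        for _ in range(n_sites):
            if carrier:
                near = bool(rng.random() < near_frac)
                if near:
                    ok = [
                        p
                        for p in all_pos
                        if not in_span[p]
                        and _gap(p, planted_span[0], planted_span[1])
                        <= spec.proximity_window
                    ]
                else:
                    ok = [
                        p
                        for p in all_pos
                        if not in_span[p]
                        and all(
                            _gap(p, lo1, hi1) > spec.proximity_window
                            for lo1, hi1 in spans
                        )
                    ]
                if not ok:
                    continue  # geometry cannot honour the label; skip the site
                pos = int(ok[int(rng.integers(len(ok)))])
            else:
                free = [p for p in all_pos if not in_span[p]]
                if not free:
                    continue
                pos = int(free[int(rng.integers(len(free)))])
            if pos in oglcnac:
                continue
            seq_list[pos - 1] = "S" if rng.random() < 0.5 else "T"
            oglcnac.append(pos)

        sequence = "".join(seq_list)

        ptyr: list[int] = []
        if has_motif_ptyr and motif.tyr_offset is not None:
            ptyr.append(planted_span[0] + motif.tyr_offset)
        n_bg_ptyr = int(rng.poisson(spec.ptyr_background_per_protein))
        tyr_positions = [
            p for p in all_pos if sequence[p - 1] == "Y" and p not in ptyr and not in_span[p]
        ]
        for _ in range(min(n_bg_ptyr, len(tyr_positions))):
            pos = int(tyr_positions.pop(int(rng.integers(len(tyr_positions)))))
            ptyr.append(pos)

        proteome.append(
            ProteinAnnotation(
                protein_id=f"SYN{i + 1:05d}",
                sequence=sequence,
                disorder=disorder,
                topology=topology,
                oglcnac_sites=sorted(oglcnac),
                ptyr_sites=sorted(ptyr),
            )
        )
    return proteome


# ---------------------------------------------------------------------------
# library tiling


def disordered_runs(protein: ProteinAnnotation, threshold: float = 0.4):
    """Maximal runs of residues with disorder > threshold, 1-based inclusive."""
    mask = protein.disorder > threshold
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(mask)))
    return runs


def generate_library(
    proteome: list[ProteinAnnotation],
    tile_length: int = 16,
    step: int = 8,
) -> list[PeptideRecord]:
    """Tile disordered regions into overlapping peptides.

    Tiles advance by ``step`` within each maximal disordered run; a final
    right-aligned tile is added when the stepping does not reach the run
    end.  Runs shorter than ``tile_length`` are skipped.
    """
    if tile_length < 1 or step < 1:
        raise ValueError("tile_length and step must be >= 1")
    records: list[PeptideRecord] = []
    for protein in proteome:
        for lo, hi in disordered_runs(protein):
            if hi - lo + 1 < tile_length:
                continue
            starts = list(range(lo, hi - tile_length + 2, step))
            last = hi - tile_length + 1
            if starts[-1] != last:
                starts.append(last)
            for s in starts:
                records.append(
                    PeptideRecord(
                        peptide=protein.sequence[s - 1 : s - 1 + tile_length],
                        protein_id=protein.protein_id,
                        start=s,
                    )
                )
    if not records:
        warnings.warn("no disordered region long enough: empty library", stacklevel=2)
    return records


# ---------------------------------------------------------------------------
# selection reads


def _sampling_weights(
    library: list[PeptideRecord], design: SelectionDesign
) -> np.ndarray:
    motif = DegenerateMotif.parse(design.enriched_motif)
    is_motif = np.array([motif.matches(rec.peptide) for rec in library])
    if math.isinf(design.enrichment_factor):
        if not is_motif.any():
            raise ValueError("enrichment_factor=inf but no motif-bearing peptide")
        w = is_motif.astype(float)
    else:
        w = np.where(is_motif, design.enrichment_factor, 1.0)
    return w / w.sum()


def generate_reads(
    library: list[PeptideRecord],
    design: SelectionDesign,
) -> dict[tuple[str, str], list[str]]:
    """Sample selection reads for every (bait, replicate).

    Returns a mapping ``(bait, replicate_name) -> list of read sequences``;
    each replicate holds exactly ``background_depth`` reads of the form
    barcode + 5' adapter + 48-nt insert + 3' adapter.  Use
    :func:`proppd.io.write_fastq_runs` to serialise to FASTQ.
    """
    if not library:
        raise ValueError("empty library")
    rng = np.random.default_rng(design.seed)
    probs = _sampling_weights(library, design)
    inserts = [reverse_translate(rec.peptide) for rec in library]
    for ins in inserts:
        if len(ins) != design.insert_length_nt:
            raise ValueError(
                f"insert length {len(ins)} != designed {design.insert_length_nt}"
            )
    nucleotides = np.array(list("ACGT"))
    runs: dict[tuple[str, str], list[str]] = {}
    for barcode, bait in design.samples:
        for rep in range(1, design.replicates_per_bait + 1):
            counts = rng.multinomial(design.background_depth, probs)
            reads: list[str] = []
            for idx in np.nonzero(counts)[0]:
                read = barcode + design.adapter_5p + inserts[idx] + design.adapter_3p
                reads.extend([read] * int(counts[idx]))
            order = rng.permutation(len(reads))
            reads = [reads[i] for i in order]
            if design.error_rate > 0:
                reads = [
                    _mutate(read, design.error_rate, rng, nucleotides)
                    for read in reads
                ]
            runs[(bait, f"rep{rep}")] = reads
    return runs


def _mutate(read: str, rate: float, rng: np.random.Generator, nucs) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    chars = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        current = chars[pos]
        options = [n for n in nucs if n != current]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)
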