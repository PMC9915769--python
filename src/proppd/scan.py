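"""Proteome-wide motif scanning under disorder, proline and topology filters.

A raw pattern match in a protein only becomes a biologically credible SLiM
instance when (i) it sits in an intrinsically disordered region (all motif
residues with disorder score > 0.4 by default), (ii) none of the wildcard
positions is a proline (proline at the spacer positions breaks the bound
conformation), and (iii) the protein — or the matched region — is
intracellular, since the partner enzyme is cytoplasmic/nuclear.  All
coordinates are 1-based and inclusive, matching how residues are numbered
in protein databases (e.g. a motif at P145…I149 spans 145–149).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .motif import DegenerateMotif

INTRACELLULAR = "intracellular"
SECRETED = "secreted"
EXTRACELLULAR_DOMAIN = "extracellular_domain"

DISORDER_THRESHOLD = 0.4


@dataclass
class ProteinAnnotation:
    """A protein sequence with per-residue disorder and PTM annotations.

    ``disorder`` holds one score in [0, 1] per residue.  ``topology`` is a
    protein-level flag; optional ``extracellular_regions`` (1-based closed
    intervals) refine it to domain granularity.  PTM site lists hold 1-based
    residue positions.
    """

    protein_id: str
    sequence: str
    disorder: np.ndarray
    topology: str = INTRACELLULAR
    oglcnac_sites: list[int] = field(default_factory=list)
    ptyr_sites: list[int] = field(default_factory=list)
    extracellular_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=float)
        if len(self.disorder) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: disorder length {len(self.disorder)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Check site bounds (error) and site-residue consistency (warning)."""
        for name, sites, allowed in (
            ("OGlcNAc", self.oglcnac_sites, "ST"),
            ("pTyr", self.ptyr_sites, "Y"),
        ):
            for pos in sites:
                if not 1 <= pos <= self.length:
                    raise ValueError(
                        f"{self.protein_id}: {name} site {pos} outside [1, {self.length}]"
                    )
                if self.sequence[pos - 1] not in allowed:
                    warnings.warn(
                        f"{self.protein_id}: {name} site {pos} on "
                        f"{self.sequence[pos - 1]!r}, expected one of {allowed}",
                        stacklevel=2,
                    )


@dataclass
class MotifHit:
    """One motif match; ``start``/``end`` are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    sequence: str
    motif_tyr_position: int | None
    passed_disorder: bool
    passed_proline_exclusion: bool
    passed_topology: bool

    @property
    def passed(self) -> bool:
        return (
            self.passed_disorder
            and self.passed_proline_exclusion
            and self.passed_topology
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _topology_ok(protein: ProteinAnnotation, start: int, end: int) -> bool:
    if protein.topology == SECRETED:
        return False
    if protein.topology == EXTRACELLULAR_DOMAIN and not protein.extracellular_regions:
        return False
    for lo, hi in protein.extracellular_regions:
        if start <= hi and end >= lo:
            return False
    return True


def _evaluate(
    protein: ProteinAnnotation,
    motif: DegenerateMotif,
    start0: int,
    disorder_threshold: float,
    disorder_mode: str,
) -> MotifHit:
    length = len(motif)
    start, end = start0 + 1, start0 + length
    span_scores = protein.disorder[start0 : start0 + length]
    if disorder_mode == "all":
        dis_ok = bool(np.all(span_scores > disorder_threshold))
    elif disorder_mode == "mean":
        dis_ok = bool(np.mean(span_scores) > disorder_threshold)
    else:
        raise ValueError(f"unknown disorder_mode {disorder_mode!r}")
    pro_ok = all(
        protein.sequence[start0 + off] != "P"
        for off, p in enumerate(motif.positions)
        if p is None
    )
    tyr = motif.tyr_offset
    return MotifHit(
        protein_id=protein.protein_id,
        start=start,
        end=end,
        sequence=protein.sequence[start0 : start0 + length],
        motif_tyr_position=start + tyr if tyr is not None else None,
        passed_disorder=dis_ok,
        passed_proline_exclusion=pro_ok,
        passed_topology=_topology_ok(protein, start, end),
    )


def scan(
    proteome: list[ProteinAnnotation],
    motif: DegenerateMotif | str,
    disorder_threshold: float = DISORDER_THRESHOLD,
    exclude_P_at_x: bool = True,
    topology_filter: bool = True,
    disorder_mode: str = "all",
) -> tuple[list[MotifHit], set[str]]:
    """Scan a proteome for motif instances and apply the three filters.

    Every raw (overlapping) match is reported as a :class:`MotifHit` with
    per-filter booleans; the returned protein set contains proteins with at
    least one hit passing all *enabled* filters.  Disabling a filter makes
    its predicate vacuously true for the protein-set decision while the
    boolean still records the underlying fact.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif.parse(motif)
    hits: list[MotifHit] = []
    passing_proteins: set[str] = set()
    for protein in proteome:
        for start0 in motif.finditer(protein.sequence):
            hit = _evaluate(protein, motif, start0, disorder_threshold, disorder_mode)
            hits.append(hit)
            ok = hit.passed_disorder
            if exclude_P_at_x:
                ok = ok and hit.passed_proline_exclusion
            if topology_filter:
                ok = ok and hit.passed_topology
            if ok:
                passing_proteins.add(protein.protein_id)
    return hits, passing_proteins


def brute_force_scan(
    proteome: list[ProteinAnnotation],
    motif: DegenerateMotif | str,
    disorder_threshold: float = DISORDER_THRESHOLD,
    disorder_mode: str = "all",
) -> list[MotifHit]:
    """Exhaustive position-by-position rescan; test oracle for :func:`scan`."""
    if isinstance(motif, str):
        motif = DegenerateMotif.parse(motif)
    hits: list[MotifHit] = []
    for protein in proteome:
        for start0 in range(len(protein.sequence) - len(motif) + 1):
            if motif.matches_at(protein.sequence, start0):
                hits.append(
                    _evaluate(protein, motif, start0, disorder_threshold, disorder_mode)
                )
    return hits


def passing_hits(hits: list[MotifHit]) -> list[MotifHit]:
    """Hits that pass all three filters."""
    return [h for h in hits if h.passed]
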