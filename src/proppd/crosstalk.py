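"""PTM-crosstalk statistics around motif instances.

Quantifies how O-GlcNAcylation and tyrosine phosphorylation distribute
relative to motif instances: the distance from each O-GlcNAc site to the
nearest motif (gap convention — residues strictly between site and motif,
so a site at 114 sits 30 residues from a motif spanning 145–149), overlap
sets among motif-containing / O-GlcNAcylated / pTyr / motif-phosphorylated
proteins, and generic hypergeometric set enrichment with Benjamini–Hochberg
FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scan import MotifHit, ProteinAnnotation, passing_hits

GAP = "gap"
NEAREST = "nearest"


def percentage(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 1 decimal (126/223 -> 56.5)."""
    if denominator == 0:
        return 0.0
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def site_motif_distance(
    site: int,
    hits: list[MotifHit] | list[tuple[int, int]],
    convention: str = GAP,
) -> int:
    """Residue separation between a site and the nearest motif instance.

    ``gap`` (default): 0 inside any motif span, otherwise the number of
    residues strictly between the site and the nearest motif residue,
    minimised over hits.  ``nearest``: absolute offset to the nearest motif
    residue (gap + 1 outside a span).
    """
    if not hits:
        raise ValueError("no motif hits for this protein")
    spans = [h.span if isinstance(h, MotifHit) else tuple(h) for h in hits]
    best = None
    for lo, hi in spans:
        if lo <= site <= hi:
            d = 0
        elif convention == GAP:
            d = lo - site - 1 if site < lo else site - hi - 1
        elif convention == NEAREST:
            d = lo - site if site < lo else site - hi
        else:
            raise ValueError(f"unknown convention {convention!r}")
        best = d if best is None else min(best, d)
    return best


@dataclass
class CrosstalkSummary:
    """Counts and percentages of the motif/PTM overlap analysis.

    All denominators follow the protein-set logic of the study design:
    percentages of proteins are over the motif-containing set (except the
    motif-pTyr percentage, which is over pTyr proteins, and the
    with-O-GlcNAc percentage, over motif-pTyr proteins); the site-level
    fraction is over assigned O-GlcNAc sites in motif-containing proteins.
    """

    window: int
    n_motif_proteins: int
    n_oglcnac_proteins: int
    n_sites_assigned: int
    n_sites_within_window: int
    n_ptyr_proteins: int
    n_motif_ptyr_proteins: int
    n_motif_ptyr_with_oglcnac: int
    pct_oglcnac_proteins: float = field(init=False)
    pct_sites_within_window: float = field(init=False)
    pct_ptyr_proteins: float = field(init=False)
    pct_motif_ptyr_of_ptyr: float = field(init=False)
    pct_motif_ptyr_with_oglcnac: float = field(init=False)

    def __post_init__(self) -> None:
        self.pct_oglcnac_proteins = percentage(
            self.n_oglcnac_proteins, self.n_motif_proteins
        )
        self.pct_sites_within_window = percentage(
            self.n_sites_within_window, self.n_sites_assigned
        )
        self.pct_ptyr_proteins = percentage(self.n_ptyr_proteins, self.n_motif_proteins)
        self.pct_motif_ptyr_of_ptyr = percentage(
            self.n_motif_ptyr_proteins, self.n_ptyr_proteins
        )
        self.pct_motif_ptyr_with_oglcnac = percentage(
            self.n_motif_ptyr_with_oglcnac, self.n_motif_ptyr_proteins
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def site_distances(
    proteome: list[ProteinAnnotation],
    hits: list[MotifHit],
    convention: str = GAP,
) -> pd.DataFrame:
    """Per-site distance table for O-GlcNAc sites in motif-bearing proteins.

    Only hits passing all filters define motif instances; proteins without
    a passing hit contribute no rows.  ``motif_ptyr`` flags sites in
    proteins phosphorylated exactly on a motif tyrosine.
    """
    ok = passing_hits(hits)
    by_protein: dict[str, list[MotifHit]] = {}
    for h in ok:
        by_protein.setdefault(h.protein_id, []).append(h)

    rows = []
    for protein in proteome:
        phits = by_protein.get(protein.protein_id)
        if not phits:
            continue
        tyr_positions = {
            h.motif_tyr_position for h in phits if h.motif_tyr_position is not None
        }
        motif_ptyr = bool(tyr_positions & set(protein.ptyr_sites))
        for site in protein.oglcnac_sites:
            rows.append(
                {
                    "protein_id": protein.protein_id,
                    "site": site,
                    "distance": site_motif_distance(site, phits, convention),
                    "motif_ptyr": motif_ptyr,
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "site", "distance", "motif_ptyr"])


def summarize(
    proteome: list[ProteinAnnotation],
    hits: list[MotifHit],
    window: int = 100,
    convention: str = GAP,
    bin_width: int = 10,
) -> tuple[CrosstalkSummary, pd.DataFrame]:
    """Protein- and site-level crosstalk summary plus distance histogram.

    Returns the summary and a histogram table (columns ``bin_lo``,
    ``bin_hi``, ``all_motifs``, ``motif_ptyr``) of site-to-motif distances
    for all motif proteins and for the motif-phosphorylated subset.
    """
    ok = passing_hits(hits)
    by_protein: dict[str, list[MotifHit]] = {}
    for h in ok:
        by_protein.setdefault(h.protein_id, []).append(h)

    motif_proteins = [p for p in proteome if p.protein_id in by_protein]
    n_og = sum(1 for p in motif_proteins if p.oglcnac_sites)
    n_py = sum(1 for p in motif_proteins if p.ptyr_sites)
    motif_ptyr_ids = set()
    for p in motif_proteins:
        tyr_positions = {
            h.motif_tyr_position
            for h in by_protein[p.protein_id]
            if h.motif_tyr_position is not None
        }
        if tyr_positions & set(p.ptyr_sites):
            motif_ptyr_ids.add(p.protein_id)
    n_mpy_og = sum(
        1 for p in motif_proteins if p.protein_id in motif_ptyr_ids and p.oglcnac_sites
    )

    dist = site_distances(proteome, hits, convention)
    n_sites = len(dist)
    n_within = int((dist["distance"] <= window).sum()) if n_sites else 0

    summary = CrosstalkSummary(
        window=window,
        n_motif_proteins=len(motif_proteins),
        n_oglcnac_proteins=n_og,
        n_sites_assigned=n_sites,
        n_sites_within_window=n_within,
        n_ptyr_proteins=n_py,
        n_motif_ptyr_proteins=len(motif_ptyr_ids),
        n_motif_ptyr_with_oglcnac=n_mpy_og,
    )

    if n_sites:
        top = int(dist["distance"].max()) + 1
        edges = np.arange(0, top + bin_width, bin_width)
        all_counts, _ = np.histogram(dist["distance"], bins=edges)
        sub = dist.loc[dist["motif_ptyr"], "distance"]
        sub_counts, _ = np.histogram(sub, bins=edges)
        hist = pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "all_motifs": all_counts,
                "motif_ptyr": sub_counts,
            }
        )
    else:
        hist = pd.DataFrame(columns=["bin_lo", "bin_hi", "all_motifs", "motif_ptyr"])
    return summary, hist


def enrich(
    query: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a query set.

    Exact upper tail P(X >= k) drawing ``n = |query|`` from a universe of
    ``N`` with ``K`` term members, BH-corrected across terms; the
    ``significant`` column marks q < alpha.  Terms with no member in the
    universe are skipped with a warning.
    """
    if not query <= universe:
        raise ValueError("query set must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, members in term_map.items():
        in_universe = members & universe
        if not in_universe:
            warnings.warn(f"term {term!r} has no members in universe; skipped",
                          stacklevel=2)
            continue
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame["significant"] = frame["q"] < alpha
        frame = frame.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        frame["q"] = []
        frame["significant"] = []
    return frame
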