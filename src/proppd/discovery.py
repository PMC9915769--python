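"""De novo degenerate motif discovery from an enriched peptide set.

Seed-and-degenerate enumeration: every ungapped k-mer present in the
peptides seeds candidates by wildcarding interior positions (at least three
positions stay fixed; the first and last never degenerate to wildcards),
and candidates identical except at one fixed position are merged into
two-residue sets when both variants occur — the step that turns ``PxYxI``
plus ``PxYxL`` into ``PxYx[IL]``.

Overrepresentation is modelled per peptide: a peptide of length W either
contains a match or not, with background probability
``p_bg = 1 - (1 - p_site)^(W - L + 1)`` where ``p_site`` multiplies the
background frequencies of the allowed residues over fixed positions.  The
candidate's p-value is the exact binomial upper tail of the number of
motif-bearing peptides, Benjamini–Hochberg corrected across candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motif import AMINO_ACIDS, DegenerateMotif, uniform_background

P_VALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class MotifScore:
    """Binomial overrepresentation of one motif in a peptide set."""

    k: int
    N: int
    p_bg: float
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class Candidate:
    motif: DegenerateMotif
    support: frozenset  # indices of peptides containing >= 1 match


def _interior_masks(length: int, min_fixed: int = 3):
    interior = range(1, length - 1)
    max_wild = length - min_fixed
    for r in range(0, max_wild + 1):
        yield from itertools.combinations(interior, r)


def enumerate_motifs(
    peptides: list[str],
    L_range: tuple[int, int] = (4, 6),
    max_ambiguous: int = 1,
    min_support: int = 2,
) -> list[Candidate]:
    """Enumerate degenerate candidates present in the peptides.

    Candidates are keyed by their position tuple, and each carries the set
    of peptide indices containing at least one match — exact by
    construction, because a merged pattern's support is the union of its
    variants' supports.  ``min_support`` prunes candidates backed by fewer
    peptides (a single peptide still yields its own exact k-mers when
    ``min_support <= 1``; with one input peptide the floor drops to 1
    automatically so exact substrings survive).
    """
    if not peptides:
        raise ValueError("empty peptide set")
    lo, hi = L_range
    if lo < 3 or hi > 8 or lo > hi:
        raise ValueError("motif length range must lie within [3, 8]")
    floor = min(min_support, len(peptides))

    # slots are interned strings (1 residue fixed, 2 residues ambiguous)
    # or None for wildcards; frozensets are built only for the survivors.
    support: dict[tuple, set[int]] = {}
    for idx, pep in enumerate(peptides):
        for L in range(lo, hi + 1):
            for s in range(len(pep) - L + 1):
                kmer = pep[s : s + L]
                for mask in _interior_masks(L):
                    key = tuple(
                        None if j in mask else kmer[j] for j in range(L)
                    )
                    support.setdefault(key, set()).add(idx)

    # iterative pairwise merging of singleton residues into 2-residue sets;
    # |a ∪ b| <= |a| + |b| lets hopeless pairs be skipped exactly.
    current = dict(support)
    for _ in range(max_ambiguous):
        merged: dict[tuple, set[int]] = {}
        groups: dict[tuple, list[tuple]] = {}
        for key, sup in current.items():
            for p, slot in enumerate(key):
                if slot is None or len(slot) != 1:
                    continue
                groups.setdefault((p, key[:p], key[p + 1 :]), []).append((slot, sup))
        for (p, left, right), members in groups.items():
            if len(members) < 2:
                continue
            for (a, sup_a), (b, sup_b) in itertools.combinations(members, 2):
                if len(sup_a) + len(sup_b) < floor:
                    continue
                new_key = left + ("".join(sorted((a, b))),) + right
                union = sup_a | sup_b
                prev = merged.get(new_key)
                if prev is None:
                    merged[new_key] = union
                else:
                    prev |= union
        for key, sup in merged.items():
            if key in current:
                current[key] |= sup
            else:
                current[key] = sup

    out = []
    for key, sup in current.items():
        if len(sup) < floor:
            continue
        positions = tuple(None if s is None else frozenset(s) for s in key)
        out.append(Candidate(DegenerateMotif(positions), frozenset(sup)))
    return out


def score_motif(
    motif: DegenerateMotif,
    peptides: list[str],
    background: dict[str, float] | None = None,
) -> MotifScore:
    """Exact binomial upper tail for the motif's per-peptide match count.

    Matches are counted by scanning every peptide; a degenerate background
    (zero frequency for a required residue) yields p_site = 0, reported as
    p = 1 when no peptide matches and as the 1e-300 floor otherwise.
    """
    if background is None:
        background = uniform_background()
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides must share a single length")
    W = lengths.pop()
    L = len(motif)
    if L > W:
        raise ValueError("motif longer than peptides")
    k = sum(motif.matches(p) for p in peptides)
    N = len(peptides)
    p_site = motif.site_probability(background)
    p_bg = 1.0 - (1.0 - p_site) ** (W - L + 1)
    if p_bg <= 0.0:
        p_value = 1.0 if k == 0 else P_VALUE_FLOOR
    else:
        p_value = max(float(stats.binom.sf(k - 1, N, p_bg)), P_VALUE_FLOOR)
    return MotifScore(k=k, N=N, p_bg=p_bg, p_value=p_value)


def rank_motifs(
    candidates: list[Candidate],
    peptides: list[str],
    background: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score candidates (support-set counts), BH-correct and rank.

    Ordering: ascending p-value, then more fixed positions, then pattern
    string — so the ranking is invariant to peptide input order.  The
    support-set count equals what :func:`score_motif` counts by scanning;
    the two routes are cross-checked in the test suite.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    if background is None:
        background = uniform_background()
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("peptides must share a single length")
    W = lengths.pop()
    N = len(peptides)

    rows = []
    for cand in candidates:
        L = len(cand.motif)
        p_site = cand.motif.site_probability(background)
        p_bg = 1.0 - (1.0 - p_site) ** (W - L + 1)
        rows.append((cand.motif.pattern, len(cand.support), L, cand.motif.n_fixed, p_bg))
    frame = pd.DataFrame(rows, columns=["pattern", "k", "L", "n_fixed", "p_bg"])
    frame["N"] = N
    p = stats.binom.sf(frame["k"] - 1, N, frame["p_bg"])
    p = np.where(frame["p_bg"] <= 0, np.where(frame["k"] == 0, 1.0, P_VALUE_FLOOR), p)
    frame["p_value"] = np.maximum(p, P_VALUE_FLOOR)
    frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame = frame.sort_values(
        by=["p_value", "n_fixed", "pattern"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return frame


def discover(
    peptides: list[str],
    L_range: tuple[int, int] = (4, 6),
    max_ambiguous: int = 1,
    min_support: int = 2,
    background: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, DegenerateMotif]:
    """Enumerate + rank; returns the ranked table and the top motif.

    Peptides are taken as given (duplicates count as repeated observations);
    deduplicate beforehand if one vote per unique sequence is wanted.
    """
    candidates = enumerate_motifs(peptides, L_range, max_ambiguous, min_support)
    ranked = rank_motifs(candidates, peptides, background)
    best = DegenerateMotif.parse(ranked.iloc[0]["pattern"])
    return ranked, best


def build_pfm(
    peptides: list[str],
    motif: DegenerateMotif,
    flank: int = 4,
) -> pd.DataFrame:
    """Position-frequency matrix of peptides aligned on their first match.

    Columns run from ``-flank`` to ``len(motif)-1+flank`` relative to the
    motif start; each column is normalised over the peptides that actually
    cover it, so every occupied column sums to 1.  Suitable for logo
    renderers.
    """
    L = len(motif)
    cols = list(range(-flank, L + flank))
    counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=cols)
    coverage = pd.Series(0, index=cols, dtype=float)
    n_contrib = 0
    for pep in peptides:
        starts = motif.match_starts(pep)
        if not starts:
            continue
        n_contrib += 1
        s = starts[0]
        for col in cols:
            pos = s + col
            if 0 <= pos < len(pep):
                counts.loc[pep[pos], col] += 1
                coverage[col] += 1
    if n_contrib == 0:
        raise ValueError("no peptide matches the motif")
    occupied = coverage > 0
    counts.loc[:, occupied] = counts.loc[:, occupied] / coverage[occupied]
    return counts.loc[:, occupied]
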