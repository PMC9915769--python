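"""PTM-crosstalk distances, overlap summary and set enrichment."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from proppd.crosstalk import (
    CrosstalkSummary,
    enrich,
    percentage,
    site_distances,
    site_motif_distance,
    summarize,
)
from proppd.scan import scan
from proppd.simulate import SynthProteomeSpec, generate_proteome

from conftest import make_protein


class TestDistanceConvention:
    def test_upstream_site_gap_count(self):
        # a site at 114 sits 30 residues upstream of a motif spanning 145-149
        assert site_motif_distance(114, [(145, 149)]) == 30

    def test_site_inside_span_is_zero(self):
        assert site_motif_distance(147, [(145, 149)]) == 0

    def test_adjacent_site_has_zero_gap(self):
        assert site_motif_distance(150, [(145, 149)]) == 0

    def test_minimised_over_hits(self):
        assert site_motif_distance(114, [(145, 149), (300, 304)]) == 30
        assert site_motif_distance(114, [(116, 120), (145, 149)]) == 1

    def test_nearest_residue_convention(self):
        assert site_motif_distance(114, [(145, 149)], convention="nearest") == 31
        assert site_motif_distance(150, [(145, 149)], convention="nearest") == 1
        assert site_motif_distance(147, [(145, 149)], convention="nearest") == 0

    def test_no_hits_is_error(self):
        with pytest.raises(ValueError):
            site_motif_distance(10, [])


class TestPercentages:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(126, 223, 56.5), (64, 374, 17.1), (189, 223, 84.8),
         (61, 189, 32.3), (47, 61, 77.0)],
    )
    def test_published_style_ratios(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_up_rounding(self):
        assert percentage(1, 800) == 0.1  # 0.125% -> 0.1
        assert percentage(1, 16) == 6.3  # 6.25% -> 6.3 (half-up)

    def test_summary_percentages_derive_from_counts(self):
        s = CrosstalkSummary(
            window=100,
            n_motif_proteins=223,
            n_oglcnac_proteins=126,
            n_sites_assigned=374,
            n_sites_within_window=64,
            n_ptyr_proteins=189,
            n_motif_ptyr_proteins=61,
            n_motif_ptyr_with_oglcnac=47,
        )
        assert s.pct_oglcnac_proteins == 56.5
        assert s.pct_sites_within_window == 17.1
        assert s.pct_ptyr_proteins == 84.8
        assert s.pct_motif_ptyr_of_ptyr == 32.3
        assert s.pct_motif_ptyr_with_oglcnac == 77.0


class TestSummarize:
    def _proteome(self):
        seq = "AA" + "PVYQI" + "A" * 193  # motif at 3-7, length 200
        a = make_protein("A", seq, oglcnac_sites=[50], ptyr_sites=[5])
        b = make_protein("B", seq, oglcnac_sites=[150, 190], ptyr_sites=[120])
        c = make_protein("C", "G" * 200)  # no motif
        return [a, b, c]

    def test_counts_by_hand(self):
        proteome = self._proteome()
        hits, _ = scan(proteome, "PxYx[IL]")
        s, hist = summarize(proteome, hits, window=100)
        assert s.n_motif_proteins == 2
        assert s.n_oglcnac_proteins == 2
        assert s.n_sites_assigned == 3
        # gaps: A:50 -> 42; B:150 -> 142; B:190 -> 182
        assert s.n_sites_within_window == 1
        assert s.n_ptyr_proteins == 2
        assert s.n_motif_ptyr_proteins == 1  # A has pTyr at motif Y (5)
        assert s.n_motif_ptyr_with_oglcnac == 1
        assert s.pct_sites_within_window == 33.3
        assert hist["all_motifs"].sum() == 3
        assert hist["motif_ptyr"].sum() == 1  # only A's site

    def test_empty_annotations(self):
        seq = "AA" + "PVYQI" + "A" * 193
        proteome = [make_protein("A", seq)]
        hits, _ = scan(proteome, "PxYx[IL]")
        s, hist = summarize(proteome, hits)
        assert s.n_sites_assigned == 0
        assert s.pct_sites_within_window == 0.0
        assert s.pct_oglcnac_proteins == 0.0
        assert hist.empty

    def test_subset_chain_invariant_on_synthetic_proteome(self):
        spec = SynthProteomeSpec(n_proteins=150, seed=23)
        proteome = generate_proteome(spec)
        hits, _ = scan(proteome, spec.planted_motif)
        s, _ = summarize(proteome, hits)
        assert s.n_motif_ptyr_with_oglcnac <= s.n_motif_ptyr_proteins
        assert s.n_motif_ptyr_proteins <= s.n_ptyr_proteins
        assert s.n_ptyr_proteins <= s.n_motif_proteins

    def test_directional_enrichment_of_motif_ptyr_subset(self):
        """When the generator plants more proximal O-GlcNAc on
        motif-phosphorylated proteins, the subset fraction must exceed the
        overall fraction."""
        spec = SynthProteomeSpec(
            n_proteins=400,
            seed=31,
            oglcnac_near_motif_fraction=0.15,
            oglcnac_near_fraction_motif_ptyr=0.5,
        )
        proteome = generate_proteome(spec)
        hits, _ = scan(proteome, spec.planted_motif)
        dist = site_distances(proteome, hits)
        overall = (dist["distance"] <= 100).mean()
        subset = (dist.loc[dist["motif_ptyr"], "distance"] <= 100).mean()
        assert subset > overall


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exact enumeration over draw outcomes with rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


class TestEnrich:
    def test_exact_combinatorial_example(self):
        # draw 4 of 10, term of 5, all 4 hits: C(5,4)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(4)}
        res = enrich(query, {"T": term}, universe)
        assert res.loc[0, "p"] == pytest.approx(5 / 210, abs=1e-12)

    def test_forced_and_empty_outcomes(self):
        universe = {"a", "b", "c"}
        assert enrich(universe, {"T": universe}, universe).loc[0, "p"] == 1.0
        res = enrich({"a"}, {"T": {"b", "c"}}, universe)
        assert res.loc[0, "k"] == 0 and res.loc[0, "p"] == 1.0

    def test_matches_enumeration_oracle_on_small_universes(self, rng):
        for _ in range(40):
            N = int(rng.integers(4, 13))
            universe = {f"g{i}" for i in range(N)}
            items = sorted(universe)
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(items, size=K, replace=False))
            query = set(rng.choice(items, size=n, replace=False))
            res = enrich(query, {"T": term}, universe)
            k = len(term & query)
            assert res.loc[0, "k"] == k
            assert res.loc[0, "p"] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), abs=1e-12
            )

    def test_bh_and_warnings(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        terms = {
            "hit": {f"g{i}" for i in range(5)},
            "miss": {f"g{i}" for i in range(10, 20)},
            "ghost": {"absent"},
        }
        with pytest.warns(UserWarning, match="ghost"):
            res = enrich(query, terms, universe)
        assert set(res["term"]) == {"hit", "miss"}
        assert (res["q"] >= res["p"] - 1e-15).all()
        assert res["p"].is_monotonic_increasing

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"x"}, {"T": {"a"}}, {"a", "b"})


class TestParameterRecovery:
    def test_within_window_fraction_recovers_planted_value(self):
        f = 0.3
        spec = SynthProteomeSpec(
            n_proteins=400, seed=41, oglcnac_near_motif_fraction=f
        )
        proteome = generate_proteome(spec)
        hits, _ = scan(proteome, spec.planted_motif)
        dist = site_distances(proteome, hits)
        n = len(dist)
        frac = (dist["distance"] <= 100).mean()
        se = math.sqrt(f * (1 - f) / n)
        assert abs(frac - f) <= 3 * se
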