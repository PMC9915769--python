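# Methods

This note documents the models, conventions and numerical choices behind
`proppd`, and what the synthetic benchmark does and does not establish.

## Synthetic study generator

The generator (`proppd.simulate`) emulates the statistical structure of a
ProP-PD selection against a motif-binding bait, not its biochemistry.

**Proteome.** Proteins are i.i.d. uniform over the 20 residues, with
lengths uniform on `length_range` (default 250–400, typical of
disorder-rich signalling proteins). Disorder is block-wise: alternating
blocks of 25–60 residues are disordered with probability
`disorder_block_fraction` (default 0.5), scored 0.8 versus 0.1 for ordered
blocks. Only the > 0.4 threshold matters downstream, so block-wise
constants are sufficient; real per-residue disorder profiles are an input,
not something this package predicts.

**Motif planting.** Each protein is a carrier with probability
`motif_carrier_fraction` (default 0.3). One instance of the planted
pattern (default `PxYx[IL]`) is written wholly inside a disordered block,
with wildcard positions drawn from the 19 non-proline residues — so a
planted instance always survives the disorder and proline filters, and
topology (10% of proteins are flagged secreted) is the only way a planted
instance can drop out, as in the real filtering logic.

**PTM tables.** O-GlcNAc sites per carrier are Poisson(4) (Poisson(1) for
non-carriers); each site is "near" with probability
`oglcnac_near_motif_fraction` (default 0.171, the study-scale within-window
fraction) and placed so that its gap distance to the planted motif is
≤ `proximity_window` (default 100), otherwise > window from **every** raw
match of the pattern in the finished sequence. Validating far placements
against all matches — not just the planted one — removes the bias that
incidental background matches would otherwise introduce, which is what
makes the planted fraction exactly recoverable. Sites are never placed
inside a match span, and the S/T substitution at a site cannot create a
new match (neither residue occurs in a fixed position of the pattern), so
the near/far label is exact by construction. Carriers are phosphorylated
on the motif tyrosine with probability `ptyr_on_motif_fraction` (default
0.323); background pTyr sites are Poisson(1) over non-motif tyrosines.
`oglcnac_near_fraction_motif_ptyr` optionally raises the near fraction for
motif-phosphorylated carriers, producing the directional enrichment of
proximal O-GlcNAcylation that the crosstalk summary is designed to detect.

**Library and reads.** 16-mers are tiled at step 8 across maximal
disordered runs (the tiling step of the real library is not public; step 8
gives the half-overlap that the ≥ 8-residue overlap criterion presumes),
with a final right-aligned tile when stepping undershoots a run end.
Reads are `barcode + 5'adapter + insert + 3'adapter`; inserts come from a
fixed most-frequent-codon reverse translation (determinism). Peptides are
sampled multinomially with weight `enrichment_factor` (default 50; ∞
restricts sampling to motif peptides) for motif-bearing peptides,
`background_depth` reads per replicate (default 5,000), two baits × three
replicates by default. An optional uniform substitution rate is the only
error model; quality scores are constant and ignored downstream.

What passing synthetic tests shows: the pipeline's logic — conservation,
criteria, ranking, recovery — is correct under known ground truth. What it
does not show: robustness to amplification bias, avidity effects,
sequencing error structure, or real disorder/composition biases, none of
which the generator models.

## Read processing

Adapters are anchored at their designed offsets (the library is
fixed-architecture); the 3' anchor is checked at its expected position
first, so an adapter-like sequence inside an insert cannot truncate it. A
read shorter than the architecture is a `length_error`; a displaced 3'
anchor (indels) is a `length_error` when found elsewhere, otherwise
`adapter_mismatch`; any in-frame stop is `stop_codon`. Barcode matching is
exact by default; Hamming ≤ 1 demultiplexing requires a unique nearest
barcode. Translation is Biopython's standard table.

## Confidence criteria

"High counts" has no public definition, so the threshold is a
scale-free quantile (default 0.75) of the nonzero per-peptide totals
within a bait — computed as an **order statistic** (numpy `method="lower"`)
rather than an interpolated quantile, because the order statistic makes
the monotonicity invariant exact: adding reads to a peptide can raise the
threshold past an interpolated quantile it previously met, but never past
the order statistic. "Overlapping" means sharing ≥ 8 identical consecutive
residues with another observed peptide of the same protein — half a
16-mer, i.e. the designed tiling overlap. Criteria are evaluated per bait;
peptides enriched by both baits carry a `shared_between_baits` flag.
Replication is counted within bait (cross-bait agreement is reported by
the flag instead). With no consensus motif supplied the motif criterion is
false, so a first discovery pass runs on peptides meeting the other three.

## Motif discovery statistics

The significance model is deliberately per-peptide (a peptide contains a
match or not), not a full SLiMChance-style correction: it is exactly
testable against closed forms and matches how hits are reported (peptides
containing the motif). Consequences: candidate p-values are not
calibrated for the non-independence of overlapping tiled peptides, so the
*ranking* is the meaningful output, and the test suite asserts recovery
(top rank) rather than absolute p-values. Ties are broken by more fixed
positions, then lexicographic pattern, making the ranking invariant to
peptide input order. Ambiguity is capped at two residues per position and
(by default) one ambiguous position per motif; enumeration is bounded by
construction since every candidate descends from an observed k-mer.
p-values are floored at 1e-300; a background residue with zero frequency
inside a required set yields p = 1 when no peptide matches (and the floor
otherwise). Peptide sets of mixed length are rejected rather than
approximated. The default candidate support floor is 2 (a merge requires
both variants anyway); the pipeline raises it to 5 to prune the
combinatorial tail of single-occurrence background k-mers in large
selected sets.

## Scanning conventions

Coordinates are 1-based inclusive everywhere. "In disorder" means every
motif residue scores > 0.4 (`disorder_mode="all"`); a mean-score variant
exists behind a flag because "the motif lies in a disordered region" is
ambiguous at region edges. The proline exclusion applies to wildcard
positions only (for `PxYx[IL]`, motif positions 2 and 4) and is a filter
on raw matches rather than part of the pattern, so excluded matches remain
visible with their filter booleans. Topology is protein-level by default
(`intracellular` / `secreted`), with optional per-region extracellular
intervals; any overlap with the motif span excludes the hit. All
overlapping matches are reported; a protein counts once in the motif set.

## Crosstalk conventions

Site-to-motif distance uses the strict-gap convention (residues strictly
between the site and the nearest motif residue; 0 inside or adjacent to a
span), which reproduces the canonical "site at 114, motif at 145–149,
30 residues upstream" case; an absolute nearest-residue convention is
available by flag. "Within the window" is gap ≤ window (default 100).
Site-level denominators count assigned O-GlcNAc sites in proteins with at
least one fully passing hit. Percentages are rounded half-up to one
decimal. Set enrichment is the exact hypergeometric upper tail with BH
correction; terms with no members in the universe are skipped with a
warning rather than scored.

## Surface areas

Shrake–Rupley with a golden-spiral point set (deterministic; default 960
points, at which the 240→960 drift is < 1% and rigid-motion sensitivity
< 0.5%), probe 1.4 Å, and vdW radii C 1.70, N 1.55, O 1.52, S 1.80 Å
(unlisted elements fall back to 1.70 Å). Neighbour search uses a k-d tree.
A sample point exactly on a neighbour's expanded sphere (coincident
duplicate atoms) is assigned to the lower-index atom so degenerate inputs
count shared surface once. Hydrogens, waters and heteroatom ligands are
excluded by default, so a protein–peptide partition measures the
protein–peptide interface even when a nucleotide ligand sits nearby; flags
re-include them. Chain groups must be named explicitly — crystals may
carry several complex copies per asymmetric unit, and guessing a partition
would silently average interfaces. BSA values carry the usual ±few-percent
dependence on radii set and point density; comparisons across tools should
expect differences of that order.

## Problem sizes and defaults in the benchmark suite

The shipped tests and `scripts/acceptance.py` use 60-protein proteomes
with 4,000 reads per replicate for the 20-seed recovery benchmark, a
2,600-protein proteome (≈ 2,800 O-GlcNAc sites) for proximity-fraction
recovery, 1,000 random sequences for the scan/brute-force equivalence,
200,000-point Monte-Carlo sampling for the SASA oracle, and universes of
≤ 12 for exact hypergeometric enumeration — sizes chosen so the whole
benchmark completes in minutes on a single CPU while keeping every
statistical tolerance at 3 standard errors or tighter.

## Known limitations

* The binomial motif score ignores peptide non-independence (overlapping
  tiles from one protein); it ranks, it does not calibrate.
* The generator's uniform residue background understates the
  low-complexity structure of real disordered regions; a composition table
  can be supplied to the scorer but not yet to the generator.
* Per-region topology must be provided as explicit intervals; no signal-
  peptide or membrane-topology prediction is attempted.
* SASA treats all atoms as spheres at full occupancy; altlocs are not
  resolved beyond the duplicate-atom tie rule.
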