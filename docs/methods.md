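# Methods

## Percent identity

Identity between two rows of a multiple sequence alignment is computed
column-wise. The default *coverage* convention scores every column where
at least one of the two sequences carries a residue: equal non-gap
residues are matches, a residue opposite a gap is a mismatch, and columns
gapped in both sequences are excluded from the denominator. This is
stable, symmetric and standard for MSA-derived identities, but published
identity figures rarely state their convention, so two alternatives are
selectable throughout (`aligned`: only columns where both sequences have
residues; `columns`: every alignment column). Ambiguity codes (`X`
protein, `N` nucleotide) never count as matches — a conservative choice
that can only lower identities. Sequences are upper-cased and `.` gaps
normalised to `-` on input; columns that are gaps in every record are
dropped by the reader.

Catalytic-domain extraction takes a window in 1-based ungapped residue
coordinates of a named reference sequence and keeps every alignment
column spanned by it (including internal gap columns); rows that become
all-gap are retained so downstream code can decide their fate, columns
that become all-gap are dropped. Domain boundaries are treated as input:
the package does not infer them.

tRNA alignments are consumed pre-aligned. Structure-guided tRNA alignment
is a manual/curated step upstream of this package and no folding is
performed here.

## Clustering

Clustering is unweighted average-linkage (UPGMA) agglomeration performed
directly on the identity matrix: the pair of clusters with the highest
average cross-cluster identity merges first, with the unweighted average
maintained by the Lance–Williams update (algebraically identical to
re-averaging all leaf pairs). Working in similarity space is equivalent
to classical UPGMA on the distance 100 − identity but keeps merge heights
directly comparable to the screening thresholds (55 % for synthetase
catalytic domains, 75 % for tRNAs). Average linkage produces no
inversions, so merge heights are non-increasing; this is asserted at run
time.

The threshold cut applies exactly the merges whose height is *strictly*
greater than the threshold, following the "merged if, and only if,
greater than" rule; whether the original analyses used strict or
non-strict comparison exactly at 55.00 %/75.00 % is not decidable from
their description, and strict was chosen to match the wording. One
deliberate exception: merges at exactly 100 % identity (duplicate
sequences) are always applied, so duplicates never split.

Ties between candidate merges are broken by the lexicographically least
leaf id of each cluster, making trees identical across runs and
platforms. Newick export writes ultrametric branch lengths with node
height (100 − merge identity)/2, so the path between two leaves equals
100 minus the identity at their join.

Cluster representatives are identity-space medoids: the eligible member
maximising mean identity to the rest of its cluster, ties broken
lexicographically. Eligibility models constraints such as "a cognate tRNA
gene exists for this synthetase"; a cluster with no eligible member
yields `None`.

## Activity matrices

Activities are percentages of a wild-type GFP control (a reporter without
the stop codon). Raw reporter readings normalise as
`x = 100·(raw − background)/wt_control` with an optional per-tRNA
background (reporter plus tRNA, no synthetase) and negative results
clamped to zero, since activities are reported as non-negative
throughout. Tables are assumed to be replicate-averaged upstream.

Missing measurements stay explicit (`NaN`) and are never imputed: a tuple
of pairs is only certified orthogonal when all N² of its cells are
measured. An explicit `treat_missing_as_zero` flag exists for exploratory
runs and is off by default — absence of evidence is not orthogonality.

The activity screen keeps each entity whose best measured partner
activity reaches a floor (non-strict, "at least"), defaulting to 30 % of
the control.

## Orthogonality mining

All three criteria use strict inequalities, matching their
"greater than"/"less than" definitions. The orthogonality coefficient is
reported as +∞ when every cross entry is exactly zero; infinite values
sort above all finite ones, ordered among themselves by the observed
cognate floor.

Enumeration pre-computes candidate cognate pairs (every measured cell
strictly above the cognate floor; optionally restricted to a supplied
cognate map when heterologous pairing is disabled) and grows partial
assignments in lexicographic candidate order, so each unordered set is
visited once. A branch is abandoned as soon as any cross entry reaches
the ceiling or the partial o.c. bound falls to the threshold — both safe
because adding a pair can only lower the minimum cognate and raise the
maximum cross (the hereditary property). Output equivalence with
exhaustive enumeration is asserted against an independent brute-force
oracle over randomized matrices in the test suite.

Sets are unordered collections of (synthetase, tRNA) pairs; two sets are
identical iff their pair sets coincide, and engineered tRNA variants with
distinct ids count as distinct tRNAs. Families partition sets by their
unordered synthetase set.

Inter-class classification considers, for each unordered pair of
synthetase classes, every candidate doublet combining one viable pair
from each class. A passing doublet makes the relation mutually
orthogonal; otherwise the relation is *two-sided* when both cross entries
are individually disqualifying for every candidate (at or above the cross
ceiling, or forcing the o.c. down to the threshold), and *one-sided* when
some candidate fails through a single entry. The status vocabulary adds
`no-candidates` for class pairs with no viable doublet at all, rather
than mislabelling them.

## Calibration

For each measured combination, the relevant identity is between the
combination's synthetase and the cognate synthetase of its tRNA (or the
tRNA-side analogue). The cognate map defaults to same-organism pairing
and accepts overrides for heterologous cognate pairs. The headline
statistic is the fraction of combinations with identity strictly above a
threshold whose activity reaches a cutoff. The cutoff defining "active"
is deliberately exposed (default 20 % of control, consistent with the
cross-reactivity ceiling) because summary fractions in the literature do
not print it; `scan_thresholds` reports the fraction as a function of the
threshold, and empty strata are reported as undefined rather than zero.

## Synthetic data

The generator emulates the statistical structure the pipeline exploits,
not the biology producing it:

* **Sequence families.** Each class descends from an independently drawn
  ancestor; members mutate per-site at a rate solved from
  (1−r)² + r²/(k−1) = target, where the target is the midpoint of the
  within-class band and k the alphabet size (chance re-matches included).
  Independent ancestors put between-class identity near the
  random-composition baseline (5 % protein, 25 % nucleotide). Draws are
  rejection-resampled until every realised within-class identity is at or
  above the declared minimum and every between-class identity at or below
  the declared maximum (defaults 70/40); a band below the baseline, or
  one not realised within the bounded retry budget, raises rather than
  silently relaxing. All randomness flows from one explicit seed; equal
  seeds give byte-identical outputs.

* **Activity matrices.** Each entity contributes a synthetase and a tRNA;
  combinations whose entity identity exceeds the threshold are active
  with probability 0.9 by default — the empirically observed rate for
  high-identity pairs — drawn uniformly on [40, 100], otherwise on
  [0, 20]; below-threshold combinations activate with a lower probability
  (default 0.3, reflecting that such combinations behave unpredictably —
  the exact rate is not identified by the motivating data). Optional
  Gaussian noise is clamped at zero. Active and inactive ranges must not
  overlap, mirroring the 40/20 criteria.

* **Planted quintuplet.** Five pairs with cognates on [50, 95] and mutual
  crosses on [0, 10], plus three decoys violating exactly one criterion
  each (cognate 35; cross 25 against every planted synthetase; cross 18
  with cognate 42, capping the o.c. at ~2.33). Decoy crosses apply to all
  planted synthetases, so the planted quintuplet is the unique passing
  5-set. Every fixture self-validates its declared truth on generation.

What passing synthetic tests do *not* show: real alignments have gaps,
indel structure and phylogenetic correlation rather than i.i.d.
substitutions; real activity matrices have measurement noise correlated
within plates, replicate structure, and identity–activity relationships
far noisier than a two-level mixture. Synthetic recovery therefore
validates the algorithms, not the biological thresholds.

## Problem sizes and numerics

The test and acceptance runs use 12-sequence alignments (3 classes × 4,
length 120) for cluster recovery, 32 sequences for calibration (≥500
above-threshold combinations), randomized matrices up to 10 tRNAs × 8
synthetases for the enumeration oracle, and ≤8×8 matrices for the UPGMA
oracle — sizes at which exhaustive oracles are exact and fast while the
pruned search paths being verified are fully exercised. Oracle agreement
is required to 1e-9 on merge heights; floating-point ties in UPGMA are
resolved by the deterministic lexicographic rule. Reproduction of
published cluster counts (37 synthetase, 8 tRNA) and mining counts
requires the corresponding published supplementary alignments and
activity tables, which are not redistributed here; the acceptance tests
document the expected numbers and run whenever those tables are placed
under `data/reference/`. Cluster counts may shift by small amounts under
alternative identity conventions, which is why the convention is a
configuration knob.

## Known limitations

* No statistical treatment of replicate variance: activities are point
  estimates, and criteria are applied to means.
* The pruned search is exponential in the worst case; it is fast for
  realistic matrices (tens of entities, sparse high-activity cells) but
  no polynomial bound is claimed.
* The inter-class classifier reports attainability, not mechanism; it
  does not distinguish which entity causes a one-sided cross-reaction
  beyond the recorded witnesses.
* Dendrogram rendering (radial layouts, heatmaps) is out of scope; trees
  are exported as Newick for external tools.
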