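# Methods

This note documents the models and procedures implemented in
`barcodefish`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about behaviour on real archival libraries.

## Coordinates and missing data

All coordinates are 0-based, half-open, in the frame of each locus
alignment. On input, `N`, `?` and `-` are all treated as missing;
internally `N` means "no call" and `-` means "called deletion" (a
reference position confidently absent from the query). Input sequence
is case-insensitive and canonicalised to upper case.

## Synthetic archival reads (`simulate`)

The generator emulates the read properties reported for archival
wet-specimen capture libraries; it is the ground-truth side of every
downstream test.

* **Panel**: per locus, one uniform-random ancestor; one founder per
  lineage mutated from the ancestor at `between_divergence` expected
  substitutions/site; members mutated from founders at
  `within_diversity`. Substitution is Jukes–Cantor-style (a hit site
  moves to one of the three other bases uniformly), so the expected
  per-site founder–founder difference is `2d(1−d) + (2/3)d²` — the
  closed form the tests check by Monte Carlo. A richer substitution
  model is unnecessary here because the generator only needs to produce
  realistic divergence patterns for assignment; TN93 *estimation* is
  validated separately against its own closed form.
* **Fragments**: lengths normal(`fragment_mean`=60, `fragment_sd`=15)
  truncated to [20, source length]; start positions uniform, rejected
  if the fragment overlaps any `coverage_dropout` interval (this is
  what produces the discrete missing consensus stretches archival
  consensuses show). The read is the first `read_length`=75 bases of
  the fragment (75-cycle single-end sequencing).
* **Damage**: cytosine deamination is read as C→T near the 5′ fragment
  end and G→A near the 3′ end, with per-position probability
  `deam_rate·exp(−i/deam_decay)` (defaults 0.2 and 3 positions). The
  exponential end-concentration is the standard empirical shape for
  ancient/archival DNA; no quantitative damage profile is published for
  the motivating specimen, so the defaults are plausible rather than
  calibrated, and are config-exposed.
* **Noise**: uniform per-base sequencing error (`error_rate`=0.002) and
  a `contam_fraction`=0.1 of reads drawn from contaminant sequences.
  Qualities are constant Q37: quality trimming is exercised with
  hand-built reads instead, keeping simulated damage orthogonal to the
  trimmer.
* **Defaults as study conditions**: 500-nt loci (the scale of the
  ~442/501-nt barcode alignment frames), 2 lineages × 5 members at 6%
  between-lineage divergence (the uncorrected 16S divergence scale of
  the motivating species complex), 170 reads ≈ 20× mean depth, one
  60-nt dropout interval.

What the generator does **not** model: formalin crosslinking, PCR
duplicates (the motivating study deliberately kept clonal reads), indel
damage, quality-error coupling, and fragment-length/damage covariance.
Passing tests therefore show the pipeline's logic is correct under the
stated noise model, not that it is robust to every artefact of real
archival libraries.

## Fishing

Trimming: the longest read suffix matching an adapter prefix over ≥ 8 nt
with at most one mismatch per 10 nt is cut; then, scanning 5′→3′, at the
first 5-base window with mean phred < 20 the read is cut before the
first sub-threshold base in that window; reads shorter than 25 nt are
discarded.

Similarity: best local alignment of the read and its reverse complement
against each reference (match +1, mismatch −1, gap open −2, extend −1);
identity = matches / alignment columns, with mismatch *and gap* columns
in the denominator; alignments shorter than 30 columns score 0. A read
is retained iff its best identity ≥ 0.90 and is assigned to the locus of
its best hit (ties → first locus in panel order). The original study's
filtering script is not fully specified, so this is the most common
reading of "similarity to the references"; consequently the published
retained-read counts are not exactly reproducible even in principle,
and the report fields only mirror their *semantics*.

An optional shared-k-mer prescreen (`prefilter_k`) skips alignments that
cannot share an 11-mer; it is off by default because a ≥ 90%-identity
alignment of ≥ 30 columns does not mathematically guarantee a shared
11-mer. A test asserts it changes nothing on the simulated read set.

## Consensus

Placement is semi-global (read fully aligned, reference end gaps free)
under the fishing scoring scheme; placements scoring below a floor
(default 20) are rejected. Read insertions relative to the reference
are dropped so the consensus lives in reference coordinates; reference
positions deleted in a read are recorded as deletion states and are
callable like bases (emitted as `-`, counted as recovered).

Calling: per column, non-N states are tallied; coverage is the tally
total; the top state is called iff it is strictly greatest and its
fraction exceeds `majority_fraction` (default 0.5) and coverage ≥
`min_depth` (default 3); exact ties give `N`, or a two-base IUPAC code
in the optional `iupac` mode. The majority-based aligner used in the
original study publishes no depth threshold; `min_depth`=3 balances the
low-coverage tail the study reports (4–50× at fragment ends) and is
config-exposed. "Recovered" counts any non-N call, including called
deletions — whether the published recovery counts included such columns
is unstated.

## Diagnostic-position assignment

A column is diagnostic between focal groups iff, ignoring missing
characters, every focal group is monomorphic and the groups' states
differ. Fixity is assessed over the supplied panel (range-wide fixity
cannot be established from a finite panel). The query is scored only at
columns where it has a call; matches to no focal state are recorded as
off-pattern; IUPAC-ambiguous query calls match a group iff the group's
state is in the ambiguity set and are flagged weak. The verdict
requires a strict majority of agreements — equality is reported as
"ambiguous", which the pipeline treats as a finding, not a failure
(exit code 0). Phylogroup-level scoring is the same machinery at a
different label level.

Uncorrected p-distance uses pairwise deletion (columns missing in
either sequence excluded); group distance ranges are min/max over all
cross-group pairs.

## Distances, trees, bootstrap

TN93 is computed from the observed purine-transition, pyrimidine-
transition and transversion proportions with base frequencies estimated
from the pooled pair (the convention of the common desktop packages);
the gamma variant replaces `−ln x` with `a(x^{−1/a} − 1)`. Pairs where
any logarithm/power argument is non-positive (saturation) are flagged
undefined (NaN) rather than clamped. Ambiguity codes are treated as
missing for distance estimation.

Neighbor joining follows Saitou–Nei with Q-criterion ties broken by the
lowest index pair and negative branch lengths clamped to zero. The tree
is unrooted; the final join is represented as a bifurcation whose
midpoint is arbitrary, so path lengths — not individual root-adjacent
edges — are the meaningful quantities, and on additive matrices NJ
reproduces all pairwise path lengths exactly (property-tested on random
5–8-leaf trees and cross-checked topologically against scikit-bio).

Bootstrap: columns resampled with replacement per replicate, distances
and NJ rebuilt, support of an internal edge = percentage of replicates
containing the same leaf bipartition. Replicates with undefined
distances are skipped and counted (warning above 10%). Sequences are
sorted by id internally so supports are exactly invariant to input
order. The default 1000 replicates match standard practice; the
original study's maximum-likelihood search and AIC model selection are
deliberately replaced by this distance framework because the question —
which lineage contains the query — is topological and robust, and the
gamma shape their software estimated is unpublished (plain TN93 is the
default, `gamma_shape` is user-suppliable).

## Morphometrics and range area

Ratios are reported as integer percentages rounded half away from zero,
the convention consistent with both published holotype ratios
(98.07→98, 66.67→67). Size ranges exclude subadults (flagged `(SA)` in
the sex column) unless requested. The minimum convex polygon is the
hull of (lon, lat) points; its area is computed on a sphere of radius
6371.0088 km by summing l'Huilier triangle excesses fanned from one
hull vertex. The library returns full precision (a 3-significant-figure
rounding helper is applied at the presentation layer, because rounding
inside the computation would be larger than the 0.1% agreement the
closed-form oracle test demands). The hull of the eight printed
lowland-species localities is ~1.85 × 10⁴ km²; the published
approximate extent (2.2 × 10⁴ km²) drew on additional localities, so
only the order of magnitude is checked.

## Pipeline and reproducibility

One seed fans out to per-stage seeds by fixed offsets, so stages are
individually re-runnable; identically configured runs produce
byte-identical reports except for wall-clock time. Report invariants
(retained ≤ trimmed ≤ total; per-locus sums; every report number
recomputable from the written intermediates) are tested.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use 500-nt single-locus panels, 170-read
libraries, 20 seeds for parameter recovery, 100–1000 bootstrap
replicates, and 10 000-read/10 000-pair Monte Carlo samples for the
damage and divergence calibration checks — sizes chosen so the full
suite exercises every stage at the study's stated conditions while
remaining a desk-scale computation.

## Known limitations

* No damage-aware alignment or base recalibration: heavily deaminated
  terminal positions can reach the consensus if they dominate a
  low-coverage column (future work).
* No paired-end logic (the motivating data are single-end).
* Identity-threshold fishing is a hard cut; reads just under 90% due to
  damage are lost rather than down-weighted.
* Diagnostic-position fixity is panel-relative.
* The MCP is a crude extent-of-occurrence proxy; it ignores coastlines
  and habitat.
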