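# Methods

`mtmosaic` detects interspecific recombination in complete mitochondrial
genomes: contiguous fragments of a genome whose ancestry lies in another
species' mitochondrial lineage, the molecular signature of hybridization
with paternal leakage.  This note records the statistical models, the
defaults and why they hold, what the simulator does and does not emulate,
and the known limitations.

## Distances and diversity

All divergence measures are raw p-distances: the proportion of differing
sites among *comparable* sites, with no multiple-hit correction.  A site
is comparable for a pair when both sequences carry an unambiguous base;
gaps (`-`) and missing data (`N`, including all other IUPAC ambiguity
codes, which are collapsed to `N` on ingest) are excluded.  Nucleotide
diversity π is the mean p-distance over all unordered pairs.  Two
deletion policies exist: `pairwise` (default; each pair uses its own
comparable sites, which matches per-region fragment lengths reported
"excluding alignment gaps") and `complete` (only columns comparable in
every sequence).

Standard errors come from a site bootstrap: alignment columns are
resampled with replacement (default 1000 replicates, seed 1729) and the
statistic recomputed; pairs are resampled jointly so their estimates
stay coupled.  A resampling SE was chosen over an analytic variance
because it applies identically to single pairs, to π, and to any
deletion policy, and because it is directly testable.  Distances of
exactly zero are reported with SE 0.

## Sliding windows and high-divergence regions

Windows are defined on alignment columns — default 100 columns moved in
25-column steps — so a window spans gaps but excludes them from the
statistic.  Only full windows are evaluated; each value is assigned to
the window midpoint `start + (window-1)//2`.  Windows in which no pair
has a comparable site get value 0 and a flag.

High-divergence (HD) regions are maximal runs of windows whose value
exceeds `max(fold_threshold x median, absolute_floor)`, with runs
separated by a single sub-threshold window merged, runs shorter than
`min_windows` discarded, and output regions whose column spans overlap
(possible because windows overlap) merged.  Defaults: fold 5.0 over the
genome-wide median, floor 0.02, minimum 2 candidate windows.  The floor
encodes that mitochondrial conspecific window diversity of a few percent
is already far outside the intraspecific range; the fold rule adapts to
noisier backgrounds.

Two scan modes serve different inputs.  The group scan (π over all
candidate genomes) dilutes a fragment carried by one of *n* genomes by
the fraction of pairs involving the carrier, so it is the conservative,
low-false-positive view.  The pairwise panel (`hd_regions_from_pairs`)
scans every candidate pair separately and merges overlapping regions
across pairs; on a two-sequence profile at conspecific divergence the
median window value is zero, leaving only the absolute floor, which a
chance cluster of three nearby mutations can clear.  Such a point
cluster can never stay elevated for more than `window//step` consecutive
windows, so the panel requires runs of `window//step + 1` (default 5)
candidate windows; a genuine interspecific fragment of at least one
window's length sustains more.

## The PHI permutation test

Parsimony-informative sites (at least two states each carried by at
least two sequences, gaps/N excluded) are binarized to their two most
frequent states; rows carrying other states are treated as missing for
that site.  For every pair of informative sites separated by at most
`w` columns (default 100), incompatibility is the binary four-gamete
criterion: 1 if all four haplotype combinations occur among rows
observed at both sites.  The statistic is the mean incompatibility over
those nearby pairs.

Significance comes from permuting the assignment of informative sites
to their observed positions (default 100,000 permutations, which
resolves p-values to 1e-5).  Under recombination, nearby sites share a
local genealogy and are *more* compatible than randomly placed sites,
so evidence of recombination is an observed statistic in the lower tail:
`p = (1 + #{permuted <= observed}) / (n_permutations + 1)`.  On clonal
data site order is exchangeable, making the p-value uniform (slightly
conservative at the discreteness floor); the test suite verifies type-I
error <= 0.07 at alpha 0.05 over 200 clonal simulations.

## MaxChi breakpoint scanning

For a candidate/parent pair, the scan walks the alignment-variable
sites at which both carry bases, labels each site match or mismatch for
the pair, and at every cut between consecutive sites forms the 2x2
table (match, mismatch) x (left k sites, right k sites), scoring it
with the chi-square statistic without continuity correction (zero when
a margin is empty).  The breakpoint estimate is the column of the last
left-half site at the maximising cut, ties toward the smaller column.
Significance permutes the match/mismatch labels (default 1000
permutations, upper tail).  Default k = 30 variable sites per
half-window; inside `call_events` k is additionally capped at the
number of pair-variable sites in the segment under test, because a
fragment shorter than k sites would otherwise be diluted by flanking
sites on both sides of its own boundary.

## Triplet scanning and event calling

`triplet_scan` compares a candidate to two parents window by window and
calls each window for whichever parent is strictly closer; maximal runs
of donor-side calls are the raw segment proposals.

`call_events` composes the stages.  For each candidate, every
(conspecific major, other-group minor) pair is scanned; proposals are
clustered by overlap and refined to *anchor* sites: candidate-vs-major
differences where the candidate matches the minor and — when other
same-group sequences exist — at least half of them side with the major.
The majority vote makes anchors lineage-diagnostic rather than
reflections of the major's private mutations (without it, a recombinant
chosen as major parent spawns mirror-image false segments on clean
candidates); co-recombinants sharing the fragment vote against and are
tolerated as a minority.  The reported breakpoints are the midpoints of
the brackets between the outermost anchors and the nearest contradicting
sites, which is where the information about the true breakpoint ends:
the anchor alone is biased inward by one diagnostic-site spacing (~12
columns at 8.5% divergence, ~22 at 4.5%).

Parents are then assigned by distance: the major parent is the
conspecific minimising the genome-minus-segments p-distance (tried in
rank order, since a co-recombinant cannot anchor the shared fragment),
the minor parent the other-group reference minimising the within-segment
distance.  A definitional filter requires the minor to be strictly the
candidate's closest relative within the segment among all same-group
alternatives; segments failing it are native variation, not events.

Each surviving segment is tested with MaxChi at both flanks
(`maxchi_flank` = 1500 columns either side of each breakpoint); the
conservative per-event p is the worse of the two flank p-values,
Bonferroni-corrected by the number of candidate x minor x segment tests
actually performed, and events pass at alpha 0.05.  A PHI test on the
segment plus flanks is computed and reported alongside
(`p_values["phi_local"]`) as a diagnostic; it does not enter the
conservative combination because PHI needs many informative sites on
both sides of a boundary and is underpowered on short fragments that
the chi-square scan localises unambiguously.  Genome-wide recombination
evidence is instead the global PHI reported by the pipeline.

## Mosaic annotation, recency, markers

Per genome, events are ordered by begin; overlapping events (possible
only in pathological configurations) are resolved by keeping the
smaller corrected p and noting the discard.  The recency call is purely
the count of candidate-vs-minor mismatches inside the reported span:
zero mismatches means the fragment is still an exact copy of the donor
lineage ("identical"; compatible with very recent transfer — or with a
PCR-jumping artifact, which is why non-zero counts are the decisive
evidence against artifacts), non-zero means post-transfer divergence
("diverged").  No molecular-clock dating is attempted.  One diagnostic
marker is emitted per event with its identity fraction; markers at
exactly 1.0 are flagged diagnostic-identical.

## The simulator

`simulate` draws a uniform ancestral sequence, derives one reference
per species on a star phylogeny, derives individuals from their species
reference, splices donor fragments into recipients, and applies exactly
the configured number of post-transfer mutations inside each fragment
at recorded positions.  Substitution is independent-site and
Jukes-Cantor-like (uniform over the three alternatives), with no rate
heterogeneity and no indels, so alignments are gapless and planted
breakpoints are exact columns.  Per-branch substitution probabilities
are calibrated so expected pairwise p-distances hit the configured
targets exactly, using `P(differ) = q1 + q2 - (4/3) q1 q2` (coincident
substitutions accounted for); the two-branch case is closed-form and
the general star is solved by least squares, rejecting unsatisfiable
target sets.  Conspecific individuals use the same exact two-branch
calibration at the intraspecific target.

Defaults are the study conditions the pipeline targets: 16,500-column
genomes; a recipient species with five individuals and two single-genome
donor species at 8.5% and 4.5% reference divergence (donor-donor 8.0%);
0.3% conspecific divergence.  The bundled `paper_mimic_config` plants
five fragments: 140, 1710, and 359 columns into one recipient (0, 2, 0
post-transfer mutations), the same 1710-column fragment into a second
recipient (2 mutations), and a 425-column fragment from the second
donor into a third (4 mutations) — two recipients stay clean.

What the simulator does *not* emulate: alignment gaps and indel
evolution (real control regions align with gaps; the pipeline handles
gaps, but gap-robustness is exercised only by unit tests on small
inputs), regional substitution-rate variation (real mitochondrial
fragments can be locally more divergent than the genome average), base
composition bias, and within-species population structure.  Passing
tests therefore demonstrate the statistical machinery under calibrated
divergence, not robustness to alignment error.

## Numerical and procedural choices

- Coordinates are 1-based inclusive alignment columns everywhere;
  BED export converts to 0-based half-open.
- All maxima break ties toward the smaller column; iteration follows
  ingest order; every permutation and bootstrap is seeded, and seeds are
  recorded in results, so reports are byte-identical across runs.
- Permutation p-values use the add-one estimator
  `(1 + #{as-or-more-extreme}) / (n + 1)` and can never be zero.
- Windows with no comparable sites, pairs with no comparable sites, and
  under-informative PHI/MaxChi inputs yield flagged not-computable
  results rather than exceptions; zero-comparable whole-pair distances
  raise, since no downstream statistic is meaningful.
- Test and acceptance problem sizes: full 16,500-column genomes for the
  single-dataset checks; 3,000-column genomes for the 200-replicate
  PHI type-I battery; 20 seeds for recovery properties; 100,000 PHI
  permutations for headline p-values and 500–2,000 inside iterated
  batteries.

## Known limitations

- Breakpoints are identifiable only up to the bracket between adjacent
  lineage-diagnostic sites (expected half-spacing error ~6 columns at
  8.5% divergence, ~11 at 4.5%); mismatch counts over the reported span
  can accordingly gain or lose one site at a fragment edge relative to
  the planted truth (a tail mutation just outside the last anchor).
- A fragment shared identically (zero mismatches in both carriers) by
  two recombinants would fail the strict minor-closest filter in the
  carrier-vs-carrier comparison; the regime studied always leaves
  post-transfer differences, and real shared fragments are expected to
  accumulate them.
- Fragments much shorter than one window (~100 columns) fall below the
  triplet scan's resolution; fragments below ~300 columns at 4.5%
  divergence are detected but with breakpoint error approaching the
  +/-50-column scale.
- The pairwise HD panel's run-length rule (`window//step + 1`) is
  derived for overlapping windows (step <= window, the default
  geometry); with non-overlapping windows it degenerates to a 2-window
  minimum, which is still stricter than a single point cluster can
  sustain.
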