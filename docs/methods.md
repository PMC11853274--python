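# Methods

## Splice-mode classification

Introns are inferred between consecutive exons of each GTF transcript;
each intron is a splice event joining a donor site (first intronic base)
to an acceptor site (last intronic base), identified by 1-based genomic
coordinate and strand-normalized so that "upstream" always means 5′ in
transcription direction. Deduplicated events form a bipartite graph over
distinct donor and acceptor sites, and the acceptor mode follows from the
degrees:

| acceptor degree | donor degrees | mode |
|---|---|---|
| 1 | 1 | common |
| >1 | all 1 | constitutive |
| 1 | >1 | alternative |
| >1 | any >1 | ambiguous (excluded) |

Only the three pure pairing cases are defined; many-to-many structures are
labelled ambiguous and excluded rather than forced into a class.

**Sub-modes.** An alternative acceptor shares its donor with other
acceptors, and its sub-mode is positional: at the annotated intron–exon
junction (*normal*), strictly inside an exon (*exonic*) or strictly inside
an intron (*intronic*). The annotation alone does not say which of the
competing acceptors defines the reference gene model, so the package uses
transcript support: the donor's pairing with the most supporting
transcripts is taken as the reference, its transcripts supply the
exon/intron model, and the remaining acceptors are placed in that model.
Principal junctions recur across isoforms in real annotations, which is
what this majority rule encodes. Ties, disagreement between reference
transcripts, or positions outside the reference span make the acceptor
unclassifiable, and it is excluded rather than guessed.

## Window extraction and filters

Windows are 100 bp centered on the junction — 50 intronic bases ending in
the canonical AG, 50 exonic bases — in transcription orientation
(minus-strand windows reverse-complemented). Site labels are
zero-skipping: −50..−1 upstream, +1..+50 downstream, A and G at −2/−1.

Events are excluded when the intron spans fewer than 100 bases (span =
|acceptor − donor| + 1, boundary bases included; a 100-base span is
retained — the inequality is strict) or when two alternative acceptors
sharing a donor lie closer than 100 bp (both members of the close pair are
removed). Windows containing N are rejected by default because hexamer
counts are undefined over ambiguous bases; windows whose −2/−1 bases are
not AG are rejected when `canonical_only` is set (the default), since the
analysis targets canonical GT-AG splicing.

## Dispersion of hexamer subsets

For N windows, the hexamer starting at each of the 95 sites −50..+45 is
counted over the rank-ordered 4096-word vocabulary (lexicographic,
A<C<G<T). For each dinucleotide XY the vocabulary splits into XY1
(containing XY, orientation-specific, overlaps allowed) and XY0 subsets;
the split depends only on whether the pattern can overlap itself
(X = Y: 991/3105; X ≠ Y: 1185/2911), which a two-term linear recurrence
reproduces and the test suite cross-checks for k = 2..8.

At a site, the dispersion of a subset is ρ = σ_subset/σ_total, the ratio
of population standard deviations of member frequencies (about the member
mean) to that of all 4096 frequencies. Numerical choices:

* population (divide-by-n) form on both numerator and denominator — the
  ratio only requires the two conventions to agree, and the population
  form is defined for any subset size;
* frequencies are counts/N; unobserved hexamers stay in the distribution
  as zeros;
* the ratio is scale-invariant, so counts and frequencies give identical ρ;
* a site whose 4096 frequencies are all equal has no defined ρ and raises
  a degenerate-distribution error rather than returning NaN.

The law of total variance ties the two subset σ to the total σ and is
asserted in the tests to 1e−9 relative tolerance at every site; it also
implies ρ_XY1 and ρ_XY0 cannot both exceed 1 at a site, which is why the
two curves move oppositely around the site trend.

## Region tests

Dispersion curves of two modes are compared with a paired t-test over the
sites of a region, pairing by site: upstream −50..−7 (44 sites, df 43),
core −6..+1 (7 sites, df 6), downstream +2..+45 (44 sites, df 43) by
default. An alternate descriptive boundary set (upstream to −8, core from
−7) is provided as `DESCRIPTIVE_REGIONS`, and bounds are configurable; the
statistical defaults above are what `compare_modes` uses.

Tests are two-sided. BH-FDR is applied within one region over the family
of all 16 patterns × all mode pairs, matching how results are reported
per region. Stars follow the conventional inclusive thresholds (≤0.05 *,
≤0.01 **, ≤0.001 ***, ≤0.0001 ****). Each pattern is grouped per region:
A — every pairwise comparison significant; C — none; B — anything in
between (with three modes, B means one mode is distinguished from the
other two, or a single pair differs).

A caveat the procedure inherits by construction: adjacent hexamer sites
share five of six bases, so per-site dispersion values are strongly
autocorrelated and the paired-t independence assumption is violated. The
package reproduces the procedure as defined rather than substituting an
autocorrelation-corrected test; the null-calibration test treats the
resulting error control as smoke-level (pooled false-positive fraction
below 20% on null data), not as exact nominal control.

Degenerate paired-t inputs are handled explicitly: all-zero differences
give t = 0, p = 1; zero-variance differences with nonzero mean give
t = ±inf with p reported as 0.

## Synthetic data

The generator emulates what the analysis assumes about acceptor regions,
not any fitted corpus:

* **upstream** (bases −50..−8): i.i.d. draws with a pyrimidine fraction of
  0.7 by default (C and T split evenly, likewise A and G), emulating the
  polypyrimidine tract;
* **core** (bases −7..+6): per-position weights, defaulting to a
  pyrimidine-heavy run-in at −7..−3, A fixed at −2 and G at −1, and a mild
  G bias at +1 — low-entropy positions that reproduce the qualitative
  dispersion dip in the core;
* **downstream** (bases +7..+50): i.i.d. draws from a uniform base
  composition by default.

Each mode draws from its own deterministic sub-stream of the master seed,
so equal configurations across modes are exact null conditions.
`generate_null_pair` exposes the two-draw special case.

**Injections** enrich one dinucleotide in a site interval of one mode. The
target expectation is multiplier × the baseline expected occurrence count
in the interval; each window receives a Poisson-distributed number of
extra occurrences planted at non-overlapping uniform positions. Direct
planting was chosen over resampling-until-enriched because the latter has
unbounded runtime at realistic multipliers; the match to the target
expectation is approximate (planting can coincide with, create or destroy
chance occurrences), which the power checks tolerate by design. An
injection whose target exceeds the interval's occupancy capacity raises an
error. The canonical AG at −2/−1 is restored after injection and is never
disturbed.

What the generator does **not** emulate: positional dependence beyond the
three blocks, branch-point structure, dinucleotide or long-range correlations of
real genomic DNA, CpG depletion, isochore structure, or mode-specific
composition differences other than explicit injections. Passing tests
therefore demonstrate that the machinery detects planted differences at
realistic sample sizes and stays quiet on nulls — not that real splicing
modes differ.

**Toy annotation.** A deterministic two-contig genome (≤10 kb) plants one
acceptor of every mode and sub-mode, an ambiguous case, a minus-strand
case, one sub-100-bp intron and one pair of alternative acceptors 50 bp
apart, with canonical GT..AG at every intron boundary. The planted truth
table drives the end-to-end classification and filter tests.

## Problem sizes and defaults

Synthetic study conditions are 2,000 windows per mode; discrimination
checks (null specificity and 3× AG injection power, downstream sites
+5..+30) use 20 seeded repetitions and require 18/20 successes. A full
three-mode run — generation, counting, profiling, testing — takes well
under a second, and the whole acceptance recomputation about 15 s on one
CPU.

## Known limitations

* The majority-support reference model for sub-modes is a design choice;
  annotations whose principal isoform is not the best-supported pairing
  will misplace sub-modes (the real-data analogue is resolved by the
  source databases, not by this package).
* Acceptors appearing in overlapping genes on the same strand are not
  specially resolved; a site is a (chrom, strand, position) key.
* The paired-t autocorrelation caveat above applies to all region tests.
* Quantitative splicing levels (PSI), non-canonical splice pairs and
  donor-side analysis are out of scope.
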