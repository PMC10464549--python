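# Methods

`modsite` detects and quantifies RNA modifications on a single, deeply
covered reference (the targeted 18S-rRNA setting) from the basecalling
errors of nanopore direct RNA-seq.  Native modified bases perturb the
pore signal and hence the basecaller's output — mismatches, deletions and
insertions — not only at the modified nucleotide but across the 5-mer the
pore reads, for some marks out to offsets −3..+3.  The pipeline turns that
perturbation into per-position divergence scores between two conditions,
calls outlying positions, and calibrates score against modification
stoichiometry.

## Divergence score

For two conditions and a reference position, each error channel is reduced
to a count vector: called bases (A, C, G, T) for the mismatch channel, and
(event, no event) 2-vectors for deletions and insertions.  The score is
the multinomial log-likelihood-ratio statistic

G = 2 [ Σᵢ c₁ᵢ ln(c₁ᵢ/n₁) + Σᵢ c₂ᵢ ln(c₂ᵢ/n₂) − Σᵢ (c₁ᵢ+c₂ᵢ) ln((c₁ᵢ+c₂ᵢ)/(n₁+n₂)) ],

with 0·ln 0 := 0.  G is symmetric, non-negative, zero exactly at equal
proportions, and asymptotically χ²_{K−1} under the null, which gives a
closed-form reference for the background score distribution (checked in
the test suite at depth 1000 with overdispersion off).  This score is this
package's own divergence statistic: it shares the contract of published
two-condition error-profile callers (non-negative, zero under identity,
growing with divergence) but makes no claim of numeric equivalence to any
of them.

Replicates are handled two ways.  The headline per-position score pools
(sums) counts within each condition.  For outlier detection, every
(replicate i of condition 1) × (replicate j of condition 2) single-replicate
comparison is scored separately and the set of pairwise comparisons becomes
the feature space — 9 comparisons for 3 vs 3.  Zero-depth positions
propagate as missing and are excluded downstream, never imputed as zero.

## Feature sets

Four feature sets per comparison: `M` (site mismatch score, 1 column),
`MDI` (site mismatch/deletion/insertion, 3), `M_Con_DI` (mismatch over the
5-mer context centred on the site plus site deletion/insertion, 7), and
`MDI_Con` (all three channels over the context, 15).  Context features are
the per-offset scores concatenated rather than aggregated — this preserves
the neighbourhood signature of context-perturbing marks; a summed-context
variant is available behind `sum_context=True`.  Offsets falling outside
the reference contribute 0; positions with missing scores are dropped and
recorded in the matrix's `attrs`.

## Outlier calling

Candidates are positions whose pooled mismatch score is strictly above the
median over non-missing positions (the prefilter halves the candidate set
and removes the uninformative bulk).  Candidates are ranked by Local
Outlier Factor with Euclidean distance on the raw feature matrix —
features share a common likelihood-ratio scale, so no per-column scaling
is applied by default.  Neighbourhood size defaults to k = 20;
`ceil(contamination × n_candidates)` positions are flagged, contamination
defaulting to 0.001 and intended for targets with one or two expected
differential sites.  Ties on LOF break by higher pooled mismatch score,
then lower position.  The LOF computation is delegated to scikit-learn's
`LocalOutlierFactor`; the test suite holds it to an independent naive
O(n²) implementation of the textbook definition (k-distance, reachability
distance, local reachability density) to 1e-9, with coincident points
assigned LOF = 1.  LOF is a relative-density method: it is appropriate
when few differential sites are expected, not for globally divergent
comparisons such as native-vs-IVT profiling.

Flagged positions are labelled post hoc against a modification map:
`modified` (annotated site), `neighbour` (within ±2, the context width at
which a modification still perturbs basecalling), else `non-modified`.
To compare outlier strength across runs whose LOF scales differ, the
normalized LOF distance (lof(site) − median lof) / max lof is used.

## Stoichiometry calibration

Mixtures of reads from a fully modified pool (WT) and an unmodified pool
(KO/MUT) at known ratios emulate partial modification.  For each ratio r
and seed, round-half-away(r·n) WT reads and the complement of KO reads are
sampled without replacement (n = 1000 by default), piled up, and scored
against the unmodified comparator; the curve records mean ± sd of the site
score per ratio over 5 seeds at ratios {0, 0.5, 5, 10, 25, 50, 75, 100}%.
Level estimation inverts the isotonic-regression-monotonized mean curve by
piecewise-linear interpolation; plateaus created by the isotonic projection
invert to their ratio midpoint, and observations outside the curve clip to
0 or 1 (scores saturate at high stoichiometry).  The ±1 sd bands invert to
an interval.  A curve whose monotone span does not exceed twice its median
seed-to-seed sd is declared unidentifiable rather than inverted — this is
what a null (signal-free) calibration run produces.  On synthetic fixtures
(depth 1000, 40% mismatch signature) the inversion recovers true levels
0.25/0.50/0.75 within ±0.10 absolute.

Robustness to coverage is quantified by downsampling both conditions to a
grid of read counts (default 0.3k, 0.5k, 1k, 5k, 10k; several seeds each)
and tracking two measures per cell: the site score minus the median score,
and the normalized LOF distance.  The raw score distance grows with depth
(G scales with counts); the normalized LOF distance is approximately
scale-free.

## Benchmark machinery

Ranked per-position scores are evaluated against a modification map by
average precision (step-interpolated area under the precision-recall
curve; a trapezoidal estimator is available).  Because flanking positions
carry genuine signal, the default neighbour policy excludes the ±2 flanks
of true sites from the negatives; `negative` and `positive` policies are
provided since benchmark conventions differ.  Evaluation can be stratified
by class — pseudouridine (including the hypermodified m1acp3ψ),
2′-O-methylation (optionally by nucleobase), and other marks — with other
classes' sites excluded from a stratum's negatives, plus per-class score
summaries (n, median, quartiles).

## Synthetic data model

The generator emulates the targeted protocol: full-length, forward-strand
reads over one reference, uniform coverage, MAPQ 60, MD tags written.
Per read and position one categorical draw over six outcomes — match,
three mismatch bases, deletion, insertion — with the insertion category
calling the reference base plus one inserted nucleotide anchored
immediately to its left-flanking position, so base + deletion counts
always conserve depth.  (An earlier design treated insertions as an
independent per-read Bernoulli; the joint categorical is equivalent at the
small rates modelled and keeps every probability vector summing to 1.)

A modified site is a pair of categorical error vectors (unmodified,
modified) plus a context kernel w_o over offsets −3..+3 with w₀ = 1; at
stoichiometry s and offset o the effective vector is the linear mixture
(1 − s·w_o)·base + s·w_o·mod.  The default background profile is ~6%
mismatch spread over the three alternative bases, 2% deletion, 1%
insertion — typical direct RNA-seq basecalling error; the default modified
profile concentrates a 40% mismatch on one alternative base, as base
methylations do.  Replicate-to-replicate variability is
Dirichlet-multinomial: each replicate's per-position probabilities are a
Dirichlet draw centred on the effective vector with concentration κ
(default 2000, i.e. mild overdispersion of error rates; κ = ∞ disables it
and is used wherever a test checks an exact multinomial/χ² property).

Study-condition defaults mirror a targeted 18S run: reference length 1869
nt, 1000 reads per sample, three replicates per condition.  What the
generator does **not** model — and what passing tests therefore do not
establish for real data: signal-level artefacts and basecaller-specific
error modes, read truncation and coverage ramps, position-dependent
(sequence-context) background error, correlated errors within a read, and
quality scores.  The acceptance-style tests show the machinery recovers
signatures planted under this model, not that any particular chemistry is
detectable on a given flow cell.

## Numerical and design choices

- Coordinates are 0-based half-open internally (htslib convention),
  1-based inclusive in every report and in the modification map.
- `min_mapq` defaults to 1 ("poor alignments" is protocol-dependent);
  reverse-strand reads are excluded by default because the targeted
  adapter yields sense-strand reads and antisense molecules are a library
  artefact.  Both are configurable.
- Insertions are counted once per read regardless of length, anchored to
  the left flanking reference position; deletions count at every deleted
  reference position.
- Mixing rounds half away from zero, so 0.5% of 1000 reads is exactly 5.
- The contamination→count mapping is `ceil`, fixed and tested.
- Exact duplicate feature rows receive LOF = 1 (no density contrast).
- Downsampling and mixing derive child seeds from (seed, tags) via
  `numpy.random.SeedSequence`, so every cell of a grid is independently
  and reproducibly seeded.
- Sub-sampled suite sizes (e.g. 4000–10 000-read pools for calibration and
  downsampling fixtures, 20-seed recovery experiments) are the package's
  chosen study sizes; they keep every property measurable with comfortable
  statistical margins.

## Known limitations

- The divergence score is a stand-in with the right contract, not a
  reimplementation of any published caller's internal model; absolute
  score values are not comparable across tools.
- LOF calling assumes few differential sites; contamination must be chosen
  from prior expectation (automatic fitting exists in scikit-learn but is
  deliberately not the default).
- Calibration curves are site- and signature-specific; a curve built for
  one site does not transfer to another.
- Single-reference design: multi-reference BAMs are rejected unless the
  target reference is named.
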