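# Methods

## The measurement being modeled

A spotted antibody array quantifies proteins in click-captured conditioned
media. Each target antibody is printed in duplicate; a scanner reports the
median foreground and local background fluorescence per spot, plus a QC
flag (GenePix convention: negative = bad spot). Slides also carry printed
positive-control spots at a nominally fixed bright level and negative
controls near background. Samples come from a 2×2 design: genotype
(MetRS(L274G)-expressing vs unmodified control cells) × condition (baseline
vs stimulated co-culture). Only MetRS-expressing cells incorporate the
azide-bearing methionine surrogate, so only their secreted proteins should
be captured; control-genotype samples measure what sticks anyway.

## Processing stages and their assumptions

1. **Background subtraction** — `max(fg − bg, floor)` per spot, floor 0 by
   default. Clamping encodes that signals are physical abundances; an exact
   zero later makes a fold change incalculable rather than negative or
   infinite.
2. **Duplicate collapse** — arithmetic mean over valid (flag ≥ 0) duplicate
   spots. Cells with no valid spot are missing with reason
   `no_valid_spots`; a duplicate CV (sd/mean, ddof 1) is retained for QC
   only. The mean, not the median, is used: with two duplicates they
   coincide in breakdown behavior anyway.
3. **Positive-control normalization** — each array is scaled so its
   positive-control summary (mean by default, median selectable) equals the
   grand mean across arrays. Equalizing to the grand mean rather than a kit
   reference only changes a global scalar, which cancels in fold changes.
4. **Loading normalization** — each array is scaled by
   mean(concentration)/concentration. Division by loading is the only
   physically sensible direction: more loaded protein means more signal for
   equal secretion. This factor deliberately does **not** rescale the
   control-spot values: printed controls do not depend on how much sample
   was loaded. That choice also makes the two normalizations commute
   exactly (both are per-array scalars on the target signals).
5. **Non-specific exclusion** — default `per_control_array_rank` mode: on
   each control-genotype array with P valid probes, the cutoff is the
   ceil(P/3)-th largest value; every probe at or above it (ties inclusive)
   is excluded from all groups. A probe excluded on *any* control array is
   excluded globally. The alternative `pooled_tertile` mode pools all valid
   values of all arrays and uses the empirical 2/3 quantile as the cutoff.
   Both readings of "top tertile of expression amongst all groups" are
   legitimate; the per-array rank is the default because a tertile most
   naturally ranks proteins within one expression profile. Note the rank
   rule always excludes one third of the probes per control array — that is
   the intended cost of the filter, not an error.
6. **Fold change and calls** — per-condition signal is the mean of valid
   values over MetRS-genotype replicate arrays; FC = stimulated/baseline,
   incalculable if the baseline is ≤ 0 or either side is missing. Calls use
   the manufacturer's bounds FC > 1.5 (up) / FC < 0.65 (down), strict at
   the boundary. No replicate-level statistical test or multiple-testing
   correction is applied — the calling rule is a fold-change threshold by
   design. An optional pseudocount (default off) is available for
   exploratory work with zero baselines.
7. **Reporting** — up calls sorted by descending FC, truncated to the top
   10; down calls sorted ascending, never truncated; ties break
   lexicographically by probe id; ranks are 1..n within each report.

## Synthetic data generator

`SimConfig` defaults describe the emulated study: 507 duplicate-spotted
targets, 6 positive and 4 negative controls, one array per 2×2 design cell.
Per probe, baseline abundance is LogNormal(µ=7, σ=1) in arbitrary
fluorescence units; spot noise is multiplicative LogNormal with σ = 0.1
(10% CV, typical for fluorescence arrays); per-array scale drift is
LogNormal with σ = 0.3; loading concentrations are drawn uniformly over a
2-fold range (1–2 µg/µL); background is Normal(100, 20) truncated at zero,
drawn independently for the foreground additive term and the recorded
background median. `study_config()` plants 15 upregulations at FC 3, 10
downregulations at FC 0.3 and 30 non-specific binders.

Control-genotype arrays emit a low residual level per probe
(LogNormal(µ−3, σ): unlabeled material that survives capture), except
planted non-specific binders, whose level is placed strictly above the
largest residual draw — this *guarantees* top-tertile membership when spot
noise is off, making exclusion recovery exact rather than probabilistic.
Loading concentration scales only sample-derived (target) spots, not
printed controls, so the two normalization factors are separately
identifiable from simulated data.

Randomness: one `SeedSequence` per dataset, with one spawned child stream
for probe-level truth and one per array, so individual arrays reproduce
under design edits. Outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: spatial artifacts and print-tip
effects, saturation, carrier effects in capture chemistry, probe-specific
affinity differences, or correlated secretion programs. Passing recovery
tests therefore show the *pipeline logic* is correct under the stated noise
model, not that real arrays meet that model.

## Taggability annotator

Internal methionine = 'M' at 1-based position ≥ 2 after stripping
whitespace and one terminal stop; a protein is taggable iff it has at least
one. The initiator Met is always discounted, a conservative reading of
"frequently cleaved" N-terminal processing. Ambiguity codes (X, U, B, Z)
contribute nothing. Applying the annotator to a downloaded reference
proteome is supported via the `taggability` CLI command; results then
depend on the proteome release used.

The simulated-FASTA check uses the closed form: with per-position Met
probability r and length L (initiator forced), the taggable fraction is
1 − (1 − r)^(L−1); observed fractions are compared within three standard
errors.

## Numerical choices and degenerate inputs

- Exclusion cutoffs use exact sorting (rank mode) or `numpy.quantile` with
  linear interpolation (pooled mode); ties at the cutoff are inclusive.
- Normalization factors must be strictly positive and finite; an array with
  a non-positive positive-control summary raises a degenerate-array error
  naming the array.
- Validation aggregates all detected design/spot mismatches into one report
  instead of failing on the first.
- Report files serialize floats with 6 significant digits; all internal
  computation is double precision.
- Problem sizes in the test suite and acceptance script (15–60 targets for
  exactness checks, the full 507-target design for recovery, 2000 simulated
  proteins for taggability) were chosen so each check exercises the
  relevant regime while the whole suite stays fast.

## Known limitations

- The exclusion rule's per-array variant always removes a third of probes
  per control array; sensitivity figures are therefore conditional on
  surviving exclusion.
- Fold changes pool replicates by mean without dispersion estimates; with
  one replicate per cell (the default design) no within-group variance
  exists to exploit.
- Single-channel arrays only; no spatial correction or image-level
  processing.
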