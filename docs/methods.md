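# Methods

## Problem and model

In a sex-separated sequencing project every read's sex of origin is
known from its library prefix, so the assembler's read-tracking
records determine, per scaffold, how many reads came from male vs
female DNA.  Writing `p` for the genome-wide male-read proportion and
`n` for a scaffold's read count, the number of male reads in an
autosome-like scaffold is `Binomial(n, p)` under the assumption that
reads land on scaffolds independently of sex.  Three consequences
drive the pipeline:

1. **False-positive probability.** An autosome-like scaffold is
   all-male by chance with probability `p^n`.  This is a per-scaffold
   bound, with no multiple-testing correction; the summary instead
   reports the expected number of chance all-male scaffolds,
   `Σ p^n` over retained scaffolds, so the genome-wide burden stays
   visible.
2. **Minimum-read threshold.** The smallest `n` with `p^n ≤ α` is
   `⌈ln α / ln p⌉` (implemented with an integer fix-up so that
   `p^n ≤ α < p^(n−1)` holds exactly despite floating point).  At
   `p = 0.585`, `α = 1/200` the model gives `n = 10`, while the
   conventional filter in this field excludes scaffolds with 10 reads
   *or fewer* (`min_reads = 11`).  The default reproduces the
   published filter; the pipeline logs a warning whenever the
   configured and model-derived values disagree rather than silently
   picking one.
3. **Class expectations.** With copy numbers per (male, female)
   individual of 2:2 (autosome), 1:2 (X) and 1:0 (Y), and per-copy
   sampling-rate ratio `r = p/(1−p)`, the expected male fraction is
   `m·r/(m·r+f)`: `r/(r+1)` for autosomes, `r/(r+2)` for X, 1 for Y.

Classification is exhaustive and mutually exclusive, in precedence
order: contaminant → no reads → low-read exclusion → Y candidate
(all-male, with `p^n` attached) → X band → autosome-like.  The X band
(default half-width 0.05 around `r/(r+2)`) is a weak flag only:
autosomal sampling noise overlaps it heavily, so it must not be read
as a confident X call.  When the global read set is degenerate
(`p ∈ {0, 1}`) the band is undefined and skipped.

`p` is estimated from all retained reads.  Y and X content perturbs
the genome-wide totals only marginally (the Y candidates cover a
fraction of a percent of such assemblies), and the estimate matches
how the headline 58.5 % figure is computed in practice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1/200 | per-scaffold false-positive bound |
| `min_reads` | 11 | scaffolds with fewer total reads are excluded (published filter: "10 reads or less") |
| `x_band_halfwidth` | 0.05 | male-fraction half-width of the X flag around `r/(r+2)` |
| contaminant identity cutoff | 95 % (strict >) | bacterial/TE screen on candidates; the genome-level bacterial screen uses 100 % inclusive |
| per-database filters | protein/TE: e ≤ 1e-6; transcripts/annotated genes: e ≤ 1e-8 and 100 % identity | mirrors the search settings these tables come from |
| `min_databases` | 3 | distinct gene-evidence databases required to select a candidate for linkage testing |

## Evidence tiers

Per candidate scaffold, filtered non-contaminant hits are ranked
(lowest = strongest): (1) conserved known gene in RefSeq or NR,
(2) conserved hypothetical gene in RefSeq, (3) annotated gene of the
species itself, (4) unconserved hypothetical gene in RefSeq or NR,
(5) discarded annotation (GeneID trash).  Transcript support is not a
tier but a separate boolean treated as the strongest evidence in the
selection ordering.  Design choices made where the procedure is
genuinely open:

- **Conservation labels are inputs, not inferences.** What counts as
  "conserved" is not derivable from a hit table, so labels arrive as a
  `subject_id → label` TSV and a missing label for a RefSeq/NR subject
  is a hard metadata error.
- A conserved hypothetical in **NR** contributes no rank of its own
  (only the RefSeq variant is ranked), though the NR hit still counts
  toward `databases_hit`.
- Only the five gene-evidence databases count toward the ≥3-database
  selection rule; bacterial/TE screens never do.
- All orderings break ties lexicographically by scaffold id, so output
  is deterministic.
- The contaminant identity boundary is strict (`> 95 %`); the
  genome-level bacterial screen is exact-100 % and exposed as
  `identity_cutoff=100, inclusive=True`.  Both are configurable
  because reasonable projects differ here.

## Synthetic data: what it emulates and what it does not

`simulate_counts` draws, per scaffold: length log-uniform on
`(500, 100 000)` bp (real assemblies of this kind are heavily skewed
toward short scaffolds); total reads
`Poisson(length × reads_per_bp × w)` with copy weight
`w = (m·r + f)/2` normalised so `reads_per_bp` (default 0.01, i.e. a
few million reads over a few hundred Mb) is the density of one female
autosomal copy-pair; male reads `Binomial(n, m·r/(m·r+f))`; then each
read's sex label flips independently with the contamination rate.
Defaults: 900 autosomal, 60 X and 40 Y scaffolds; male effort 0.585;
no contamination.  `fixed_n_total` bypasses the Poisson draw for
calibration studies at a fixed read count.  `emit_read_map` writes a
read map whose recount reproduces the drawn counts exactly, which is
what makes the parser and counter testable end-to-end.

Not modelled: sequences, read lengths, GC or mappability bias,
chimeric/mis-assembled scaffolds, and homology hits (evidence-module
fixtures are hand-written tables).  A green recovery test therefore
establishes that counting, the binomial model and classification are
internally correct and calibrated — not that a real assembly is free
of assembly artefacts, which are a known source of false positives in
this method.

Closed forms used as oracles in the tests: among autosomal scaffolds
at fixed `n`, the all-male fraction converges to `p^n`; a Y scaffold
of `n` reads survives label-flip contamination `ε` with probability
`(1−ε)^n`; and the expected false-positive rate `mean(p^n)` falls as
coverage rises.

## Numerical and formatting choices

- Male percentages print to one decimal; a zero-read scaffold's
  fraction is undefined and serialises as `NA` (never 0/0).
- Histogram bins floor to integer percent, with bin 100 reserved for
  exactly-all-male scaffolds so 99.6 % cannot round into the Y bin.
- `genome_fraction` reports percent to one decimal over the retained
  (post-filter) assembly by default.
- Duplicate `(scaffold, read)` pairs collapse; a read placed on `k`
  scaffolds counts once in each, matching read-tracking semantics.
- Unknown library prefixes are a hard error by default; an opt-in
  skip-and-count mode exists because silent misclassification would
  corrupt the male fraction.
- All simulation randomness flows through one `numpy` Generator per
  seed; identical spec + seed gives byte-identical outputs.

## Known limitations

- X-linkage is flagged, never called: the method cannot separate
  X scaffolds from autosomal sampling noise at realistic depths.
- The false-positive model assumes reads are exchangeable across
  scaffolds; repetitive or collapsed regions violate this in real
  assemblies.
- The pipeline consumes search output; it does not run the homology
  searches, repeat-masking or gene annotation itself.
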