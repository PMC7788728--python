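# Methods

## Scope and model

`virhost` decides, from read-abundance evidence alone, whether a virus
assembled from host RNA-seq is plausibly replicating in that host. The
underlying model is deliberately simple: if a virus is an active resident,
its transcripts should be (a) on the abundance scale of the host's own
constitutive genes, (b) consistently above a detection floor, and it should
(c) sit among insect viruses phylogenetically and (d) have been recovered
as a complete coding sequence. Criteria (c) and (d) are upstream judgments
supplied as boolean metadata — this package does no phylogenetics, BLAST,
or assembly.

Counts, not percentages, are the canonical on-disk input; percentages are
always derived. A percentage-mode loader exists because published abundance
tables print percentages without the underlying counts, and the whole
downstream pipeline is well defined on percentages alone. In that mode a
whole-genome "Total" row may be carried as printed; it can disagree with
the sum of printed segment cells by up to 0.001 because each printed cell
is rounded independently to three decimals.

## Abundance and fold-changes

Abundance of feature *f* in library *ℓ* is `100 · n(f,ℓ) / N(ℓ)` with
*N(ℓ)* the library's total read count (post-trimming), not the non-host
subset — the total is the denominator a sequencing depth argument actually
needs, and it is the published convention this pipeline follows. A
`denominator` switch is reserved in the config for the non-host variant.

Fold-changes are ratios of two percentages and are kept at full precision
internally. Presentation rounding (`format_fold`) follows the conventions
of the source tables: nearest integer at ≥ 10, three decimals below 1,
truncation to two decimals in between. The truncation rule exists because
published whole-body fold maxima are printed truncated (2.698 → 2.69);
this is a display decision only.

Normalized segment shares divide each segment's abundance by the summed
abundance of all segments of the same virus in the same library; libraries
where the virus is undetected are omitted rather than reported as NaN, so
share tables never contain placeholder rows.

## Rank statistics

The group comparison is the Kruskal–Wallis test on midranks with the
standard tie correction, p-value from the χ² approximation on k−1 degrees
of freedom (no exact permutation option). The degenerate all-equal input is
defined as H = 0, p = 1 rather than an error, because detection-gated
virus groups can legitimately be tiny.

The post hoc is the Conover rank-LSD procedure: mean ranks compared against
`t(1−α/2, N−k) · sqrt(S² · (N−1−H)/(N−k) · (1/nᵢ + 1/nⱼ))` with S² the
variance of all pooled midranks, and **no multiplicity adjustment**
(Fisher's unprotected LSD) — this reproduces the behaviour of the widely
used agronomy-statistics implementation of the same procedure. The
deflation factor is clamped at zero in the extreme-tie corner case where
the corrected H exceeds N−1.

Detection gating: a virus's group uses only the libraries where the virus
is detected, and the housekeeping groups are restricted to those same
libraries, so all groups are sampled under identical conditions. The
default natural-log transform before testing is acknowledged to be a no-op
for rank statistics (a property test asserts this); it is retained for
parity with common practice and any future parametric extension.

Compact letters label the maximal cliques of the non-significance graph
(found via networkx), ordered so the clique containing the highest mean
rank gets "a". Maximal cliques guarantee the defining invariant exactly:
two groups share a letter iff their pairwise difference is non-significant.

## Classification rule

Criterion (i) is true unless the virus is significantly below *all three*
housekeeping genes; (ii) compares the **median** whole-virus abundance over
detected libraries against the threshold (default 0.01%, strict
inequality) — the median was chosen because the source procedure states no
aggregation, and the median is insensitive to duplicated libraries and
single outlier libraries; an `any`-library mode is available. The default
call rule makes criterion (iv) mandatory plus ≥ 2 of the rest. The literal
"≥ 2 of 4" rule is provided but not default: on the bundled data it calls
the partial densovirus hosted (with only two detection libraries it cannot
be statistically separated from the two minor housekeeping genes, and it
clusters with insect densoviruses), whereas the mandatory-CDS rule is the
minimal rule reproducing all five published calls. The rule used is echoed
in every output row.

## Compositional bias

Codon usage is raw 64-codon counts (stop codons included, no RSCU
normalization — an `rsu`-style option was considered and rejected as the
counting tool this mirrors defaults to raw counts; scaling can be applied
at the PCA step instead). Dinucleotide odds ratios use overlapping windows
on the linear sequence (L−1 windows, no wrap-around) with mononucleotide
frequencies from the full sequence; ρ is 0 by convention when a
mononucleotide frequency vanishes. PCA centers columns without
unit-variance scaling by default; components come from a full SVD and
signs are fixed by forcing each component's largest-magnitude loading
positive, making score files reproducible byte-for-byte.

## Terminal motifs

Motif scanning anchors the 5′ consensus at position 1 and the 3′ consensus
at the last |motif| bases (offset-0 anchoring; a windowed scan for ragged
draft ends is intentionally out of the default path). Matching is Hamming
distance with U ≡ T; mismatch offsets are 1-based within the motif. Two 3′
presets ship: `canonical` (ACUUUGUGU, the exact reverse complement of the
5′ consensus — a perfect panhandle) and `variant_a` (ACUUUGAGU, a one-base
variant seen in some assemblies). Published sources print both; neither is
silently preferred and the preset name is echoed in output. Coordinates in
`extract_cds` are 1-based inclusive (GenBank convention), with
minus-strand extraction returning the reverse complement for ambisense
ORFs.

## Synthetic data

The generators define the test conditions; they are not tuned per test.

* **Count tables.** Exact mode sets `count = round(target% · N / 100)`, so
  recomputed abundances match targets within `100/(2N)` percentage points
  (quantization only); multinomial mode draws seeded counts at the target
  probabilities for stochastic-robustness checks. The bundled preset
  encodes every printed cell of the fire-ant abundance table (including
  the not-detected dashes) plus the per-virus phylogeny/completeness
  flags. Per-library totals were not published; the preset fixes realistic
  totals of ~27–45 million reads per library, which makes quantization
  error ≈ 1e−6 percentage points — far below the 3-decimal precision of
  the printed cells.
* **CDS sets.** Sequences are drawn codon-by-codon from per-group weight
  vectors (stop codons weighted 0 inside ORFs), with an optional
  dinucleotide tilt applied by rejection at codon junctions. The bundled
  three-group regime (plant-like / non-plant / focal, 12+12+4 sequences of
  1998 nt) favours disjoint codon sets at a 3:0.05 weight ratio — an
  effect size chosen to mimic the clearly separated group structure the
  compositional analysis is meant to detect, not a marginal case.
* **Segmented genomes.** Four segments with lengths in the range of real
  tenui-like segments (8.9/3.6/2.3/1.9 kb), termini equal to the consensus
  motifs with an exactly specified number of planted substitutions per
  end. Termini depend only on the requested mismatch plan; the interior
  RNG seed never touches them, so scanner round-trips are exact.

Synthetic data emulates abundance structure, compositional separation and
terminal conservation. It does **not** emulate mapping ambiguity, uneven
coverage, assembly chimeras, or real codon-usage distributions of any
taxon; passing tests demonstrate the statistics and scanners are correct,
not that the four-criterion rule is biologically optimal.

## Numerical choices and limitations

* Ties are handled by midranks everywhere; no jittering.
* Abundance equality at the detection threshold fails criterion (ii)
  (strict inequality, matching "higher than").
* The χ² approximation for H is poor below ~5 observations per group; the
  smallest bundled comparisons (n = 2–3 per group) inherit this caveat
  from the source procedure, which used the same approximation.
* Host calls are only as good as the metadata flags; the pipeline cannot
  rescue a mis-stated completeness or phylogeny flag.
* No read mapping, trimming, assembly, ORF prediction or phylogenetics is
  performed; sequence inputs are assumed to be correct assemblies.

## Problem sizes

The default test suite and the acceptance script run the full pipeline on
the 13-library preset, 200-instance random oracle comparisons for the rank
statistics, 28 synthetic CDS of ~2 kb for the PCA separation check, a
100 kb iid sequence for odds-ratio convergence, and a 4-segment ~17 kb
synthetic genome for motif recovery — sizes at which every quantity checked
is stable to well within the asserted tolerances.
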