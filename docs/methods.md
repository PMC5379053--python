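# Methods

This note documents the models, conventions and numerical choices behind
`tecrm`, and what the synthetic-data generator does and does not emulate.

## Coordinates and interval semantics

All coordinates are 0-based, half-open (BED native), matching the
`intersectBed`/`closestBed` semantics the analysis mirrors. The center of an
even-width interval is `floor((start+end)/2)`. rmsk-style annotation tables
use `genoStart` as 0-based and `milliDiv` as divergence × 1000.

## Site clustering

A TF binding site is anchored at a single reference point: the peak center
for ChIP-seq peaks, the motif start for motif hits. Sites are chained per
chromosome by single linkage on sorted reference points; consecutive points
at distance ≤ 100 bp (boundary-inclusive — the inclusive reading is a
choice, documented here, since either reading is defensible) join one
cluster. A cluster's TF count is the number of *distinct* TF names, so two
peaks of the same factor count once. Peak extension to a fixed width
(default 200 bp) re-centers on the reference point and clips at the
chromosome start without re-centering, so near-edge intervals may be
shorter than requested.

A TE is "bound by *i* TFs" when a cluster with `n_tfs = i` overlaps it by
at least 1 bp; overlap is evaluated on the cluster span (smallest interval
containing all reference points). A TE hit by several clusters takes the
maximum `n_tfs`: "bound by two or more TFs" is a per-element property and
the maximum is its conservative monotone summary.

## Enrichment statistic

For subfamily *j* and TF count *i* over *N* annotated TE copies, with
*N_j* copies in the subfamily, *K_i* copies bound by *i* TFs genome-wide
and *k* of those in the subfamily, the 2×2 table is
(a, b, c, d) = (k, N_j−k, K_i−k, N−N_j−K_i+k) and

    LOR = log2( a·d / (b·c) ).

The base-2 convention is pinned by the equivalence LOR 6 ↔ 64-fold. When
any cell is zero, 0.5 is added to every cell (Haldane–Anscombe) to keep the
LOR finite; this is the only smoothing applied. Significance is the
hypergeometric upper tail P(X ≥ k) with population *N*, successes *K_i*,
draws *N_j* (scipy's survival function, which is computed stably; an
exhaustive-enumeration cross-check for all tables with N ≤ 12 is part of
the test suite). TF counts are binned exactly at i = 1..5 plus a ">=2"
aggregate. Rows need k ≥ 10 bound elements to be eligible for flagging;
flagging requires LOR ≥ 4.5 (configurable; 6 marks the strong tier) and
P < 0.001. No multiple-testing correction is applied to the flagging
decision; a Benjamini–Hochberg FDR column is emitted as supplementary
output only.

The hypergeometric universe is all annotated TE copies. An alternative
universe (genomic cluster regions) would change *N* and *K_i*; the TE-copy
universe matches the odds-ratio framing on TEs and is used throughout.

## Motif scanning

PWMs are 4×L probability matrices with a background distribution (uniform
by default). The log-odds matrix adds a pseudocount of 0.01 to numerator
and denominator before the log so zero-probability bases score finitely;
information content IC_l = 2 + Σ_b p_{b,l} log2 p_{b,l} uses the raw
probabilities, because the ranking should reflect the matrix as given.

Score significance is exact, not sampled: per-column score distributions
are discretized to a 0.01-bit grid and convolved, giving the full null
distribution of the window score under the background model. The scanner
scores windows on the same grid, so scanner and distribution agree
identically (verified against brute-force enumeration over all 4^L
sequences for L ≤ 6). The hit threshold is the smallest attainable score
with tail probability ≤ p (default 0.001); a PWM equal to its background
has no such score and yields an explicit +∞ sentinel. Both strands are
scanned; windows containing N are skipped. The "consensus match" filter
requires the window to equal the consensus base wherever one base has
probability > 0.5 — the criterion is not standardized elsewhere, so the
majority-base reading is adopted and configurable in effect via the flag.

The EKS module is called present in an element when Esrrb, Klf4 and Sox2
each have at least one hit within the 5′ (upstream) fraction of the element
(default one half), measured strand-aware from the element's annotated 5′
end. The one-half default quantifies "upstream part", which is otherwise
unspecified; it is a parameter.

## Mutagenesis design

Up to four positions per motif (the ones with highest IC; ties broken
leftmost) are mutated to the least probable base of their column (ties
broken alphabetically A<C<G<T; if the site already carries that base, the
next-least-probable base is used). All tie-breaks are total, so designs are
deterministic. Verification rescans the mutated sequence against the whole
PWM library on both strands: the design fails if any hit overlapping a
mutated position appears that was absent at the same (offset, strand, TF)
in the original. This in-house rescan replaces an external motif–motif
comparison tool; it tests the property actually needed — that no new
binding site was created. On the bundled motifs, the four-position knockout
always drops the site below the P < 0.001 threshold; this is asserted for
the bundled set but is not a theorem for arbitrary PWMs.

## Evolutionary dating

Divergence *p* of a copy to its subfamily consensus is corrected to
substitutions per site with the Jukes–Cantor model, K = −¾ ln(1 − 4p/3),
undefined at p ≥ 0.75. LTR pairs are formed greedily per
chromosome/subfamily/strand: adjacent copies with inner gap ≤ 7 kb are
candidates, taken smallest-gap-first with each copy used at most once, so
an ambiguous triple pairs its closest two. Intactness of the provirus is
approximated by the span/subfamily/strand criteria; internal ORF checks are
out of scope. Pairwise LTR divergence *d* comes from a global alignment
(match +1, mismatch −1, gap open −4, gap extend −1) as mismatches over
non-gap columns; a gapped alignment of unrelated sequences lands near its
chance level (≈0.4), so divergences above 0.3 trigger an orientation
warning. Insertion time is T = d/(2r): both LTR lineages accrue divergence
independently after insertion. The raw p-distance feeds T by default,
matching the low-divergence regime (2rT ≤ 0.05) where the Jukes–Cantor
correction is below 1%; a correction flag exists for older elements. Rate
bounds default to the mouse–rat 1.2% and 0.05% per site per Myr; T at the
faster rate is the lower bound.

## Metaprofiles

Coverage is averaged in 50-bp bins over 3-kb windows (1.5-kb flanks)
centered on the TE midpoint, scaled to reads per million by the track's
library size. "Normalized read density" admits several readings; RPM is
the minimal standard one and is configurable (ratio tracks such as
methylation are averaged unscaled). Profiles are unstranded. Windows
truncated by chromosome ends contribute only their covered bins; truncated
bins are excluded from category means. Category profiles are elementwise
means over TEs with 0, 1 and ≥2 bound TFs; only means are reported.

## Reporter quantification

Luciferase: per-record firefly/renilla ratios are averaged over technical
replicates within an experiment, then over experiments; fold change divides
by the empty vector processed identically; the s.d. is across
experiment-level values. Records with renilla ≤ 0 are dropped with a
warning. Fold change > 2 classifies an enhancer, > 10 a strong enhancer
(strict inequalities).

CRE-seq: per-barcode expression is (cDNA + 0.5)/(DNA + 0.5); barcodes with
DNA < 10 reads are excluded. The pseudocount guards division by zero and
the DNA floor suppresses low-depth noise; neither value is canonical and
both are parameters. Construct expression averages retained barcode ratios
across replicates and is normalized by the mean basal-construct expression
(mean, not median — a choice). Mutant effects divide mutant by wild-type
fold change, with a Welch t-test across replicate-level expression values;
Welch is preferred over the pooled-variance test because equal variances
are not guaranteed.

qPCR: ΔCt = Ct_target − Ct_ref within condition, ΔΔCt = ΔCt_mut − ΔCt_wt,
relative expression = 2^(−ΔΔCt). The negative exponent is required for the
statistic to report a reduction as a value < 1 (the "2^ΔΔCt" label seen in
some protocols omits the sign); identity inputs give exactly 1.

## Synthetic-data generator

The generator defines the package's study conditions:

- **Genome**: uniform random A/C/G/T background, default 5 Mb, one
  chromosome. TE copies are the subfamily consensus with i.i.d.
  substitutions (each hit site replaced by one of the three alternative
  bases uniformly — the Jukes–Cantor generative model, matching the dating
  model downstream). Placement is uniform, non-overlapping, by rejection
  sampling bounded at 1,000 retries per element; exhaustion raises a
  capacity error rather than silently crowding. Default decoy substitution
  rate 0.05 (young-subfamily territory), 6 subfamilies × 100 copies of a
  300-bp consensus.
- **Planted modules**: half the copies of one subfamily carry one exact
  best-scoring site per module PWM (Esrrb, Klf4, Sox2), in order, spaced
  5 bp apart starting 10 bp from the element's 5′ end — inside the
  upstream half, and close enough that peak centers chain at the 100-bp
  gap. Minus-strand copies carry the reverse-complemented module at
  mirrored coordinates. Realized divergence (recorded in milliDiv) is
  measured after planting.
- **Peaks**: one 200-bp peak centered on each planted motif plus uniform
  background peaks at 10 peaks/Mb/TF by default — sparse enough that decoy
  subfamilies stay far below the 10-element filter, dense enough that the
  null is not trivially empty.
- **LTR pairs**: each pair descends from one random ancestral sequence
  (default 300 bp); both copies mutate independently with per-site
  probability r·T, so pairwise divergence ≈ 2rT at the promised
  low-divergence regime (2rT ≤ 0.05; the binomial oracle in the tests is
  valid only there). The two LTRs are separated by a 6.5-kb internal span,
  inside the 7-kb pairing window. Defaults T = 13 Myr, r = 5×10⁻⁴ —
  mid-range of the 12–14 Myr insertion-time band at the slow rate bound.
- **Coverage**: per-base Poisson at background depth 20, mean multiplied by
  5 over module carriers; library size is the total generated
  read-equivalents, used for RPM normalization downstream.
- **Reporter**: DNA counts Poisson at depth 1,000 per barcode; cDNA counts
  Poisson at depth × basal × fold × lognormal(σ = 0.1) noise; 8 barcodes ×
  3 replicates per construct; luciferase pairs drawn so the expected
  ratio-over-empty equals the planted fold. σ = 0.1 (≈10% CV) is a
  realistic well-to-well noise level for a transfection assay.

All randomness flows through one `numpy` generator seeded from the config;
identical (config, seed) reproduce every output byte-identically, and the
run manifest (seed, config hash, version) suffices to reproduce a run.

What the generator does **not** emulate: indels and nested insertions (so
alignment-based divergence is exercised only lightly), read-level
artifacts (no FASTQ, no mapping bias), CpG-aware methylation, correlated
ChIP-seq background, barcode dropout, or batch effects. Passing tests
therefore demonstrate correctness of the statistics and recovery under the
stated generative model, not robustness to every artifact of real data.

## Problem sizes

The bundled experiments use a 5-Mb genome with 600 TE copies, 100 LTR
pairs, and 20 simulation seeds per recovery experiment — sizes at which
the planted effects are identifiable with comfortable margins while a full
suite run stays interactive on a single CPU.

## Known limitations

- The enrichment universe is TE copies; region-level universes are not
  implemented.
- `pair_ltrs` operates on annotation intervals only; it will pair any
  same-subfamily neighbors within the span window, including coincidental
  ones in dense annotations.
- The exact-score scanner discretizes at 0.01 bits; scores and p-values
  are exact on that grid, and thresholds can differ from a continuous-score
  implementation by up to L/2 bins.
- Metaprofiles report means only; no confidence bands are drawn.
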