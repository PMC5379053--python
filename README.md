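# tecrm — transposable-element cis-regulatory module analysis

`tecrm` is a Python toolkit for studying how transposable elements (TEs)
spread *cis*-regulatory modules — clusters of transcription-factor (TF)
binding sites — through a genome. The motivating system is mouse embryonic
stem cells, where copies of young ERVK/LTR subfamilies (RLTR9, RLTR13
families) carry a module of Esrrb, Klf4 and Sox2 (EKS) binding motifs and
act as ESC-specific enhancers. The package covers the full analysis chain:

1. **Site clustering and TE overlap** — TF binding sites (ChIP-seq peak
   centers or motif starts) are chained when their reference points are
   within 100 bp; a TE overlapping a cluster of *i* distinct TFs is "bound
   by *i* TFs".
2. **Subfamily enrichment** — for subfamily *j* and TF count *i*, the
   over-representation of *i*-TF TEs is a base-2 log odds ratio over the
   2×2 table {subfamily *j* vs other TEs} × {bound by *i* TFs vs not}:
   LOR = log₂(ad/bc), with a hypergeometric upper-tail P value and a
   ≥10-element reporting filter. LOR ≥ 6 means at least 64-fold enrichment.
3. **Motif scanning** — patser-style PWM scanning: the null distribution of
   the log-odds score under the background base composition is computed
   exactly by per-position convolution, and hits are windows with tail
   probability < 0.001 that match the motif consensus.
4. **Insertion dating** — per-copy divergence *p* to the subfamily consensus
   is corrected to substitutions per site with the Jukes–Cantor model,
   K = −¾ ln(1 − 4p/3); paired LTRs of one proviral insertion (≤ 7 kb
   apart) diverge independently after insertion, so T = d/(2r) with the
   mouse–rat rate bounds r ∈ {1.2%, 0.05%} per site per Myr.
5. **Epigenetic metaprofiles** — reads-per-million coverage in 50-bp bins
   over 3-kb windows centered on TEs, averaged by TF-occupancy category
   (0, 1, ≥2 TFs).
6. **Reporter quantification** — luciferase fold change (firefly/renilla,
   normalized to the empty vector; enhancer if > 2, strong if > 10),
   CRE-seq/MPRA expression (cDNA/DNA barcode count ratios normalized to
   basal constructs, 8 barcodes × 3 replicates), mutant-vs-wild-type
   effects with Welch t-tests, and qPCR 2^(−ΔΔCt) quantification.
7. **Mutagenesis design** — up to four point mutations per motif at the
   highest-information-content positions, each replaced by the least
   informative base, with a rescan check that no new binding site was
   created.
8. **Synthetic data** — a generator producing a toy genome with TE copies
   mutated from a consensus, planted EKS modules, diverged LTR pairs,
   enriched coverage and barcode counts with known fold changes, so every
   stage is testable against ground truth.

## Worked example

Run the whole pipeline on the default synthetic study conditions (5-Mb
genome, 6 subfamilies × 100 copies, EKS modules planted in half the copies
of one subfamily, 100 LTR pairs inserted 13 Myr ago at 5×10⁻⁴
substitutions/site/Myr):

```sh
tecrm run --seed 11 --out demo/
```

which prints

```
simulate: 800 annotation rows
cluster: 61 of 800 TEs bound
enrich: 2 flagged rows
age: 100 LTR pairs, median T at true rate 10.0 Myr
profile: 180 profile rows
reporter: 4 constructs quantified
```

The flagged rows of `demo/enrichment.tsv` are the planted subfamily, at the
exact-TF-count bin and at the ≥2 aggregate:

```
subfamily i_label  k  N_j  K_i   N       lor       pvalue
  SimLTR1       3 50  100   50 800 10.452241 1.027069e-51
  SimLTR1     >=2 50  100   51 800  9.449149 4.895694e-50
```

Reading: of 800 annotated TE copies, 50 are bound by exactly three TFs, and
all 50 belong to SimLTR1 (the subfamily carrying the planted EKS modules) —
a log odds ratio of 10.5, i.e. ~1400-fold enrichment, at P ≈ 10⁻⁵¹. No
decoy subfamily is flagged. `demo/reporter_potential.tsv` recovers the
planted reporter fold changes (wild-type constructs planted at 10×, mutants
at 3×):

```
construct  fold_change       sd           class
     mut1     3.020252 0.054221        enhancer
     mut3     3.015452 0.050565        enhancer
      wt1    10.246188 0.289389 strong enhancer
      wt2    10.190938 0.133988 strong enhancer
```

The single-run median insertion time (10 Myr here) is quantized by the
1/300 per-pair divergence granularity; across seeds it centers on the true
13 Myr (see below). Re-running with the same seed reproduces every output
byte-for-byte; `demo/manifest.json` records the seed and config hash.

Every stage is also exposed as a library function
(`tecrm.enrichment.log_odds_ratio`, `tecrm.motifs.scan`,
`tecrm.evolution.insertion_time`, ...) and as individual subcommands
(`simulate`, `cluster`, `enrich`, `scan`, `age`, `profile`, `mpra`,
`luciferase`, `ddct`, `design-mutations`, `associate-genes`).

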