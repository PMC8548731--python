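# Methods

This note records the statistical model behind each stage of `lncm6a`, the
parameters that matter, and the design choices made where more than one
reasonable definition exists.  Everything quantitative below is computed by
the test suite or the acceptance script; nothing is asserted from memory.

## Coordinates and annotation

All internal coordinates are 0-based half-open; GTF's 1-based inclusive
convention is converted at file boundaries only.  Every analysis that needs
a transcript model uses the gene's *canonical* transcript, defined as the
longest by spliced length (transcript id as tie-break).  Spliced-transcript
coordinates used for window bookkeeping run in genomic (plus-strand) order
along the concatenated exons; 5'→3' orientation is applied only where
biology requires it (metagene position, summit sequences, first/last exon
labels), via the strand-aware mapping
`genomic_to_transcript` / `transcript_to_genomic`.

Exon-element classification uses the interval midpoint: unambiguous for
peaks spanning junctions, and exact for the single-exon-contained peaks the
generator plants.  "First" and "last" exons follow transcript orientation,
so the genomically last exon of a minus-strand transcript is its first.
Single-exon transcripts are excluded from the three-way tally and counted
separately — a three-way split is undefined for them.

## Peak detection

Windows are `window` nt wide (default 100, matching the ~100 nt RNA
fragmentation of a MeRIP library) at `step` nt (default 50) over the
spliced transcript; a window spanning a junction is split into genomic
pieces but tested as one unit.  Transcripts shorter than one window get a
single full-length window; the final <step nt of a transcript are not
re-covered by an extra stub.

Per window, replicate-pooled IP and input counts are compared with the
conditional binomial test: under equal IP/input rates,
`x_IP | n ~ Binomial(n, N_IP/(N_IP+N_in))` with `n = x_IP + x_in` and
library totals `N`.  This test is exact whenever IP and input counts are
(mixed) Poisson draws from a shared underlying abundance, which is how the
generator models paired libraries (below).  BH runs across all windows of a
condition; windows at `q <= 0.05` merge into a peak when their spliced gap
is at most one step.  A merged peak inherits its minimum window p and q
(recomputing BH at peak level is a documented alternative, not the
default); its summit is the midpoint of its maximum-enrichment window.
Methylation level of a span is `log2(((x_IP+1)/N_IP)/((x_in+1)/N_in))` —
pseudocount 1, log base 2.

## Differential methylation

The union of per-condition peaks (overlapping spliced intervals merged per
transcript) is tested peak by peak: the 2x2 table of replicate-summed IP
and input counts by condition goes into Fisher's exact test (two-sided,
"sum of <=-probability tables" convention); BH across peaks;
`diff.lg.fdr = log10(q)`, so the 0.05 cutoff sits at -1.30103; a peak is
*hyper* (or *hypo*) when `q <= 0.05` and the D4 - GM level difference is
positive (negative).

Depth normalization: the four cells are rescaled to the geometric mean of
the library totals and rounded before the exact test, with totals computed
over *background* windows (those not overlapping any union peak).  Raw
cells would confound the odds ratio with sequencing depth, and whole-library
totals are contaminated by the enrichment signal itself when peaks carry a
non-trivial fraction of IP reads — as they do at desk scale.  The residual
approximation (scaled counts are treated as Poisson) makes the test slightly
anti-conservative at very large counts; in the recovery studies this costs
at most an occasional false positive among dozens of true calls.

## Differential expression

A deliberately simple negative-binomial Wald test, not a re-implementation
of any published DE package: median-of-ratios size factors (error if no
gene is positive in every sample); `log2FC = log2((m_D4+0.5)/(m_GM+0.5))`
on normalized condition means; per-gene dispersion by method of moments,
`alpha = (s^2 - mu)/mu^2` pooled across conditions.  With two replicates
the moment estimate collapses to zero for a large minority of genes,
inflating Wald statistics, so each gene uses at least the across-gene
median of the positive estimates (and never less than 1e-8).  This
stabilization is deliberately conservative: it preserves type-I control at
the cost of some power at low replication.  The delta-method standard error
is `Var(log2 m_c) = (m_c + alpha m_c^2)/(n_c (m_c+0.5)^2 ln^2 2)` summed
over conditions; two-sided normal p; BH across tested genes.  A mean-RPKM
floor (default 0 = no filter) can exclude weakly expressed genes before BH.
"Expressed" means mean raw count >= 1 in at least one condition.
RPKM is `count * 1e9 / (library_size * exonic_length)` with exonic length
from the canonical transcript; the reported `meanfpkm` is the arithmetic
mean over all samples (per-condition means are a plausible alternative; the
all-sample mean is the documented choice).

## Peak anatomy and motifs

*Relative enrichment* of an exon element is its share of classified peaks
divided by its share of exonic length over the distinct multi-exon host
transcripts of those peaks — the only length-aware normalization consistent
with presenting a proportion pie next to an enrichment histogram.  Under
uniform peak placement all three enrichments are 1 by construction.

The metagene profile counts each peak once at its summit, binned as
`floor(n_bins * transcript_coord / L)` with `n_bins = 100`; coverage-
weighted profiles are out of scope.  Summits that fail to map onto an exon
are skipped and counted.

Motif enrichment scans the given strand only (RNA semantics; U and T are
interchangeable on input).  Pattern mode takes any IUPAC string (DRACH by
default) and reports foreground-vs-background rate fold and a one-sided
binomial p; de-novo mode enumerates exact k-mers for k in {5,6,7,8} and
BH-adjusts within each k.  No PWM optimization and no mismatches: the
bounded exact-k-mer core captures consensus-motif recovery and stays
testable.  The default background is 10 dinucleotide-preserving shuffles
per foreground sequence (Altschul–Erikson edge shuffling, seeded).  The
background rate used in p-values is floored at half a pseudo-hit to avoid
degenerate zero-rate nulls.  Motif statistics are most informative on
summit-centered sequence windows, where planted or biological motifs
concentrate; whole-peak sequences dilute the signal.

## Integration

Quadrant classification requires expression `padj <= 0.05` *and*
methylation `FDR <= 0.05` (ties at a threshold are significant, matching
"<=" as printed in the worked examples); survivors split by the signs of
the two changes into Hyper-up, Hyper-down, Hypo-up, Hypo-down.  The
methylation significance column may arrive as plain FDR or as log10(FDR);
the caller must state which — it is never guessed from the data.  When a
gene hosts several differential peaks, the peak with the smallest FDR
represents it.  Records with missing statistics or an exactly-zero effect
are Excluded with a reason code, so groups plus Excluded always partition
the input.

Pearson correlation of methylation change with expression change uses the
same dual-significance rule to define its "significant" subset; p is
two-sided from the t distribution with n-2 df and undefined below n = 3.
The two-sample KS test reports the exact D statistic and the asymptotic
Kolmogorov p with effective size `n1 n2/(n1+n2)`; the p is approximate for
groups smaller than ~10.

## Cis neighbors and ORA

Upstream/downstream follow chromosome orientation (upstream = lower
coordinates), not lncRNA strand; a flag switches to strand-aware labels.
Distance is the closest-edge gap between gene spans (0 when overlapping;
overlapping genes are assigned to the side of their start coordinate), with
ties broken by smaller gene start.  Up to five neighbors per side; fewer
near chromosome ends.  A pair survives filtering when the coding gene is DE
(`padj <= 0.05`), the lncRNA is DE, and the lncRNA carries at least one
differential peak at `FDR <= 0.05`; concordance is positive for equal
expression signs, retrograde for opposite.  Functional context comes from
user-supplied GMT gene sets scored by the hypergeometric upper tail
`P(X >= overlap)` with BH across sets; no ontology structure is modeled.

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, at desk
scale: random-sequence chromosomes; interleaved non-overlapping multi-exon
lncRNA (lincRNA/antisense/processed_transcript, 0.5/0.3/0.2) and
protein-coding loci on both strands; per-gene expression levels log-normal
(sigma 0.5) around `nb_mean` (default 50 expected input fragments per
100 nt window); library size factors log-normal (sigma 0.2) to exercise
normalization.

MeRIP counts use a gamma–Poisson construction: per window, condition and
replicate one gamma-distributed abundance (marginal NB with dispersion
`nb_dispersion`, default 0.1, variance `m + alpha m^2`) is shared by the
paired IP and input libraries, IP with its enrichment fold applied.  The
sharing reflects that IP and input are sequenced from the same RNA sample,
and it makes the window test's conditional-binomial null hold exactly —
the type-I calibration the null-simulation tests verify.  RNA-seq gene
counts are independent NB draws with the same dispersion, mean proportional
to expression times spliced length.

Planted structure: `floor(frac_lnc_with_peak * n_lnc)` lncRNAs get one
200 nt exonic peak (enrichment fold 8 by default; none when the fold is 1);
`floor(frac_de * n)` genes of each class are differentially expressed at
+-`de_log2fc_magnitude` (default 2), the condition effect split
symmetrically around the baseline.  LncRNAs that are both DE and peaked are
*coupled*: their methylation change is +-`meth_log2fc_magnitude` (default
1.5, small jitter), with the methylation sign matching the expression sign
with probability `(1+rho)/2` so the population sign-correlation equals
`meth_expr_correlation` (default 0.6).  The peak's per-condition folds are
`fold * 2^(+-meth/2)`, floored at 1.2.  With motif planting on, a GGACU
instance is written at each summit on the transcript strand.  Optionally,
planted cis pairs force a coupled lncRNA and its nearest coding neighbor
into a retrograde (opposite-sign) or positive (same-sign) configuration;
the coding DE marginal is preserved by unflagging another coding gene.
Selection of flagged genes is deterministic (first-k by gene index, floor
rounding), so truth-table marginals equal the requested fractions exactly.
A fixed seed reproduces byte-identical output files.

What the generator does **not** emulate: read-level artifacts (alignment,
mappability, duplicates), isoform mixtures, GC or length biases beyond the
explicit length scaling, batch effects, more than two conditions, and
peaks spanning splice junctions.  Passing tests therefore demonstrate the
statistical machinery, coordinate bookkeeping and calibration of the
pipeline — not robustness to those real-data artifacts.

## Study sizes and replication in the recovery tests

Null-calibration studies use ~23,000 windows (800 genes) and 10 x 2,000
genes, sizes at which binomial bounds on the checked fractions are sharp.
The fold-change-recovery and planted-cis-pair studies run at four
replicates per condition: with NB dispersion 0.1 the sampling sd of an
estimated log2FC at two replicates is ~0.46 independent of depth, so a
median-absolute-error bound of 0.3 or a 95% single-gene detection
requirement is simply outside two-replicate power; at four replicates both
hold with margin.  The correlation-recovery study keeps two replicates (its
acceptance band is wide) and estimates r over all coupled lncRNAs, the
planted population itself.  Other tests use the generator defaults.

## Known limitations

- The Wald DE test has no fold-change shrinkage; estimates at low counts
  are noisy, and the dispersion floor trades power for calibration.
- Window-level BH with min-p inheritance slightly overstates merged-peak
  significance relative to peak-level BH; the alternative is noted above.
- Fisher on depth-rescaled counts is approximate at very large counts.
- The asymptotic KS p and the normal Wald p are approximations at small n.
- Single-isoform transcript models throughout (canonical transcript only).
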