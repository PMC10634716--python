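# Methods

## The footprinting model

MNase digests naked DNA and spares protein-bound DNA, so fragment length
reports the protecting protein: a bound CTCF protects ~40 bp (fragments of
~40–60 bp once cut jitter is added), a nucleosome ~147 bp. In an MNase
HiChIP library sequenced with 150 bp reads, a pre-ligation fragment's exact
length is known only when the ligation junction falls inside a read — an
"observed ligation" — which requires both pieces to map and therefore caps
observable lengths at roughly `read_length − 25` bp (25 bp being the
minimum mappable stub). Observed ligation is thus a proxy for a short,
TF-protected fragment; everything longer is length-censored and treated as
nucleosome-scale.

Around a bound motif, short-fragment 5′ ends are bimodal and
strand-specific: '+'-strand reads start at the fragment's left (upstream)
edge, '−'-strand reads at its right (downstream) edge. Partitioning reads
in a window of half-width `w` around a candidate center into quadrants —
Q2 ('+', upstream), Q1 ('+', downstream), Q3 ('−', upstream),
Q4 ('−', downstream) — binding enriches Q2 and Q4 and depletes Q1 and Q3.
The statistic is

    alpha_hat = min(n2, n4) / max(n1, n3),

tested on the log2 scale. The min/max construction requires a pile-up in
*both* flanking quadrants, so a one-sided pile-up (e.g. a nucleosome edge)
cannot produce a call.

### The empirical null

Under no binding each read is equally likely to fall in any quadrant, i.e.
`(n1..n4) ~ Multinomial(N, 1/4)` — no distributional assumption on read
counts beyond exchangeability. The null distribution of `log2(alpha_hat)`
is tabulated by Monte Carlo per total count `N` on a fixed grid
0.00..5.00 (step 0.01; `alpha_hat` in [1, 32]), for `N` from 5 to 500;
windows with larger `N` reuse the `N = 500` row, which has effectively
converged. Observed statistics are snapped *down* to the grid
(conservative), `min(n2,n4) = 0` reports p = 1 regardless of the
denominator, a zero denominator with a non-zero numerator is capped at the
grid top, and p-values are floored at `1/reps`. The table is reproducible
bit-for-bit given a seed. The suite tabulates 2–3×10⁵ draws per `N`
(p floor well below the 1e−05 calling threshold); the acceptance script
uses 10⁶; 10⁸ is the production-scale setting for real libraries.

### Peak calling

Windows (default half-width 100 bp — short-fragment enrichment is confined
to roughly ±100 bp of the motif — step 1 bp) holding at least `min_reads`
(5, the table minimum) short-fragment reads are tested; both sides of a
contact contribute their observed-ligation reads. Windows with
p < 1e−05 are merged when within 30 bp, and the summit is the window
maximizing the statistic (ties: larger `N`). On clean pile-ups the maximal
statistic is flat across a ~±19 bp plateau, so the summit is placed at the
**midpoint** of the tied run: a leftmost rule would bias the summit by half
the plateau width, and the midpoint is the unbiased, deterministic choice.
A read exactly at the window center counts to the downstream quadrant
(deterministic; the symmetric alternative does not change results
materially). For motif-level inference, each motif takes the p of the
nearest tested window (ties: smaller p; no window within 1 kb: p = 1) and
q-values are Benjamini–Hochberg across motifs.

## Cohesin analytics

**Footprint differencing.** Fragment coverage is accumulated ±80 bp around
motif centers in motif-strand orientation (downstream = right of a '+'
motif, left of a '−' motif) and the difference downstream − upstream is
taken per offset. Only mid-size fragments (length 80–120 bp, the
CTCF+cohesin scale) with long-range (>10 kb) cis contacts are used,
stratified by RAD21 ChIP level at the motif (top/bottom 25% of the signal
of the peak within 50 bp; nearest peak when several qualify; quantile ties
straddling a cutoff are left unassigned so HIGH and LOW stay disjoint) and
by whether the focal fragment is the upstream or downstream partner of its
contact. A cohesin stabilized at CTCF's N-terminal (downstream) face shows
up as positive difference at offsets ~20–60 for upstream fragments at
high-RAD21 motifs only.

**Fully extruded state.** TF-protected (length < 115 bp, both edges ≥15 bp
from the center) upstream fragments with >10 kb contacts overlapping a
bound '+' CBS are collected; a partner is *convergent* when its fragment
interval overlaps a '−' motif downstream of the CBS (overlap pad 0 by
default). The genome-wide point estimate is
`(Σ convergent / Σ fragments) × occupancy` with occupancy 0.5 — the ratio
is conditional on CTCF being bound at the anchor, and CTCF occupancy is
~50% — and the CBS-level range is the occupancy-scaled 1st/99th percentile
over CBS with ≥50 qualifying fragments. The ratio form makes the estimate
invariant to duplicating every contact.

**Loop size by chromatin state.** The 1 Mb window downstream of each bound
'+' CBS (truncated and flagged at chromosome ends) is annotated with
ChromHMM state fractions, H3K27ac bp covered (union of peak overlaps) and
RNAPII peak count. The 15 states are collapsed to three groups — active,
polycomb/bivalent, quiescent — either by a user map or automatically by
Ward agglomerative clustering on `1 − Pearson` correlation of the
per-state fraction vectors across regions, cut at three clusters and named
by keyword vote over member state names. Each group's analysis set is the
20% of regions with the highest summed group fraction (ties resolved
toward the lowest region index). Extruded loop size per stratum is the
mean log10 interaction length of long-range TF-protected fragments, also
reported back-transformed (`10^mean / 1000` kb).

**Cohesin effect.** To control locus-specific contact propensity, the
per-CBS difference in mean log10 interaction length between TF-protected
and nucleosome fragments is combined across CBS by inverse-variance
weighting, with variances `sigma² (1/n_TF + 1/n_nuc)` built from a pooled
within-(CBS, class) residual variance so CBS with a single fragment in a
class remain usable; the SE is `sqrt(1/Σw)`. This precision-weighted
estimator stands in for a full random-intercept mixed model: with the
pooled-variance assumption it is the same fixed-effect estimate, without
REML machinery.

## The synthetic generator

`SimConfig` plants every quantity the analyses estimate:

| parameter | default | meaning |
|---|---|---|
| `occupancy` θ | 0.5 | fraction of cells with CTCF bound at a bound motif (benchmark runs use 0.8) |
| `ctcf_protect` / `cut_jitter` | 40 / 10 bp | protected span and uniform linker-cut jitter → 40–60 bp TF fragments |
| `cohesin_ext` | 40 bp | extra downstream protection on upstream-partner TF fragments at cohesin-positive motifs → 80–100 bp fragments |
| `nucleosome_len` / `spacing` | 147 / 200 bp | phased nucleosome arrays at motifs (k = −2..2, jittered) |
| `read_length` − `min_mappable` | 125 bp | observed-ligation censoring threshold |
| `convergent_capture` c | 0.10 | conditional probability an upstream TF fragment at a '+' CBS ligates onto its planted downstream '−' motif |
| `group_log10_size` λ | 5.16 / 5.28 / 5.40 | mean log10 extruded distance per chromatin group (~144 / ~190 / ~252 kb) |
| `cbs_log10_sd` τ, `frag_log10_sd` σ | 0.05, 0.25 | CBS-level intercept and fragment-level spread of log10 distance |
| `class_effect_delta` δ | 0.4 | deficit in mean log10 distance of nucleosome- vs TF-protected fragments at the same motif |
| `background_fraction` | 0.10 | uniform-position observed short reads with s⁻¹ power-law partners on [1 kb, 2 Mb] |

Extruded contact distances are log-normal in log10, so the loop-size
estimand (mean log10 length of long-range TF fragments) equals the planted
λ directly; the >10 kb filter truncates a negligible tail at these scales.
Two deliberate constructions keep planted parameters exactly recoverable:
partner directions that would leave the chromosome are flipped rather than
clipped (clipping piles partners onto one coordinate and fabricates a
binding-like pile-up), and non-convergent partners of upstream TF
fragments at '+' CBS are resampled away from '−' motifs so the conditional
convergence equals c exactly. MNase cut bias is not modeled (uniform
cutting within accessible linker), trans contacts and ligation artifacts
are not generated, and chromatin-state windows are tiled per CBS, so
closely spaced CBS share annotation; the compact `recovery_config`
(45 '+' CBS at 1.1 Mb spacing, depth 160) keeps windows disjoint for
recovery studies.

What passing tests show — and do not. The generator produces the read
geometry the caller exploits by construction, so detection benchmarks
certify the statistic, null calibration, and summit localization under the
stated noise, not robustness to real-data pathologies (mappability holes,
copy-number variation, antibody efficiency, cut bias). Parameter-recovery
tests certify that the estimators are unbiased for their estimands under
the model that defines those estimands.

## Numerical and scale choices

The default test-suite problem sizes (benchmark: 2,000 motifs over ~13 Mb,
~110k contacts, null table to N = 150; recovery: 20 replicates of 45 CBS)
were chosen so the whole suite runs in about a minute of CPU while leaving
every Monte-Carlo comparison at ≥3σ separation; the acceptance script runs
the same benchmark with the full N = 5..500 table at 10⁶ draws per row.
Degenerate inputs are contracts, not corner cases: empty files and empty
strata produce empty-but-typed results, trans contacts return no
interaction length, motifs without nearby windows get p = 1, and
quantile-tied RAD21 signals stay unassigned.

## Known limitations

The pairs dialect (per-side fragment length, −1 for censored) is this
package's reconstruction of a post-parse contact table, not an upstream
tool's format. Real-data inputs (ENCODE peak tracks, ChromHMM
segmentations) are accepted through the BED-family readers but no
alignment or pairs-parsing is performed. The cohesin-effect estimator
assumes a common residual variance across CBS and classes; strongly
heteroscedastic loci would argue for the full mixed model it approximates.
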