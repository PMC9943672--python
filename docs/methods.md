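# Methods

## The statistical model

Each sequencing read is treated as one tRNA molecule carrying a vector of
binary features: a mismatch (misincorporation signature) at each candidate
modified site it covers, an aminoacylation state read off its 3' terminus,
and a fragmentation class derived from where the read ends. For a feature
pair (A, B) on one transcript, reads informative for both features form a
2x2 contingency table and the association is the cross-product odds ratio
`OR = n11*n00 / (n10*n01)`. Independence of the two per-molecule events
gives OR = 1; OR > 1 means the features co-occur on the same molecules
(stimulatory), OR < 1 that they exclude each other (inhibitory). The test
is a two-sided Fisher exact test on the raw counts; p-values are
Benjamini-Hochberg corrected. The method is deliberately associational:
nothing here orders the events causally.

"Informative" is defined per pair: a read must cover both site positions
(aligned span contains the position and the position is not deleted in the
read), and for the charging feature must have a determined CCA/CC call.
Reads truncated before a site are therefore *excluded* from that site's
tables, not counted as unmodified — a truncated read carries no evidence
about the site.

## Coordinates and input model

All computation runs in 1-based transcript coordinates of the mature tRNA
reference, which must include the 3' CCA. Canonical (Sprinzl) numbering is
treated as a labelling concern only, because mapping transcript positions
to canonical numbers requires a per-tRNA structural alignment that is out
of scope here. Insertions in reads are ignored; deletions make positions
"not covered" rather than mismatched, since the modification signal of
interest is misincorporation. Only primary alignments are used; resolving
multi-mapping between near-identical isodecoders is the job of the upstream
alignment/deconvolution pipeline.

## Charging calls

After periodate library chemistry, charged tRNAs end 3'-CCA and uncharged
3'-CC. A read is CHARGED only when it ends exactly at the reference 3' A
with the terminal CCA intact, UNCHARGED only when it ends one base short
with the terminal CC intact. A mismatch or deletion within those terminal
bases makes the call UNDETERMINED rather than guessing — conservative, at
the cost of a small loss of informative reads. The reference 3' end is
located per transcript from the FASTA, never assumed at a fixed length.

## Thresholds and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `min_fraction` | 0.05 | a position is a candidate modified site at >= 5% mismatch (inclusive) |
| `min_coverage` | 50 reads | absolute per-site floor so that site fractions are stable; exposed as a flag |
| `min_pair_reads` | 50 reads | informative-read floor per tested pair; Fisher on a handful of reads is noise |
| `alpha` | 0.05 | significance level on BH q-values |
| FDR family | all pairs in one sample | the conservative choice; per-transcript correction available |
| `min_replicates` | 2 | consensus requires the same-direction significant call in >= 2 replicates |
| `min_delta` | 0.03 | consistency analysis considers only changes > 3 percentage points |
| tRF 5' anchor | `align_start <= 5` | a read must be 5'-anchored to count as a 5' tRF or full-length molecule |

Zero-cell tables: the raw OR is reported as 0 or +inf (NaN when numerator
and denominator both vanish) and a separate Haldane-Anscombe estimate
(+0.5 to every cell) provides a finite effect size; the Fisher test always
runs on the raw counts, keeping estimation and testing separate.

Replicate consensus excludes pairs that are significant with conflicting
directions across replicates (with a logged warning) instead of majority
voting; a direction conflict is evidence of instability, not of a
crosstalk.

Differential tests use Pearson chi-square without continuity correction
(flag to enable Yates); a zero marginal makes chi-square undefined and the
implementation falls back to Fisher, flagged in the output. The >3%-change
filter of the consistency analysis is applied to *both* endpoints by
default (stricter); a flag relaxes it to either endpoint.

## Fragmentation

Only 5' tRFs are analyzed, because a 3' fragment is indistinguishable from
a reverse-transcription stop. Bins by 3' terminus: 30-39 (anticodon/C-loop),
40-49 (variable loop), 50-59 (T-loop), full-length > 60. Position 60 falls
in no bin by these definitions and is left unclassified rather than
silently absorbed into a neighbouring class. Bins are transcript
coordinates; for type II tRNAs with long variable arms the bins therefore
shift relative to canonical numbering, a known limitation. A site pairs
with a tRF class only when the site position does not exceed the class's
lower bound, so every read of the class can cover it. Charging is never a
fragmentation feature (truncated reads have no CCA context).

## Simulator

The generator plants Bernoulli mismatches at two positions (defaults 26
and 58 of the 76-nt mature yeast tRNA-Phe) with marginals p_A, p_B and a
target OR. The joint probability p_AB solves the quadratic odds-ratio
identity; the "-sqrt" root is the valid one (the other root leaves the
probability simplex). Because the closed form cancels catastrophically as
OR -> 1, the root is polished with Newton iterations on
`g(p) = p(1-p_A-p_B+p) - OR(p_A-p)(p_B-p)`, giving back-substitution
accuracy of 1e-9 or better everywhere; the OR = 1 limit is p_A*p_B exactly.
Degenerate marginals (0 or 1) are permitted in sample generation, where the
joint cell is forced by the marginals.

Layers: charging is an independent Bernoulli realized as a CC-ending read;
truncation draws a tRF bin per read with probabilities optionally
conditional on the modification state at the first position, then a
uniform 3' terminus within the bin. A planted mismatch is *observed* only
when the read's span reaches it, reproducing the truncation-censoring of
real data. Mismatch bases are the first non-reference base alphabetically —
deterministic, since base identity is irrelevant downstream. Each sample's
RNG is seeded by the tuple (master seed, grid indices), so grids are
reproducible and order-independent; identical specs give byte-identical
output tables.

What the simulator does not emulate: reverse-transcription stop profiles
and the resulting 5' coverage drop-off, sequencing error, quality scores,
ligation bias, multi-transcript libraries with isodecoder ambiguity, and
per-position variation in misincorporation rates. Passing the validation
grid therefore demonstrates the statistical machinery (calibration, power,
estimate recovery) under clean Bernoulli censored-observation conditions,
not robustness to alignment artefacts.

## Validation experiment

The default grid draws one 20,000-read sample for every combination of
p_A, p_B in {0.075, 0.175, ..., 0.975} and log2(OR) in
{-1, -0.5, -0.25, 0, 0.25, 0.5, 1} — 700 samples — and runs each through
the full pipeline. With a fixed master seed the suite checks:

* exactly 700 analyzed samples;
* type-I error at OR = 1 within [3%, 7%] at nominal 5% (1,000 null
  samples of 2,000 reads; the smaller per-sample size keeps the run fast
  and leaves the calibration property unchanged, as cell counts stay in the
  hundreds);
* median |estimated - generating| log2(OR) < 0.1 over cells with both
  marginals in [0.075, 0.875];
* the sensitivity floor: the smallest positive grid OR detected
  (q < 0.05) in at least 75% of those cells. "At least 75%" operationalizes
  "the large majority" and is fixed a priori; the observed detection
  fraction at log2(OR) = 0.25 is ~89% at the default seed, so the floor is
  2^0.25 ~ 1.19. Detection weakens toward extreme marginals (> 95% or
  < 5% mismatch), where one margin of the 2x2 table collapses.

The Fisher implementation is verified against an exact integer
hypergeometric enumeration (point weights as products of binomial
coefficients, two-sided p as the normalized sum of weights not exceeding
the observed one) over *all* 316,250 tables with total <= 50, to 1e-10.

## Codon usage weighting

Translational efficiency is polysome TPM / total TPM for genes with >= 10
TPM in both measurements. Per-gene RSCU follows the standard family-size-
scaled frequency; families unused in a gene are NaN, excluded codon-wise.
The condition-level profile weights gene RSCU by z-scored log2(TE). Since
z-scores sum to zero, a plain weighted mean is ill-defined; the signed
convention `sum(w * RSCU) / sum(|w|)` is used, which scores 0 for codons
with no TE association and positive for codons enriched in efficiently
translated genes. A top-vs-bottom TE-quartile RSCU contrast is emitted
alongside as a convention-free robustness output. The synthetic CDS
generator couples a per-gene GC3 bias to log2(TE) (slope 2 on the
half-unit bias scale, Gaussian noise SD 0.25, 200 genes of 300 codons by
default) so the qualitative claim — GC-ending codons enriched at high TE —
is testable without external data.

## Numerical and degenerate-input choices

* BH is applied over a stably sorted (p, transcript, pair) order for
  reproducible output; q-values are order-invariant regardless.
* Empty feature tables (no informative reads) are skipped by the
  `min_pair_reads` floor; an all-zero table never reaches Fisher.
* Identical feature pairs and empty read sets raise errors rather than
  returning empty results.
* Ambiguous read bases (N) are not counted as mismatches.
* `simulate_sample` accepts int or int-tuple seeds (numpy SeedSequence
  entropy), all below 2^31 in normal use.

## Known limitations

* No canonical-numbering awareness: positions are transcript coordinates.
* Reads are molecules only to the extent the library is PCR-deduplicated;
  amplification duplicates would inflate counts and significance.
* The charging caller ignores non-templated edits other than CCA/CC loss.
* Consistency analysis treats endpoints independently; correlated
  measurement error between two sites of the same transcript can bias the
  TRUE/FALSE tally in either direction.
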