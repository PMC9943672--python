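# slac

**Single-read analysis of crosstalks in tRNA-seq data.**

tRNAs are short enough that one NGS read can span an entire molecule, so a
single read simultaneously reports several properties of that molecule:

* **modifications** — base modifications that perturb Watson-Crick pairing
  (m1A58, m2,2G26, m1G9/37, m3C32, ...) cause reverse transcriptases to
  misincorporate, leaving a mismatch "mutation signature" against the
  reference;
* **aminoacylation (charging)** — with periodate oxidation / beta-elimination
  library chemistry, charged tRNAs end 3'-CCA and uncharged ones 3'-CC;
* **fragmentation** — 5' tRNA fragments (tRFs) are identified by where their
  3' terminus falls on the transcript.

Conventional pileup analysis collapses these signals to per-position
percentages and discards the per-molecule coupling. `slac` keeps the
single-read resolution: for every pair of features A, B on a transcript it
counts, over the reads informative for both,

```
OR = (#reads with A and B) x (#reads with neither)
     ---------------------------------------------
     (#reads with A only)  x (#reads with B only)
```

OR > 1 is a *stimulatory* crosstalk (features co-occur on the same
molecules), OR < 1 an *inhibitory* one. Significance is a two-sided Fisher
exact test, Benjamini-Hochberg corrected across all tested pairs. The same
machinery covers site-site, site-charging and site-fragmentation pairs,
plus condition-vs-condition differential tests (ratio-of-odds + chi-square),
replicate-consensus and crosstalk-consistency scoring, and a TE-weighted
relative synonymous codon usage module.

The package operates downstream of alignment: input is either a SAM/BAM of
reads aligned to a mature tRNA reference (FASTA, 3' CCA included) or a
tab-delimited single-read table (`read_id, transcript, start, end,
mismatches, end_call`). A validated simulator generates ground-truth
datasets with prescribed marginal mismatch probabilities and pairwise odds
ratio, using the closed-form joint probability

```
p_AB = [1 + (p_A+p_B)(OR-1) - sqrt((1 + (p_A+p_B)(OR-1))^2 + 4 OR (1-OR) p_A p_B)] / (2(OR-1))
```

(the OR -> 1 limit is p_A p_B).

## Worked example

Plant a stimulatory crosstalk (OR = 2) between positions 26 and 58 of yeast
tRNA-Phe (the m2,2G26 / m1A58 pair) with marginal mismatch fractions 0.30
and 0.40, then recover it:

```python
from slac import SimSpec, simulate_sample, all_crosstalks, pileup, candidate_sites

reads, truth = simulate_sample(
    SimSpec(p_a=0.30, p_b=0.40, target_or=2.0, n_reads=20_000, seed=7)
)
sites = candidate_sites(pileup(reads))        # {(tRNA-Phe-GAA-2, 26), (..., 58)}
results = all_crosstalks(reads, sites=sites, include_charging=False)
print(results[["transcript", "feature_a", "feature_b", "n11", "n10", "n01", "n00",
               "or_raw", "log2_or", "p", "q", "direction"]].to_string(index=False))
```

```
    transcript  feature_a  feature_b  n11  n10  n01  n00   or_raw  log2_or             p             q   direction
tRNA-Phe-GAA-2         26         58 3101 2844 4813 9242 2.093738 1.066081 1.749099e-122 1.749099e-122 STIMULATORY
```

The 2x2 counts (n11 = reads mismatched at both 26 and 58, ..., n00 =
mismatched at neither) give an estimated odds ratio of 2.09 (log2 = 1.07)
against a generating value of 2.0, overwhelmingly significant at 20,000
reads: the two modification signatures co-occur on the same molecules far
more often than independence would allow.

The same pipeline is available from the shell:

```bash
slac simulate --p-a 0.3 --p-b 0.4 --or 2 --n 20000 --seed 7 --out-dir sim/
slac crosstalk --reads sim/reads.tsv --reference sim/reference.fasta --out-dir ct/
slac grid --out-dir grid/        # the full 700-sample validation experiment
```

Every command writes its result TSVs plus `config.json` (parameter
snapshot) and `summary.json` (counts at each filter stage).

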