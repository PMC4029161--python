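# Methods

## The model

The analysis treats a repeat family as a set of copies emitted over time by
one (or a few) actively transposing **master elements**. A consensus built
from all copies approximates the ancestral sequence; each copy's divergence
from the consensus is an age proxy under a constant substitution rate. Two
biases are corrected before interpretation:

* **Master-lineage drift.** The master element itself accumulates
  substitutions; copies emitted later inherit them. Relative to the
  consensus these inherited substitutions appear in many copies at the same
  position with the same derived base. The refinement treats substitution
  *signatures* (position, derived base) seen in ≥ `min_copies` copies,
  grouped by the exact copy set carrying them with ≥ `min_group` signatures
  per group, as master-lineage events, and removes those sites from both the
  numerator and the denominator of the mismatch proportion. Removing them
  only from the numerator would bias the estimate downward.
* **CpG hypermutability.** Substitutions at CpG dinucleotides (both
  positions, defined on the consensus top strand) are excluded wholesale
  because convergent substitution at such sites breaks the
  identical-by-descent interpretation of a shared signature, and inflates
  divergence generally.

The refined proportion is converted to a Jukes–Cantor distance
d = −(3/4)·ln(1 − (4/3)·p), undefined (flagged, counted, never silently
dropped) at p ≥ 0.75.

Frequencies are modelled per genome as binomial sampling: each shotgun read
maps to a given repeat with probability f. All tests are likelihood-ratio
tests; cutoffs are calibrated by simulating binomial counts at the observed
frequencies (κ²), p-values are percentile ranks among simulated null
statistics with the (r+1)/(n+1) finite-sample correction, and one-sided
confidence bounds for f_g/f_s (the λ thresholds) come from a profile
likelihood along the ridge f_g = λ·f_s, where the constrained maximum is the
admissible root of a quadratic and the bound is located by bisection to
1e-4 relative tolerance.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 0.80 | identity gate for read-to-consensus alignments |
| `min_overlap` | 100 bp | minimum aligned non-gap columns |
| `min_copies` | 2 | copies that must share a signature |
| `min_group` | 2 | co-carried signatures per excluded group (1 = laxer reading) |
| `alpha` | 0.05 | test level; λ bounds also computed at 0.01 |
| `n_sim` | 10,000 | simulated datasets per cutoff/p-value |
| replicate filter | 0.99 / 1.0 / 3 | identity cutoff, length requirement, initial bp match |
| ORF `min_len` | 100 nt | strictly-greater length gate, both ORF modes |
| genome sizes | 15 / 3 Gb | germline / soma haploid-equivalents |

Alignment scoring (match +1, mismatch −2, gap open −4, extend −1) is
config-exposed but deliberately mild: the identity filter, not the score,
is the effective gate. Candidate families are pre-screened with an
edit-distance infix search (edlib) and only the best few candidates receive
the affine alignment, windowed around the located hit.

## What the generator emulates — and what it does not

`simkit` draws a random consensus per family, applies an ordered list of
master-lineage substitutions, lets each copy branch after a uniform-random
prefix of that order, then adds private substitutions at per-site
probability p_true (× a CpG multiplier at consensus CpG sites). Diminution
is per-copy Bernoulli survival with a family-specific retention
probability, so the somatic pool is always a subset of the germline pool.
Reads are random substrings (random strand) of pool copies, with normal
read lengths (mean 183/216 bp, floor 50 bp) matching pyrosequencing scale,
plus a configurable fraction of random background sequence — defaults
0.124/0.283, the complements of the study system's masked fractions
(87.6 %/71.7 %).

The default landscape (23 families) encodes the biological scenario under
study: young (0.5–5 % divergence), high-frequency DNA/LINE/unknown families
with low somatic retention (0.12–0.25); old (8–14 %) LTR/LINE-CR1 families
with high retention (0.8–0.95); and intermediate families near the
genome-wide retention rate. A second canned landscape (`burst_landscape`)
sharpens the proliferation-burst signal, placing the young tier below 1 %
divergence with a reference tier whose retention matches the bp-weighted
genome average, so its frequency ratio is ~1 by construction.

**Problem sizes.** Defaults are 10,000 germline and 5,000 somatic reads over
a ~21 Mb germline copy pool. The read counts are a desk-scale reduction of
the study system's 612,470/207,451 reads; the pool is sized so per-copy
sampling depth stays ≈ 0.1×. This matters: at depth ≳ 1 independent reads
resample the *same* copy, and its private substitutions genuinely satisfy
the shared-signature criterion (they are identical by descent — from the
copy, not the master), overwhelming the master-lineage signal. Real surveys
sit at ~0.01× per-copy depth; the simulator must stay in that regime for
the refinement to be meaningful. Residual same-copy overlap at 0.1× is the
main reason refined divergence runs a few percent below truth.

Not emulated: pyrosequencing homopolymer error profiles,
whole-genome-amplification bias, chromosomal placement of excised
heterochromatin, and indels (an optional geometric-length indel mode exists
but defaults off so the substitution-only divergence oracle stays exact).
"Simple" families use random consensus sequence rather than true tandem
structure. Passing tests therefore demonstrate correct recovery of the
generative model's structure, not robustness to sequencing artefacts or
tandem-repeat annotation.

## Numerical choices

* Likelihood terms use `xlogy` so 0·log 0 ≡ 0; f = 0 with x > 0 gives −∞.
* κ² is the empirical (1 − α) quantile (linear interpolation) of the
  simulated statistics; with the same seed the value is bit-reproducible.
* The equality test leaves x_s = x_g = 0 repeats untested (p = NaN); ratio
  and λ are reported as undefined whenever either count is zero —
  pseudo-counts would alter the likelihood.
* λ search: the one-sided critical value defaults to the asymptotic
  one-sided χ²₁ value, chi2.ppf(1 − 2α, 1) ≈ 2.706 at α = 0.05; simulation
  calibration (`cutoff="simulate"`) is available. For non-rare repeats the
  two agree, which is also why the simulated joint-region κ² matches the
  χ²(2 df) quantile 5.991. When even λ = 1 is not rejected at the requested
  level the bound does not exist and is reported as NA (this reproduces the
  pattern where a marginally significant repeat has a 95 % bound but no
  99 % bound).
* Tie-breaks in read assignment: highest score, then highest identity, then
  lexicographically smallest family id — assignment is deterministic.
* Overlapping mask intervals on one read are merged before bp accounting;
  the longer hit keeps the class attribution (ties: earlier record).
* All internal coordinates are 0-based half-open; RepeatMasker files are
  converted on parse, and complement hits are reverse-complemented into
  consensus-forward orientation so substitution bases are always reported
  on the consensus strand.
* One global seed expands into per-family and per-stage sub-seeds through
  `numpy.random.SeedSequence.spawn`, so outputs are platform-stable and
  stages can be regenerated independently.

## Open design points, as resolved here

* *"Groups of two or more substitutions shared by two or more copies"*: a
  lone shared signature is **not** excluded under the default
  `min_group=2`; `min_group=1` implements the laxer reading. Under the
  strict reading, exclusion requires signatures co-carried by an identical
  copy set, which staggered branch points and read windows fragment — the
  CpG exclusion then carries most of the correction. Neither reading is
  asserted as the original intent.
* Divergence distributions bin the Jukes–Cantor-corrected percentage by
  default (`bin_corrected=False` bins the uncorrected proportion instead).
* Frequency denominators count **all** reads of a genome (assigned or not),
  making frequencies comparable across genomes; `freq_denominator:
  "assigned"` is provided as a sensitivity toggle.
* CpG status is assessed on the consensus, not the copy.
* Relaxed ORFs truncate at the last complete codon (no wrap-around);
  overlapping same-frame ORFs collapse to the longest (first ATG per
  stop-delimited segment); ">100 nt" is strict; codons containing N match
  neither ATG nor stop. Strict ORF lengths include the stop codon.

## Known limitations

* The replicate filter re-specifies a retired web tool from its published
  parameters; removal fractions are not expected to match that tool
  byte-for-byte.
* Superfamily tests are not corrected for multiple testing (by design —
  results are per-superfamily statements, not a family-wise claim).
* The annotation is single-best-family per read; reads spanning two repeat
  copies (rare at ~200 bp) contribute to only one family.
* Divergence above ~20 % is outside the generator's support, and the
  identity filter censors copies beyond ~20 % anyway; conclusions about
  very old repeats are limited accordingly.
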