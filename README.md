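# repeatdim

Germline vs somatic repeat-landscape analysis for genomes undergoing
**chromatin diminution** — the programmed deletion of DNA from presomatic
cell lineages during development, which leaves a single organism carrying
two different nuclear genomes (e.g. a ~15 Gb germline genome reduced to a
~3 Gb somatic genome in cyclopoid copepods).

The package is aimed at molecular evolution researchers working with
low-coverage shotgun surveys of paired germline/somatic samples. It answers
three questions:

1. **What is deleted?** Reads from each genome are assigned to a repeat
   library (best affine local alignment, ≥ 80 % identity over ≥ 100 bp);
   masked base-pair fractions are extrapolated to genomic gigabases per
   repeat class (known TE superfamilies, simple repeats, unknown repeats,
   rRNA), and unknown repeats are screened for open reading frames.
2. **How old are the deleted repeats?** Copy-to-consensus divergence is an
   age proxy, but a consensus summarises a *drifting* master element:
   substitutions on the active master lineage are inherited by whole cohorts
   of copies and inflate every copy's apparent age. The package catalogues
   substitutions per family, excludes signatures shared by multiple copies
   (master-lineage candidates) and CpG sites (convergence-prone), and
   converts the refined mismatch proportion *p* to a Jukes–Cantor distance
   *d* = −(3/4)·ln(1 − (4/3)·*p*).
3. **Is excision selective?** Each read is a Bernoulli trial with success
   probability *f*, the frequency of a repeat in one genome. With counts
   x_s, x_g out of N_s, N_g reads,

       ln L(f_s, f_g) = x_s ln f_s + (N_s − x_s) ln(1 − f_s)
                      + x_g ln f_g + (N_g − x_g) ln(1 − f_g),

   the package tests H₀: f_g = f_s with a likelihood-ratio statistic
   X² = −2 ln Λ calibrated by binomial simulation (cutoff κ²; p-values by
   percentile ranking), builds joint confidence regions with per-genome
   one-dimensional summaries, and reports one-sided 95 %/99 % confidence
   bounds λ for the ratio f_g/f_s via a profile likelihood along the ridge
   f_g = λ·f_s. Ratios ≫ 1 flag repeats disproportionately excised from
   the soma; ≪ 1 flags repeats disproportionately retained. Individual
   families are binned as excised/retained/equal with a Poisson χ²(1 df)
   shortcut, and bin age distributions are compared with 2-sample z-tests.

Because paired germline/soma datasets are rare, the package ships a seeded
synthetic generator (`repeatdim.simkit`) that emulates the generative
structure this analysis assumes — per-family age distributions, master-gene
drift, CpG hypermutability, per-copy Bernoulli survival into the soma, and
shotgun sampling at survey-scale depth — together with complete ground-truth
tables, so every estimator is testable for parameter recovery.

## Worked example

The numbered drivers under `analysis/` chain the full study on a synthetic
landscape (young, high-frequency DNA/LINE families with low somatic
retention; old LTR families with high retention):

```bash
python analysis/01_simulate.py --seed 0 --copy-scale 0.3
python analysis/02_filter_replicates.py
python analysis/03_annotate_reads.py
python analysis/04_divergence_profiles.py
python analysis/05_superfamily_frequency_tests.py --seed 0
python analysis/06_age_by_excision_bin.py
python analysis/07_genome_content_and_orfs.py
python analysis/08_statistical_calibration.py --seed 0
```

which prints, among other output:

```
germline: 8520/9987 reads assigned; 85.8% of base pairs masked by the library
soma:     3570/4997 reads assigned; 71.1% of base pairs masked by the library
germline: 8520 repeat reads, mean divergence 5.69%, modal bin [1, 2)%
soma:     3570 repeat reads, mean divergence 8.48%, modal bin [9, 10)%
KS germline vs soma: D = 0.276, p = 7.49e-170 (different age profiles)
  superfamily   p_value dominant  ratio  lambda_95  lambda_99
     DNA-MuDR 9.999e-05 Germline  3.066      2.604      2.438
      DNA-hAT 9.999e-05 Germline   3.06      2.697      2.562
    LTR-Gypsy 9.999e-05  Somatic 0.5589      0.599     0.6164
  DNA-Chapaev    0.1486  Neither   1.32        NaN        NaN
  ...
excised_vs_equal:  mean 2.42% vs 6.55% (z = -64.9, p = 0)
retained_vs_equal: mean 11.17% vs 6.55% (z = 55.2, p = 0)
germline: 85.8% masked x 15 Gb = 12.86 Gb of repeats
soma:     71.1% masked x 3 Gb = 2.13 Gb of repeats
repeats account for ~11 Gb of the DNA eliminated at diminution
```

Reading the table: the germline-dominant DNA transposon and LINE
superfamilies sit at frequency ratios ~3 with one-sided 95 % bounds above 1
(disproportionately excised from the soma), the LTR retrotransposons at
ratios ~0.56 with bounds below 1 (disproportionately retained), and
non-significant rows report `NaN` bounds. The z-tests show excised repeats
are much younger, and retained repeats much older, than repeats deleted at
the genome-wide rate — diminution targets the recent proliferation burst.

The same steps are available as a CLI (`repeatdim simulate | filter-dups |
annotate | divergence | compare-freqs | age-by-bin | genome-content | orfs |
run-all`) and as one call, `repeatdim.pipeline.run_pipeline(config, outdir)`.

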