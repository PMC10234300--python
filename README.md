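# triosel

Single-generation inference of natural selection (s) and dominance (h) from
phased parent–offspring trios.

The method conditions on parental haplotypes: for every couple it pre-simulates
an array of potential zygotes (meiosis under sex-specific recombination maps),
imposes viability selection by sampling one zygote per observed child with
probability proportional to fitness `(1+s)^k_homo * (1+h*s)^k_het`, and compares
the simulated survivors with the actual children through two summary
statistics — the offspring-minus-parent differences in mean homozygous and mean
heterozygous derived-site counts (Δ_homo, Δ_het). Inference is two-stage
approximate Bayesian computation: a pilot run under broad priors, rejection,
empirical-prior resampling, a final run, and rejection followed by local-linear
regression adjustment. Constrained models (neutral / recessive / additive) are
compared by pooled-acceptance model choice.

Because meiosis is independent of (s, h), the zygote arrays are built once and
reused across all ABC iterations; the inner loop is a numba kernel with a
dedicated fast path for single-SNP cohorts.

## Layout

- `triosel.datatypes` — sites, haplotypes, individuals, trios, cohorts
- `triosel.io` — phased VCF (via cyvcf2), PED pedigrees, genetic maps, reference tables
- `triosel.recomb` — piecewise-linear sex-specific recombination maps
- `triosel.meiosis` — crossovers, gametes, per-couple zygote arrays, de novo handling
- `triosel.selection` — fitness and fitness-proportional zygote sampling
- `triosel.summaries` — mean genotype counts and (Δ_homo, Δ_het)
- `triosel.abc` — priors, reference tables, rejection, empirical-prior resampling,
  regression adjustment, model selection, end-to-end `infer`
- `triosel.simstudy` — synthetic cohorts (single-SNP, maximal-LD block,
  exome-like burden), a compact Wright–Fisher forward simulator with gamma DFE,
  mate-and-select trio generation, recovery benchmark harness
- `triosel.cli` — `triosel simulate | infer | model-select | benchmark`

## CLI

Generate a synthetic cohort, then infer:

```sh
triosel simulate --scenario single-snp --n-trios 5000 --s -0.1 --h 0.0 \
    --seed 1 --out sim/
triosel infer --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --female-map sim/female.map --male-map sim/male.map \
    --s-lo 1e-4 --s-hi 1.0 --m-pilot 4000 --m-final 4000 \
    --t 0.1 --t-final 0.025 --seed 1 --out results/
triosel model-select --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --female-map sim/female.map --male-map sim/male.map --seed 1 --out results/
```

Every subcommand accepts `--config run.yaml` (flat YAML mapping of the same
option names; explicit flags win) and writes a `metadata.json` sufficient to
reproduce the run. Outputs are CSV/JSON; logs go to stderr.

De novo mutations: with `--denovo-L` and `--denovo-mu` set, simulated zygotes
receive Poisson(L·mu) extra heterozygous mutations; with the default zero rate,
variants present in a child but absent from both parents are stripped before
computing the observed summaries.

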