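# mitopop

Single-locus mtDNA phylogeography in Python: diversity summaries,
neutrality tests with coalescent significance, mismatch-distribution
expansion dating, and MDIV-style two-population isolation-with-migration
divergence estimation — plus a coalescent simulator that generates data
under exactly the models the estimators assume.

The package is built around the kind of dataset produced by a
range-wide mtDNA survey of a montane insect: an alignment of COI
sequences (596 bp by default), a population map assigning each sequence
to a collecting locality and each locality to a clade-level *haplogroup*
(for the bundled example, the four mountain-system lineages of the
Chinese white pine beetle *Dendroctonus armandi*: Minshan = MSM,
Qinling = QLM, Micang = MCM, Ta-pa = TPM), and/or a count-only
haplotype-frequency table.

## What it computes

* **Diversity** (`mitopop.sumstats`): segregating sites S, haplotype
  number, haplotype diversity Hd = n(1 − Σp²)/(n − 1) with Nei's
  standard error, nucleotide diversity π, mean pairwise differences k,
  and the mismatch spectrum.
* **Neutrality / expansion tests** (`mitopop.neutrality`): Tajima's D,
  Fu & Li's D (with outgroup) and D* (without), Fu's Fs via the Ewens
  sampling formula, Ramos-Onsins & Rozas's R2 — each with one-tailed
  p-values from coalescent simulation conditional on the observed S.
* **Mismatch analysis** (`mitopop.mismatch`): the stepwise-growth
  expected spectrum F_i(τ, θ0, θ1), least-squares estimation of
  (τ, θ0, θ1), SSD and Harpending's raggedness with parametric-bootstrap
  p-values and percentile CIs, and conversion of τ = 2ut to years.
* **Divergence dating** (`mitopop.divergence`): Bayesian
  isolation-with-migration MCMC over migration-labelled genealogies and
  (θ, M, T) under finite-sites HKY, posterior histograms and modes, and
  conversion to female effective size and calendar divergence times
  (T_pop = [(T·θ)/2L]·(1/μ)).
* **Simulation** (`mitopop.coalsim`): constant-size, sudden-expansion
  and two-population split coalescents with HKY mutation, seeded and
  fully reproducible.

## Worked example

Simulate a sudden-expansion sample at the strongest setting estimated in
the bundled study (τ = 4.56, θ0 = 0, θ1 = 16.98), then analyse it:

```bash
mitopop simulate --model expansion --tau 4.56 --theta0 0 --theta1 16.98 \
    -n 60 --out-fasta exp.fasta --out-map exp_map.tsv --seed 7
mitopop neutrality --alignment exp.fasta --popmap exp_map.tsv \
    --outdir out --seed 7 --n-sims 2000 --n-boot 500
```

`out/demography.tsv` then contains (columns abridged):

```
Haplogroup  n   TajimaD   p_D    FuFs        p_Fs   R2       SSD    p_SSD  tau_95CI          expansion_time_years
G1          60  -2.015**  0.005  -22.593***  0.000  0.036**  0.002  0.414  3.04 (1.69~4.21)  231815
```

A significantly negative Tajima's D, a strongly negative Fu's Fs and a
small R2, together with a small non-significant SSD, are the classic
signature of sudden demographic expansion. For this particular simulated
dataset the fitted τ̂ = 3.04 mutational units converts (596 bp, 1.1%/Myr
per-lineage, 1.5-year generations) to an expansion age of ≈ 2.3 × 10⁵
years — the `expansion_time_years` column.

The same library calls are available in Python:

```python
from mitopop import coalsim, neutrality, mismatch, sumstats

aln, _ = coalsim.simulate_dataset(
    coalsim.DemographyModel.stepwise_expansion(
        theta0=0, theta1=16.98, tau=4.56, n=60), seed=7)
print(neutrality.tajimas_d(aln).value)
fit = mismatch.fit_expansion(sumstats.pairwise_spectrum(aln),
                             n_boot=500, seed=7)
print(fit.tau, fit.ci_tau)
```

The bundled count table is available as
`mitopop.iohap.load_example_table()` (38 localities, 255 beetles,
haplotypes H01–H47 across the four mountain haplogroups).

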