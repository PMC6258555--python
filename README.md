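# divflow

Inference toolkit for **parallel ecotype divergence with gene flow** in
two-deme systems. The motivating setting is a pair of locally adapted
ecotypes — such as short-winged tidal and long-winged seasonal saltmarsh
beetles — genotyped at hundreds of short multi-locus fragments (RAD-like
data), where the questions are: *when* did the ecotypes split, *how much*
gene flow followed, *which parts of the genome* resist that gene flow,
and *how much* of the alternative ecotype's adaptive variation is already
standing in each population.

The package provides, as a library plus a `divflow` command line:

* **Simulation** (`divflow.simulate`): a structured-coalescent generator
  of multi-locus two-deme haplotype/genotype data under strict isolation
  (SI), isolation-with-migration (IM) and secondary contact (SC), with a
  fraction *P* of "genomic island" loci migrating at reduced rates
  *M*<sub>I</sub> and a fraction *Q* of loci with all effective sizes
  scaled by *hrf* (linked selection), plus an outgroup lineage for
  polarization.
* **Spectra** (`divflow.spectrum`): joint allele frequency spectra
  (JAFS) — building from genotypes, hypergeometric projection, folding,
  masking, and the standard SFS text format.
* **Demographic fitting** (`divflow.demography`): a Monte-Carlo
  expected-JAFS engine for the SI/IM/SC × {2M, hrf} family, Poisson
  composite likelihood with the mutation scaling θ profiled out
  analytically, replicated derivative-free optimization, and AIC model
  comparison (AIC = 2k − 2lnL).
* **Unit conversion** (`divflow.units`): μ = (d_out/2)/T_div from
  outgroup divergence; N_A = θ/(4μL), N_i = ν_i·N_A, T = 2·N_A·t,
  m = M/(2·N_A).
* **Statistics** (`divflow.popstats`): π, d_XY, Tajima's D, haplotype
  F_ST (1 − H_w/H_b), per-SNP Weir–Cockerham F_ST, outgroup-normalized
  divergence, LD r² decay, Mantel tests, and an empirical F_ST outlier
  scan.
* **Standing variation** (`divflow.standing`): ecotype-association of
  outlier alleles, per-individual carriage of alternative-ecotype
  alleles, and resampling accumulation curves with a closed-form
  hypergeometric expectation.
* **Filters & I/O** (`divflow.filters`, `divflow.vcfio`): presence/MAF/
  neutral-set/one-SNP-per-locus retention filters with reconciled
  reports; VCF, FASTA and TSV readers/writers.

See `docs/methods.md` for the model, its scaling conventions, the
optimizer design and known limitations.

## Worked example

Simulate a secondary-contact dataset and fit the secondary-contact
model to its joint spectrum:

```python
import numpy as np
from divflow import DemographyParams, ScenarioSpec, simulate_jafs
from divflow.demography import fit

truth = DemographyParams(nu1=1.0, nu2=0.5, t_s=1.0, t_sc=0.1,
                         M12=2.0, M21=2.0)
spec = ScenarioSpec(model="SC", params=truth, n1=8, n2=8,
                    n_loci=30_000, theta_locus=2.0, seed=13)
obs = simulate_jafs(spec)                      # observed JAFS (Poisson)
res = fit(obs, "SC", n_starts=8, engine_reps=2500, seed=213,
          symmetric_m=True)
p = res.params
print(f"lnL={res.lnL:.1f} AIC={res.AIC:.1f} theta={res.theta_hat:.0f}")
print(f"nu=({p.nu1:.2f},{p.nu2:.2f}) t_s={p.t_s:.2f} "
      f"t_sc={p.t_sc:.3f} M={p.M12:.2f}")
```

Output (exact under this seed and version):

```
lnL=-542.6 AIC=1095.2 theta=60771
nu=(1.01,0.49) t_s=0.94 t_sc=0.083 M=2.29
```

The fit recovers the simulated truth (ν₂ = 0.5, t_s = 1, t_sc = 0.1,
M = 2) from the 30,000-locus joint spectrum: the deme sizes within a few
percent, the split time within ~6%, and the migration rate within ~15%.
θ̂ ≈ 61,000 is the fitted mutation scaling of the whole dataset
(30,000 loci × θ_locus = 2). Converting to biological units:

```python
from divflow.units import CalibrationInputs, convert
est = convert(res.params, CalibrationInputs(d_out=0.03587,
                                            T_div_years=620_000,
                                            L=30_000 * 1_200))
print(f"mu={est.mu:.2e}/site/yr  N_A={est.N_A:.0f}  T_S={est.T_S:.0f} yr")
```

```
mu=2.89e-08/site/yr  N_A=14589  T_S=27375 yr
```

i.e. with a mutation rate calibrated from an outgroup at 3.6% divergence
and a 0.62 My split, this synthetic dataset corresponds to an ancestral
effective size of ~15,000 and an ecotype split ~27,000 years ago.

A full synthetic end-to-end run (simulate → filter → outlier scan →
haplotype statistics → JAFS fit → standing-variation curves):

```bash
divflow pipeline --demo --seed 1 --out-dir demo_run
```

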