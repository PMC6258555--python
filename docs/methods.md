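# Methods

## The model family

`divflow` studies a pair of demes (in the motivating system: a
short-winged "tidal" and a long-winged "seasonal" beetle ecotype) that
split from a single ancestral population and may have continued or
resumed exchanging migrants. All quantities are scaled by the ancestral
effective size `N_A`:

* sizes `nu1`, `nu2` are relative to `N_A`;
* times are in units of `2*N_A` generations (`t_s` = split, `t_sc` =
  onset of secondary contact, measured backward from the present);
* migration is the population rate `M_ij = 2*N_A*m_ij`, where `m_ij` is
  the per-generation fraction of deme *i* that are new migrants from
  deme *j*; backward in time a lineage in deme *i* jumps to deme *j* at
  rate `M_ij` per unit of scaled time;
* the mutation scaling is `theta = 4*N_A*mu*L`.

Three divergence scenarios (SI: no gene flow, IM: continuous gene flow,
SC: gene flow only since `t_sc`) combine with two kinds of genomic
heterogeneity: a fraction `P` of loci ("genomic islands") migrates at
reduced island rates `MI_ij` ("2M" models), and a fraction `Q` of loci
has every effective size multiplied by `hrf` in (0, 1], emulating the
local reduction in `N_e` caused by selection at linked sites ("_hrf"
models). `P` and `Q` act independently, so the locus-class weights are
the products `(1-P)(1-Q)`, `P(1-Q)`, `(1-P)Q`, `PQ`.

Two modelling choices that the scenario family leaves open are fixed as
follows and are switchable in code: `hrf` rescales the deme sizes in
*every* epoch including the ancestral deme (linked selection is treated
as a property of the locus, not of an epoch), and island loci use the
island rates in every epoch in which migration is active at all.

## Simulator

`divflow.simulate` implements the backward-in-time structured coalescent
for this scenario space directly (a Gillespie walk over coalescence and
migration events with piecewise-constant rates; `divflow._kernel`,
numba-compiled). Mutations follow the infinite-sites model: a locus of
length `L` receives `Poisson(theta_locus/2 * total branch length)`
segregating sites at distinct positions; back-mutation is ignored, which
matches the frequency-spectrum theory used by the fitting engine. There
is no recombination within a locus and no sequencing-error or coverage
model: loci are exchangeable gene trees, which is the idealization of
RAD-tag data in which each short tag is one non-recombining haplotype
block. Passing tests therefore validate the method's statistics and
inference machinery, not robustness to genotyping error, within-locus
recombination or reference bias in real RAD data.

An optional outgroup lineage stays separate until `outgroup_time` and
then coalesces with the ingroup root at rate `1/size_ancestral`. Its
allele defines the ancestral state (allele 0), enabling polarized
spectra and divergence normalization. The expected pairwise divergence
to the outgroup is `theta*(outgroup_time + size_ancestral)` per locus,
which the tests verify.

Diploid individuals are formed by randomly pairing haploid copies within
a deme once per dataset (no inbreeding); deme 0 is labelled ecotype "S"
(habitat code -1, tidal), deme 1 ecotype "L" (+1, seasonal).

Default study conditions used by the shipped studies: `n1 = n2 = 8`
haploid copies for spectrum fitting, `theta_locus = 2` (a ~1.2 kb RAD
locus in a moderately diverse insect), 1,200 bp loci, and datasets of
300-30,000 loci depending on the question (30,000 loci for parameter
recovery, 10,000 for model selection, 400 for the haplotype-statistics
and standing-variation pipeline). These sizes give each study clear
statistical resolution while keeping any single study in the minutes
range on one core.

## Expected spectra and the composite likelihood

The expected joint allele frequency spectrum (JAFS) of a heterogeneous
model is the `P`/`Q` mixture of homogeneous expected spectra. Each
homogeneous spectrum is estimated by Monte-Carlo: branch lengths are
accumulated by joint descendant-count class over `nreps` genealogies
(default 3,000-15,000; the precision control), giving
`E[sites in cell (i,j)] = theta/2 * E[T_ij]`. Every replicate genealogy
runs on its own RNG substream derived from a fixed engine seed, so
repeated evaluations are deterministic (common random numbers) and the
likelihood is an optimizable function of the parameters.

The fit criterion is the Poisson composite likelihood over unmasked
cells with `theta` profiled out analytically
(`theta_hat = sum O / sum F`), which is the standard choice for SFS
fitting and removes one free dimension; the corners (0,0) and (n1,n2)
are always masked as uninformative. A cell with observed sites but zero
expected mass raises an explicit precision error rather than being
clamped.

## Optimization

The Monte-Carlo likelihood surface is jagged at the scale of the engine
noise (tens to hundreds of log-likelihood units for dense spectra),
and the model family has two soft ridges: an overall time/size scaling
ridge pinned only by the ancestral epoch, and, in secondary-contact
models with recent contact, a migration-flux ridge along which only the
product `M * t_sc` is sharply identified. `fit()` is built around these
facts:

1. parameters are optimized in log10; `t_sc` is parametrized as the
   ratio `t_sc/t_s` (making the constraint structural) and, in SC
   models, each migration rate as the flux `M * t_sc`, which aligns the
   flux ridge with a coordinate axis;
2. a coarse factorial probe grid (subsampled to `probe_budget` points,
   scored at one fifth of the engine precision) locates candidate
   basins;
3. Nelder-Mead runs start from the best probes and then from
   `U(1/3, 3)` perturbations of the best point so far (`n_starts` runs
   in total; the replicate table reports all of them, flagging the best
   five);
4. coordinate line scans from the incumbent (9 points per axis, two
   cycles) escape ridge-stuck simplexes cheaply;
5. a final simplex at five-fold engine precision polishes the optimum,
   and the reported log-likelihood is evaluated at that precision.

Convergence uses `fatol = 0.05` log-likelihood units and
`maxiter = 300` per simplex run; bounds are enforced by a finite
penalty. AIC is `2k - 2lnL` with `k` the number of free parameters;
`compare_models` ranks models by AIC and records per-model failures
without aborting the comparison.

Known limitation: with Monte-Carlo noise the optimizer can still settle
on a scaling-ridge point for an individual dataset (observed for roughly
one dataset in ten at the default precision in the recovery study);
medians across replicate datasets are the supported accuracy statement,
and raising `engine_reps` tightens individual fits at linear cost.

## Unit conversion

With an outgroup per-site divergence `d_out` accumulated over
`T_div_years` on two branches, the yearly mutation rate is
`mu = (d_out/2)/T_div_years`. Then `N_A = theta/(4*mu_gen*L)`,
`N_i = nu_i*N_A`, times convert by `2*N_A` generations, and migrant
fractions by `m = M/(2*N_A)`; `nu_i*M_ij` is the effective number of
immigrant gene copies per generation. `gen_per_year` defaults to 1 (one
generation per year, typical for temperate carabid beetles) and is an
explicit parameter, not an assertion.

## Haplotype and SNP statistics

Per-locus statistics operate on 0/1 alignments: nucleotide diversity and
`d_XY` are mean pairwise per-site differences (within / between groups);
Tajima's D uses the standard constants as functions of sample size and
is flagged undefined (None) when nothing segregates. Haplotype `F_ST`
is `1 - H_w/H_b` with the two groups' within-group diversities weighted
equally; the estimator is reported as declared, without claiming to be
any particular variant in the literature's family of haplotype F-
statistics. Note that it is unbiased around zero only over sampling --
applying it to a group literally duplicated into both slots gives a
negative value by construction. Per-SNP `F_ST` uses the Weir-Cockerham
(1984) variance components with ratio-of-averages aggregation across
SNPs; negative per-SNP estimates pass through unclamped.

Dividing `pi_tot` and `d_XY` by the locus's divergence to the outgroup
removes locus-to-locus mutation-rate variation; the normalized values
are flagged undefined when the outgroup divergence is zero.

LD is the squared dosage correlation of SNP pairs with pairwise-complete
individuals and an optional minor-allele-frequency sub-filter (0.1 in
the decay summaries), binned by distance. The Mantel test correlates
off-diagonal entries of two distance matrices and permutes rows and
columns of the second jointly; `p = (1 + #{r_perm >= r_obs})/(1 +
n_perm)`.

The empirical outlier scan ranks per-SNP `F_ST` in its own empirical
distribution (support = -log10 of the upper-tail probability, flags
strictly above the chosen quantile). It is a deliberately simple,
assumption-free stand-in for Bayesian outlier machinery and shares only
its interface: a per-SNP support score feeding the downstream steps.

## Standing variation

Given outlier SNPs thinned to the single best-supported SNP per locus
(ties broken by position, then id), each SNP's alleles are assigned to
an ecotype by the pooled-frequency majority across all individuals of
that ecotype; exact ties are flagged unassignable and excluded. The
majority rule is symmetric and deterministic; assignment per population
pair is available as an option. For a focal individual, carriage is the
fraction of outlier loci at which its genotype holds at least one copy
of the allele associated with the *other* ecotype (missing genotypes
leave that individual's denominator). The accumulation curve draws, for
each N, `reps` random N-subsets of the focal cohort without replacement
(pooled across populations by default, per-population as an option) and
averages the fraction of outlier loci covered by at least one carrier;
missing genotypes count as non-carriers within a replicate
(conservative). The closed-form expectation
`sum_l [1 - C(n-k_l, N)/C(n, N)]/L` is provided as an oracle and is
provably non-decreasing in N.

## Filters and I/O

SNP retention applies presence (>= 80% of individuals called), then
strict minor-allele frequency (> 0.01 on called alleles), then optional
neutral-set exclusion (drop every SNP on a locus carrying any SNP above
a support threshold; locus-level granularity, configurable), then an
optional seeded one-SNP-per-locus thinning. Presence precedes MAF so
frequencies are computed on adequately genotyped sites; the report
counts removals per stage and must reconcile with the output size.
Read-depth and genotype-quality filtering belongs to upstream variant
calling and is assumed done.

VCF v4.2 (biallelic SNPs, GT only; cyvcf2 reader, minimal text writer),
FASTA haplotypes with `sample|pop|ecotype|locus[|outgroup]` headers, the
row-major SFS text format (`"n1+1 n2+1 [folded|unfolded]"`, entries,
0/1 mask), and TSV tables for everything else. Positions are 0-based
half-open in memory and 1-based in VCF.

## Numerical notes

* Spectrum projection is the exact hypergeometric redistribution; sites
  with missing calls are projected per-site from their callable counts
  and sites callable below the target size are dropped.
* Folding combines complementary cells, halves the equal-frequency
  boundary, and masks above the minor-allele diagonal.
* The Poisson likelihood treats `0 * log(0)` as 0; `theta_hat` absorbs
  any positive scaling of the model spectrum.
* All randomness flows from explicit seeds (dataset seed, fit seed,
  engine seed, resampling seed); identical seeds give bit-identical
  outputs.
* Tajima's D has a known finite-sample offset (measured mean ~ -0.06 to
  -0.08 at n = 10 under neutrality): the exact zero-mean quantity is
  the unnormalized `pi - S/a1`, which is what the neutrality tests pin
  at Monte-Carlo precision.
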