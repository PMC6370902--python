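# Methods

This note documents the statistical model behind `wgsdepth`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and design stance

The package evaluates the *downstream* of a WGS pipeline: given genotype
calls at a set of depths, how do concordance, filter behaviour, Ts/Tv and
HLA typing accuracy move with coverage?  Everything upstream — read
simulation, alignment, duplicate marking, the callers themselves,
model-based recalibration (VQSR) and the external HLA typers — is out of
scope and replaced by a generative emulation of its outputs.  This keeps
the whole experiment seeded, text-only and runnable in well under a
minute per sweep at desk scale.

## Truth catalog

`generate_truth` places `n_variants` unique 1-based positions on
`genome_length` effective (non-N) bases and rejects catalogs larger than
the genome.  Defaults: 20,000 sites on 10 Mb, 18% indels (a genome-like
indel share of a single individual's variant set), transition probability
0.677 among SNVs (Ts/Tv ≈ 2.1, the genome-wide human expectation).

* **AAF spectrum.**  Site frequencies are Beta(0.3, 0.7) by default — a
  skewed, site-frequency-like spectrum that populates all five strata
  (≥0.5, 0.1–0.5, 0.05–0.1, 0.01–0.05, <0.01) used for stratified
  concordance.  `AAFSpec(fixed=p)` pins every site for analytic checks.
* **Genotypes.**  Hardy–Weinberg draws from each site's AAF.  Off-array
  sites represent the subject's own variants and are conditioned on
  carrying an alternate allele; on-array sites may be hom-ref (the panel
  scores reference sites too).
* **Array subset.**  A fraction (default 0.16) of SNVs is flagged
  on-array and given QC metadata: call rate 1 − Exp(0.004) (≈8% below
  0.99), HWE p uniform with a 1% spike of genuine failures, a 0.5%
  multi-allelic flag, and an array MAF drawn from a Beta centred on the
  AAF with concentration 30.  The deliberate looseness of that last draw
  emulates the frequency difference between the array QC cohort and the
  AAF reference population; without it, MAF-based QC would empty the
  <0.01 AAF stratum entirely.

Array-side QC (`qc_filter_truth`) retains on-array sites with call rate
≥ 0.99, HWE p ≥ 1e-6, MAF ≥ 0.01 and a single alternate allele.

## Call-set emulation

For one dataset at target depth d with seed s (derived as
`base_seed + 1000·depth_index + replicate_id`):

1. **Coverage.**  Per-site read count N ~ Poisson(d); a site is callable
   with N ≥ `min_reads` (default 2).  Depth is per-site, not per read
   position — the evaluation consumes genotype calls, and per-site
   Poisson sampling reproduces the depth–missingness law (missing mass =
   Poisson CDF below the floor) exactly.
2. **Genotyping.**  Alt-read count k ~ Bin(N, p) with p = e, ½, 1−e for
   the three truth genotypes and per-read error e (default 0.001); the
   emitted genotype maximises the binomial likelihood over
   {hom-ref, het, hom-alt}, ties resolving toward reference.  Het
   miscalls therefore decay like 2·2⁻ᴺ and the genotype error is
   mechanically depth-dependent.  Setting `read_sampling=False` copies
   truth genotypes verbatim, after which four constant rates
   (`het/hom/ref/alt_error_rate`, all default 0) can inject exactly
   known error components — this is the configuration used for
   parameter-recovery tests, where CR, FNR and FPR have closed-form
   expectations.
3. **Record content.**  Called non-reference sites become VCF-style
   records with DP = N and the seven annotations.  Clean annotation
   values are truncated into the passing range of the record's variant
   type (e.g. QD ~ N(20, 5) clipped at 2.0, SOR ~ Gamma(2, 0.5) capped at
   the threshold).  With probability
   `low_cov_artifact_rate · exp(−d/low_cov_artifact_scale)` (defaults
   0.05, 5) one item, chosen uniformly from the type's rule set, is
   replaced by a failing value — annotation quality improves with
   coverage.  For SNVs an additional HaplotypeScore artifact switches on
   above 100× and grows logarithmically to 16% at 410×, emulating
   haplotype-count inflation in ultra-deep data; the hard filter then
   visibly depresses high-depth concordance, as a rule-based filter does
   on deep libraries.
4. **False positives.**  Poisson(`fp_site_rate`·n) spurious records
   (default rate 0.001) at uniform non-truth positions, thinned by the
   same coverage floor, with uniformly chosen alternate alleles (Ts/Tv
   ≈ 0.5, diluting the call-set ratio when their share is high).
5. **Indel representation.**  With probability
   `0.5·exp(−d/120)` an indel's reported allele strings are jittered by
   one base (assembly/left-alignment ambiguity).  Because the all-reads
   indel rule requires identical ref and alt strings, indel concordance
   with the full-depth set stays near 55–60% at ~17× and approaches 95%
   only past ~300× — the mechanism by which the synthetic data reproduces
   the large SNV/indel accuracy gap.  The decay scale (120) and ceiling
   (0.5) were fixed once from those two anchor behaviours.

**Depth-stage ledger.**  The six stages are RRD → RRDaT → MRD → URD →
VD → VDaF.  The target depth is URD (the standard depth metric);
upstream stages are reconstructed with trimming retention 0.99, mapping
retention 0.98 and a duplicate loss `0.304·d/(d+19.6)` that saturates
with depth, calibrated so a ~500× library loses ≈31% of raw bases by the
variant stage and a ~10× library ≈13%.  VD and VDaF are mean DP over all
and over passing records; at very low coverage conditioning on N ≥ 2
pushes VD far above URD (the ~45-fold low-depth inflation: at URD 0.052
the called-site mean is ≈2, and the printed ratio 2.36/0.052 = 45.38).

## Replicates and subsampling

Depths strictly below 45× get 10 seeded replicates and analysis metrics
are unweighted replicate means (SDs are emitted alongside for
diagnostics); at or above the threshold a single dataset is used.  The
boundary at exactly 45× is read as excluded-from-replication.
`subsample_fraction` implements samtools-style Bernoulli thinning
(independent retention, order preserved), so thinning at f then f′ is
distributionally a single pass at f·f′.

## Hard filter

Exactly the printed thresholds, strict inequalities (a record at QD = 2.0
passes), absent annotations pass — the VariantFiltration convention,
adopted because rank-sum annotations are undefined at hom-alt sites in
real caller output.  `exclusion_rates` reports, per item, the percent of
records failing that item (a record failing k items counts toward each).
VQSR is represented only by a pass-through strategy behind the same
`filtration` interface; training a Gaussian-mixture recalibrator is a
non-goal.

## Concordance definitions

The 3×3 matrix plus alternate-discordant class conserves the panel:
9 cells + alt-discordant = n sites, always.  Absent or genotype-missing
calls score hom-ref.  Matching is by (chrom, pos, ref) with the alternate
allele compared semantically; multi-allelic query records are excluded
from panel comparison (mirroring the array-side exclusion) and counted.
The index formulas are in the README; NTPR's denominator is the panel
sites at which the query called non-reference *including*
alternate-discordant sites, and its numerator the concordant
non-reference cells — the published source gives the confinement ("sites
called in the WGS data") but not the cell formula, so this reading is
isolated in `compute_metrics` for easy revision.  Heterozygote-only CR is
the RA row of the matrix (alt-discordant sites, whose truth genotype the
matrix does not retain, are outside it).  The all-reads comparison uses
the maximum-depth dataset of the schedule as the full-reads reference.

## HLA scoring

Per-allele credit: the score of a called genotype is the multiset
intersection with the truth pair, halved — truth {X, X} vs call {X, Y}
scores 0.5.  Per-allele credit is required for fractional per-gene
accuracies (e.g. 45.8%) to arise from means over 10 replicates.
Gene accuracy = 100·mean(replicate scores), one decimal half-up; tool
average = unweighted mean over the genes the tool types (six for
PHLAT/HLA-VBseq, which cannot type DPA1/DPB1; eight otherwise).  The
generator's default per-tool, per-gene miscall rates encode the observed
heterogeneity of the five tools at the 13.7× reference depth and scale as
`(13.7/d)^0.7` (capped at 1), so accuracy saturates quickly above ~20×.
A miscall draws a decoy allele of the same gene outside the truth
genotype.

## Numerical conventions

* Reported depths and accuracy percentages round half-up to one decimal
  (`util.round_half_up`); internal computation is unrounded.
* Genotype-likelihood ties resolve toward the reference genotype.
* Ts/Tv is undefined (None/NaN) with zero transversions; NTPR is
  undefined when the query called nothing on the panel; variant depth is
  an error on an empty record set.
* All randomness flows through `numpy.random.default_rng` seeded from
  `base_seed`; identical config + seed gives byte-identical TSV/VCF
  outputs.
* The default 54-level schedule is the union of a 30-point log grid
  (0.05×–410×) and a 25-point linear grid (10×–410×) sharing one
  endpoint; the exact historical levels are not published, so the
  schedule is config-overridable.

## Problem sizes

Tests run at 2,000–20,000 sites; the acceptance sweep uses 30,000 sites
on 10 Mb over 12 depths (replicates per the <45× policy), sizes at which
binomial noise on panel metrics is ~10⁻³ and every check completes in
seconds to a minute or two.

## Limitations

The synthetic data has no linkage structure, mapping-difficulty strata,
GC/coverage bias or error-rate heterogeneity along the genome; false
positives are spatially uniform and independent across datasets, whereas
real artifact sites recur.  Passing tests therefore demonstrate the
correctness of the evaluation machinery and the qualitative
depth–accuracy laws built into the generator, not the absolute accuracy
of any real caller.  Headline depth thresholds measured on real
ultra-deep data (which depth first exceeds 99% CR, etc.) depend on that
single genome and pipeline and are not reproduced quantitatively here;
the acceptance sweep reports where the *synthetic* study conditions place
them.  Joint calling, imputation, structural variants and G-group HLA
nomenclature conversion are out of scope.
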