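# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `fieldeqtl`. It states
only behaviour that the test-suite or `scripts/acceptance.py` computes.

## Setting

Two parental rice cultivars (coded `P1`/`P2`) and a panel of chromosome
segment substitution lines (CSSLs) — each carrying one contiguous donor
segment in an otherwise recurrent background — are grown in the field in
staggered transplant sets and sampled bihourly on a number of days across
the season; each sample yields a gene-level RNA-Seq count vector. Two
mosaic backcross-inbred lines (BILs, ~18 % donor genome in contiguous
blocks) are held out of all fitting and used only for validation. Markers
are SSRs with known physical positions; weather is minute-resolution air
temperature and global solar radiation.

## Preprocessing

* Samples with total read count ≤ 10⁵ are dropped; genes detected
  (count > 0) in ≤ 20 % of samples are dropped. Both filters are
  idempotent; the detection filter of a training season can be imposed on a
  validation season so models and data share a gene list.
* Expression is `log2(rpm + 1)`, rpm recomputed over the retained gene set
  (so rpm sums to 10⁶ exactly per sample before the pseudo-count). The
  pseudo-count keeps zero counts defined and is monotone.
* Precision weights are gene-level: genes are binned by the rank of their
  mean log2rpm (≤ 20 bins), the mean-variance trend v(m) is the within-bin
  median of mean squared residuals about the gene mean, and every
  observation of gene g gets weight 1/max(v(m_g), 10⁻⁶). A gene-level
  scheme (rather than observation-level) keeps weighted least squares
  coefficients identical to unweighted ones within a gene, which both
  simplifies and stabilises model selection; fewer than 10 genes falls back
  to uniform weights with a warning.
* Scaled age = (fractional days since sowing) / (days from sowing to
  heading for that line and transplant set); heading is 1.0 by definition.
  Fractional days use minutes since midnight / 1440.
* Coarser weather series are linearly interpolated to 1-minute resolution
  (original points preserved exactly). Dark periods are maximal intervals
  with radiation strictly below 0.3 kJ m⁻² min⁻¹.
* The between-sample correlation matrix is the Pearson correlation of
  log2rpm columns, each centred by its mean over genes; zero-variance
  samples yield flagged NaN rows.

## Per-parent environment-response models

For each gene and parent, log2rpm is a linear model over up to three terms:

* clock: one 24 h harmonic, `a·cos(2πh/24) + b·sin(2πh/24)`;
* age: linear in scaled age;
* environment: one gated-window feature `E = mean over [t−w, t) of
  max(x(u) − θ, 0)` with variable x ∈ {temperature, radiation},
  window w ∈ {1, 2, 4, 8, 24, 48, 72} h and gate θ at the {0, 25, 50, 75} %
  quantiles of the variable's season-wide distribution (deduplicated).

Every term subset × grid point is fitted by weighted least squares on the
background-concordant samples of that parent (parents plus same-background
CSSLs; BILs excluded), and the fit minimising
`AIC = n·ln(max(RSS_w, 10⁻¹⁰)/n) + 2k` wins. The RSS floor keeps noiseless
(saturated) fits comparable — ties then resolve toward fewer parameters.
`k` counts coefficients **plus 3 for an environmental candidate**: its
variable, window and gate are searched over the grid, and unless those
effective parameters are charged, the best of ~200 correlated grid fits
beats the 2-per-parameter penalty for most genes with no true weather
response (measured: 29/100 correct term sets uncharged, 89/100 charged,
with environmental-signal recovery at signal-to-noise 2 unchanged at
100/100). Singular candidate designs (e.g. all samples at one time of day)
are skipped with a warning, which realises "drop the offending term".

Prediction under arbitrary weather is the plain linear form with the
fitted coefficients; no refitting ever happens downstream.

## Parental polymorphism test

The statistic is a shared-vs-separate weighted RSS reduction with one fixed
column set — the union of the two parents' AIC-selected terms, the
environmental spec taken from the lower-AIC parent: the shared arm refits
that structure on all samples, the separate arm refits it per background,
`T = RSS_shared − (RSS_1 + RSS_2)` (weighted). Using each parent's own
selected structure in the separate arm, or reusing the fitted coefficients
without refitting, leaks the observed grouping into the statistic and
drives null p-values toward zero (measured null-gene median p ≈ 0.19 and
≈ 0.02 respectively, versus ≈ 0.4 for the union-structure statistic).

The null permutes background labels at the **line** level (all samples of a
line move together, preserving within-line correlation), with
`p = (1 + #{T_null ≥ T})/(n_perm + 1)`; BH across genes, polymorphic at
q < 0.05.

## Marker scan and eQTL calls

For a polymorphic gene, per-sample squared prediction errors under each
parental model are aggregated per line (`e_P1`, `e_P2`); marker m assigns
each line the model matching its allele, giving
`RSS_m = Σ_line e_allele(line)` and `T_m = RSS_BG − RSS_m` against the
background assignment (which is always an explicit candidate).

**Permutation null.** Marker allele columns are permuted across lines
*within background strata*. Allele columns in a substitution panel are
background-aligned — every line carries its background allele outside its
donor segment — so unrestricted permutation produces wholesale
misassignment that no real marker resembles (measured: 65 % of
complete-null genes called). Within-stratum exchange matches the actual
null hypothesis: which lines of a background carry the donor segment.
One shared permutation set yields per-marker empirical p-values
(`p_m = (1 + #{T_null ≥ T_m})/(n_perm + 1)`) and a per-gene genome-wide
maximum-T null.

**Error control is hierarchical.** Genes enter the scan only after passing
the polymorphism test at FDR 0.05; a gene is then called when its
genome-wide max-T permutation p is < 0.05. The max-T p has an irreducible
floor: with probability ≈ 1/(number of segments per background) a
permutation relocates the causal lines' error profiles coherently onto
another segment, reproducing the observed maximum exactly. The floor
(≈ 0.025–0.05 at the default panel) makes BH across genes on these
p-values knife-edged — across simulation seeds it returned 59/0/45/49
called genes out of ~60 planted 4σ effects — whereas the hierarchical rule
is seed-stable (recovery 0.90–0.98) and keeps the complete-null call
fraction at ≈ 0.05. BH-adjusted q across scanned genes is still computed
and reported on every call.

**Blocks.** Within a called gene, markers whose T exceeds the 95th
percentile of the max-T null are grouped into runs of contiguous markers
with identical assignment signatures; such markers are mathematically
indistinguishable in the panel, so the block is the unit of resolution.
The representative marker is the max-T member (ties to the smallest
position). Calls are cis when the representative lies on the gene's
chromosome within 2 Mb (configurable), else trans.

**Multi-eQTL.** Starting from the max-T block, further significant blocks
are accepted by forward selection when the combined assignment strictly
lowers the residual error. Combination rule: each selected block votes its
consensus allele for a line (ties to the representative); any
non-background block vote switches the line to the donor parent's model —
the majority among non-background votes, which is degenerate with two
parental alleles. A literal majority over all blocks can never differ from
the background in a single-segment panel (no line carries two donor loci),
which would make two-locus architectures undetectable by construction.

## Evaluation

* **Cross-environment prediction**: for each called gene, predictions on a
  new season's samples under the multi-eQTL assignment and under the
  background assignment, from the same fitted models. A gene counts as
  improved when its weighted squared prediction error is strictly smaller
  under the eQTL assignment; the improved fraction is taken over genes
  whose two assignments actually differ (ties count as not improved).
* **BIL permutation test**: over the called genes, the total weighted
  prediction error for one BIL under its eQTL-model assignment is compared
  with the distribution obtained by permuting the BIL's allele vector
  across markers (allele counts preserved), with
  `p = (1 + #{null ≤ observed})/(n_perm + 1)` (never zero) and the 0.1 %
  percentile of the null as the reported threshold. Assignments use the
  block-consensus rule above: a recombination breakpoint may fall inside a
  call block in a mosaic genome, and the consensus is the best available
  localisation. Exhaustive enumeration replaces sampling for ≤ 7 markers.
  Pure-P1 and pure-P2 totals are reported as references. A uniform allele
  vector is degenerate and returns p = 1 with a warning.
* **Enrichment**: two-sided Fisher exact tests per annotation term against
  the analysis universe, BH-adjusted; a term covering every gene has odds
  ratio 1 and p = 1 by convention.

## Synthetic data

The generator is first-class, tested code; its defaults are the study
conditions used throughout the tests and the acceptance script.

* **Panel**: 12 chromosomes × 12 markers (2.5 Mb spacing on 30 Mb
  chromosomes), 40 CSSLs per background whose segments tile the genome
  (identical tilings in the two backgrounds), 2 parents, 2 BILs built from
  random contiguous donor blocks (geometric lengths, mean 5 markers) until
  the donor fraction reaches 18 % with a ceiling keeping it within ~5
  points.
* **Weather**: minute resolution; temperature = seasonal half-sine trend
  (18→26→18 °C) + diurnal cosine (amplitude 5 °C, maximum 14:00) + slow
  AR(1) noise (per-minute φ = 0.999, stationary sd 1 °C); radiation =
  daylight half-sinusoid (seasonal daylength 12–14.2 h, peak
  3.3 kJ m⁻² min⁻¹) × per-day Beta(4,2) cloud factor, exactly zero at
  night. Daily temperature maxima fall in 12:00–16:00 on ≥ 95 % of days.
* **Schedule**: sampling days evenly spaced across the season (default 8),
  12 bihourly time points from 16:00 to 14:00 the next day; each
  (line, transplant set) is sampled once per day at a time point dealt by a
  stratified shuffle, so per-line totals differ by ≤ 1. Two transplant
  sets sown 14 days apart; heading days drawn per (line, set) around
  parent-specific means (100 vs 90 days, sd 3) so scaled age genuinely
  diverges between backgrounds. Optional late-season dropout (default 0).
* **Expression**: 300 modelled genes; clock/age/env terms included with
  probabilities 0.6/0.5/0.5 and effect scales ~1 log2 unit (env
  coefficients scaled to a target effect via the realised feature sd);
  20 % of genes are polymorphic with a planted ±2 log2 intercept shift
  (4× the noise sd of 0.5) and, half the time, a damped clock amplitude.
  75 % of polymorphic genes are cis (controlling marker = nearest marker
  to the gene), 25 % trans (random marker on another chromosome); an
  optional fraction get a second controlling locus under the
  any-substituted-locus rule. Latent log2rpm = controlling-genotype
  parent's model + N(0, 0.5²); counts = round(max(2^y − 1, 0) ×
  library/10⁶) with library sizes uniform on [3, 6]×10⁶ (a negative
  binomial switch exists for overdispersion studies).
* **Filler genes**: 30 high-abundance (µ ∈ [15, 17] log2rpm),
  non-polymorphic, intercept-only transcripts dominate library totals.
  In a real study rpm normalisation runs over ~24k genes and no single
  eQTL moves a sample's total; on a 300-gene panel the 60 planted shifts
  would otherwise move totals by background and imprint a
  genotype-correlated compositional shift on *every* gene (measured: ~85 %
  of null genes spuriously flagged polymorphic without filler).
* **Validation seasons** reuse the planted truth and panel with new
  weather (seasonal trend shifted +2 °C by default), a fresh shorter
  schedule, and fresh noise and library sizes.

What the generator does **not** emulate: linkage disequilibrium beyond the
segment structure, genotyping error or heterozygous residues, batch or
library-preparation effects, count overdispersion under the default
lognormal noise, realistic genome coordinates, or between-year effects
other than the weather shift. Passing tests therefore demonstrate
correctness and calibration of the machinery under the stated generative
assumptions, not performance on any real dataset.

## Problem sizes and determinism

The default study is 84 lines × 2 sets × 8 days = 1,344 samples × 330
genes, with 200 permutations for both the polymorphism test and the scan
(500 for the null-calibration run, 2,000 for the BIL test); the full
pipeline runs in a few seconds on one CPU. All randomness flows from
`numpy.random.default_rng` seeds derived from a single root seed; the same
seed reproduces byte-identical outputs.

## Known limitations

* The scan's resolution is the assignment-signature block; a single causal
  marker inside a wide block cannot be pinpointed, and the smallest-position
  representative can mislabel a cis gene as trans when the block spans more
  than the cis window. Only trans labels are scored in the recovery tests.
* The genome-wide permutation p has the relabeling floor described above;
  power therefore depends on panel segment count, and weak effects near the
  floor are missed (recovery 90–98 % across seeds at the planted 4σ
  effects).
* Gene-level precision weights treat biological dynamic range as noise for
  highly dynamic genes; observation-level weights would require a replicate
  structure the design does not provide.
* A single clock harmonic and a single environmental term per gene are
  deliberate restrictions; interactions (clock × weather) and multi-scale
  weather responses are out of scope.
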