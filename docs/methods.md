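# Methods

This note documents the models and procedures implemented in `hlamm`, the
conventions chosen where the design was genuinely open, and what the
synthetic data generator does and does not emulate.

## Mismatch definitions

Molecules are compared at two resolutions. *Antigen* mismatch (antMM) is
counted at serological split resolution: the number of distinct donor
splits at a locus absent from the recipient's splits (0–2; a homozygous
donor antigen counts once). *Molecular* mismatch is defined at the
two-field allelic level: a donor molecule is mismatched when it is absent
from the recipient's genotype. The DQ molecule is the cis αβ heterodimer —
the DQA1 aligned sequence concatenated with DQB1, in that fixed order —
because DQ serology and DQ antibody reactivity are properties of the
dimer; DR is scored on the β chain alone (DRB1), since DRA is effectively
invariant. DRB3/4/5 products are carried as a single haplotype slot
("DRB345"); they contribute to class II peptide presentation and to the
class II comparator sequence set, but do not generate their own mismatch
records.

Alignment positions are 1-based over the provided alignment; the package
never renumbers into mature-protein coordinates — input files carry the
authoritative alignment. A gap symbol is treated as a distinct residue, so
a gap-vs-residue difference counts as a mismatch (a conservative,
testable convention).

### AAMS

For donor aligned sequence *d* and recipient comparator sequences *C*
(same alignment), AAMS = #{positions *i* : *d*ᵢ ∉ {*c*ᵢ : *c* ∈ *C*}}. The
comparator set defaults to the recipient's alleles at the same locus; a
config switch widens it to all same-class recipient alleles sharing the
alignment length, matching the original class-wide formulation of the
amino-acid mismatch algorithm. The per-locus default was chosen for
interpretability; the switch preserves fidelity to the original method.

### EMS3D

Structure-based electrostatic dissimilarity is consumed as a precomputed
pairwise table (donor molecule, comparator molecule) → score; computing it
from structure (homology modelling, Poisson–Boltzmann electrostatics) is
out of scope here. Per donor molecule the pairwise scores against the
recipient's (one or two) molecules are aggregated by **minimum** — the
donor is scored against its most electrostatically similar recipient
molecule — with mean available by config. The aggregation choice is
recorded in output metadata; nothing downstream depends on it beyond the
score values themselves.

### Peptide-based scores (netMHC, netMHC1k)

All donor 15-mers absent from the recipient's sequences (gaps removed
before windowing; DQ chains windowed separately so no artificial
junction-spanning peptides arise) are submitted to a class II binding
predictor with the recipient's DRB1, DRB3/4/5 and DQ heterodimers as
presenting molecules. Each prediction returns a 9-mer core, an affinity in
nM and a percentage rank. Scores are counts of **unique** 9-mer cores
among predictions passing a filter, pooled across presenters (a core
passing with any presenter counts once; per-presenter summing is
available by config):

- netMHC1k: affinity ≤ 1000 nM (the permissive threshold used by
  indirect-epitope counting tools);
- netMHC: affinity ≤ 500 nM **and** rank < 2% (strict rank, inclusive
  affinity boundaries).

The subset relation of the filters guarantees netMHC ≤ netMHC1k for every
molecule, which the test suite asserts cohort-wide.

The external neural-network predictor is out of scope; a
`TabularPredictor` adapter ingests its tabular exports. For simulation and
testing a deterministic mock stands in: the core is the window maximising
a presenter-specific positional weight table, affinity is a keyed-hash
uniform draw mapped log-uniformly onto (1, 50000) nM, and rank is the
empirical percentile of that affinity in a fixed presenter-specific
reference distribution of 10,000 seeded random-peptide affinities — so
rank is weakly monotone in affinity within a presenter by construction.

## Imputation

Two-field genotypes are recovered from split-serotype typing by
enumerating all haplotype pairs from a population frequency table whose
implied split multiset matches the typing at every typed locus (A, B, DR
via DRB1, DQ via DQB1). Pair probability is 2·f₁·f₂ (f² for a homozygous
pair); the maximum-probability pair is assigned, with ties broken
lexicographically by allele names so imputation is deterministic. A single
reported split is treated as split-level homozygosity. Typings already at
allelic resolution pass through unchanged. Persons with no compatible pair
raise an "untypeable" error and are excluded with a logged count;
probability-weighted averaging over pairs is deliberately not done — the
assigned-pair convention matches how such cohorts are typed in practice.

## Single-molecule analysis

Each mismatched donor molecule contributes one observation (score,
molecule-specific DSA), independent of patient identity; a patient with
two mismatches contributes two rows, allelic matches contribute none. AUC
is the tie-corrected Mann–Whitney statistic; its variance (and the
covariance of paired AUCs) uses the DeLong structural-components
formulation, giving Wald 95% CIs and the two-sided z-test for ΔAUC.
Youden thresholds maximise J = sensitivity + specificity − 1 with the
classification convention **score ≥ threshold ⇒ high risk**; candidate
thresholds are the observed unique score values (so a reported cut is an
attainable score), with midpoints available by config; ties in J resolve
to the lower (more sensitive) cut. The boundary convention follows the
primary description of the stratification; the alternative strict-greater
convention is one config flag away, and the discrepancy between the two
conventions only matters for scores exactly at the cut.

Score correlation matrices are Pearson r (with p-values) over mismatched
molecules; zero-variance scores leave their entries undefined rather than
silently zero.

## Stratification

A patient's representative score per locus × method is the maximum over
their mismatched molecules; patients with no mismatch are *matched*,
otherwise *low*/*high* against the Youden threshold. For HLA-DQ, crossing
the antigen mismatch count (0/1/2) with the low/high molecular category
yields six strata (1–3 low, 4–6 high); an antigen-matched but allelically
mismatched patient can land in the 0MM/high stratum, which is precisely
what makes molecular stratification finer than antigen counting. Fully
matched patients are molecular low risk by definition (stratum 1).
In the 2MM1DSA analysis (two mismatches, one DSA), score ties are counted
as targeting the highest-scoring molecule and logged.

## Outcomes

- **DSA**: first positive test whose allelic specificity matches a
  mismatched donor molecule (a DQ β-chain specificity matches its
  heterodimer); locus event time is the earliest over molecules;
  non-donor-specific positives are ignored and logged. Censoring at last
  follow-up or death.
- **eGFR50**: baseline is the eGFR nearest month 3 within ±6 weeks; an
  event is the first measurement ≤ 50% of baseline confirmed by another
  qualifying measurement 6 months later (±6 weeks); event time is the
  *first* qualifying measurement, so the event precedes its confirmation.
  The ±6-week tolerance reflects 3–6-monthly registry visit schedules;
  the source protocol states "two consecutive results six months apart"
  without a tolerance, so one had to be fixed here.
- **Rejection**: late TCMR excludes episodes at ≤ 6 months; ABMR counts at
  any time.
- **CNI adherence**: IPV = 100·mean|x−x̄|/x̄ over levels from month 6
  (≥ 2 measurements), high iff strictly > 25%; count/fraction of levels
  strictly > 5 ng/ml; ciclosporin levels divided by 10 to approximate
  tacrolimus scale. IPV is scale-invariant, so the conversion can never
  change an IPV category.

Death is handled as right-censoring, not a competing risk, matching the
analysis design this pipeline reproduces.

## Survival modelling

Kaplan–Meier (Greenwood bands) and log-rank tests come from lifelines, as
do Cox fits with Efron tie handling — the accepted default of the
standard survival tooling. Time-varying DSA/rejection covariates switch
0→1 at their event time via counting-process expansion; the expansion is
tested against a hand-written interval table for identical partial
likelihood. Time-dependent AUC(t) is the cumulative/dynamic estimator
with inverse-probability-of-censoring weights (censoring distribution by
Kaplan–Meier, cases weighted by 1/G(T⁻); the constant control weight
cancels); it reduces *exactly* to the Mann–Whitney AUC of the event-by-t
label when censoring is absent, and a naive estimator (drop
censored-before-t subjects) is reported alongside since the variant used
by the original tooling is not documented. Calibration at a fixed horizon
is leave-one-out: each subject's predicted risk 1 − S₀(t)^exp(lp) comes
from a model fitted without that subject; subjects are binned into
quantile groups of predicted risk, observed risk is 1 − KM at the horizon
per bin, and percentile bands come from bootstrap refits (default 200).
The calibration slope is the OLS slope of observed on predicted across
bins.

Numerical safeguards: constant covariates are dropped before fitting
(they carry no risk signal and break the partial likelihood's
normalisation); a fold of the leave-one-out loop in which a covariate
becomes constant falls back the same way, and a near-singular fold
retries with a small ridge penalty (0.1). Degenerate models with no
usable covariate predict the marginal Kaplan–Meier risk. Sparse small-
sample fits of the pipeline's rejection-adjusted model fall back to the
same ridge, with the model label marked accordingly.

## Synthetic data generator

The generator emulates a paediatric kidney-transplant registry cohort:

- **Allele universe**: per locus, alleles are mutations of a locus
  consensus restricted to a polymorphic fraction of positions (default
  0.15); serological splits group ~2–4 sequence-similar alleles, each
  split having its own sub-consensus; DQA1 and DRB3/4/5 carry no splits.
- **Haplotypes**: random multi-locus haplotypes with skewed Dirichlet
  frequencies (α = 0.5) summing to 1, mirroring the dominance of a few
  common haplotypes in real tables.
- **EMS3D table**: scores are a linear blend of standardised pairwise
  AAMS and Gaussian noise, linearly rescaled to [0, 1.2], so the achieved
  Pearson correlation with AAMS equals the configured target (default
  0.7) over mismatched pairs; self-pairs are exactly 0. The
  netMHC–AAMS correlations are emergent (shared sequence structure), not
  controlled.
- **Cohort**: donor and recipient genotypes are two haplotypes each,
  drawn by frequency. Each mismatched molecule receives a latent DSA time
  with hazard `baseline · exp(slope · EMS3D)` (defaults 1.8·10⁻⁴/yr and
  7.0 per score unit), so the single-molecule method's generating
  assumption is literally true in the data. eGFR50 latent times follow
  the patient's DQ molecular risk group (max EMS3D vs the generator's
  true cut 0.6; hazards 0.013/0.0455 per year, ratio 3.5) multiplied by
  proportional-hazards effects of recipient age, donor age, baseline eGFR
  and re-transplantation. Follow-up combines an administrative window
  with exponential dropout (median ≈ 4.5 years). CNI series are noisy
  around a patient-specific mean with rare ciclosporin patients stored at
  ×10 scale; split typings are emitted alongside true genotypes so
  imputation accuracy is measurable.

Defaults were calibrated so the generated cohort reproduces the regime
the pipeline is designed for: roughly a third of patients developing DSA,
~15% reaching eGFR50, single-molecule EMS3D AUCs around 0.65–0.9, and
about two thirds of patients in the low molecular DQ risk group. Event
times are exponential for oracle tractability (a Weibull shape is
exposed).

**What passing tests do not show about real data.** The generator has no
linkage-disequilibrium structure beyond haplotype sampling, no MFI-level
antibody noise or inter-centre assay differences, no immunosuppression
effect on DSA hazard, independent molecules within patient (no shared
frailty), and DSA hazards driven by one score (EMS3D) rather than a
latent immunogenicity that all scores proxy. Pipeline performance on this
cohort therefore demonstrates correctness of the machinery and
recoverability of planted effects — not clinical performance.

On the default cohort the pipeline's estimated high-vs-low DQ hazard
ratio for eGFR50 (~2) is attenuated relative to the planted ratio (3.5):
the in-sample Youden cut differs from the generating cut and ~10% of
persons are imputed to a wrong genotype, both of which misclassify
borderline patients. This attenuation is a property of the workflow (any
in-sample thresholding pipeline shares it), and is left visible rather
than tuned away.

## Statistical checks

Parameter-recovery studies use the lightweight generators (direct
exponential event times given a group or score): 200 replicates at
n = 500 recover a group hazard ratio of 3.0 and a score slope of 0.5 with
mean log-HR bias below 10% and Wald CI coverage in [0.90, 0.98]. The
recovery studies run at a moderate event rate (~45%, baseline hazard
0.1/yr) where the Wald interval operates in its asymptotic regime; at
sparser event rates the interval is mildly conservative. The log-rank
test's type-I error is verified at nominal level by simulation (1000
null replicates, n = 200). The calibration slope of a well-specified
model at n = 1000 falls in [0.9, 1.1].

## Known limitations

- HLA-C is carried through imputation and sequence storage but not scored
  for DSA analysis.
- Eplet-based scoring and structure-based EMS3D computation are not
  implemented (the former by design, the latter consumed as a table).
- The mock predictor is a contract stand-in, not a model of peptide
  binding; netMHC-score magnitudes from the mock are not comparable to
  real predictor output.
- Cross-validated threshold selection is intentionally absent: thresholds
  are in-sample Youden cuts, matching the analysis this package
  reproduces.
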