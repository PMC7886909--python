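# Methods

This note documents the models and procedures behind each module, the
defaults that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Repertoire metrics

A repertoire is a set of unique TCRβ rearrangements with template counts.
Clone identity defaults to the CDR3 **nucleotide** sequence; amino-acid
grouping (which merges convergent rearrangements) is available via the
`identity` argument everywhere. Frequencies are recomputed from counts at
container construction and after every filter — stored frequencies are
never trusted. Non-productive rearrangements (out-of-frame or containing a
stop codon) are removed by `filter_productive` before any metric is
computed; an empty post-filter repertoire raises an explicit error rather
than propagating a zero division.

**Clonality** is `1 − H/ln R` with `H` the Shannon entropy (natural log)
of clone frequencies and `R` the richness. The normalizer `ln R` makes the
score 1 for a monoclonal population and ~0 for an even polyclonal one; the
single-clone repertoire is defined as clonality 1 (the monoclonal limit of
the otherwise indeterminate 0/0 expression). **Morisita–Horn** is the
abundance-weighted overlap `2Σxy / ((d_x + d_y)XY)`; floating-point results
are clamped into [0, 1] within 1e-12. Whether a published overlap was
computed on all clones or on a top-N restriction is often unstated, so
`morisita_horn` takes an optional `top_n`; the default uses all clones.

**Top-N** ordering is by count descending with ties broken
lexicographically on the nucleotide sequence — deterministic across
platforms and runs. **Reactive-clone calls** use a strict frequency
threshold (default 2%): a clone at exactly the cutoff is not called.

I/O reads AIRR Community headers (`junction`, `junction_aa`,
`duplicate_count`, `productive`) and immunoSEQ-export headers
(`nucleotide`, `aminoAcid`, `count (templates/reads)`, `sequenceStatus`
with In/Out/Stop); any other layout is declared with an explicit column
map. Output always uses AIRR Community names.

## Activation index

Fold changes are floored ratios `max(post, f)/max(pre, f)` with
`f = 0.01` percentage points, so an undetectable subset at one timepoint
yields a large-but-finite fold rather than dropping the patient; the
flooring event is flagged in the result. Percentages live on the 0–100
scale throughout (clone frequencies, on 0–1, are a separate concept).

The composite is the geometric mean of the three fold changes. Published
composites of this kind differ in whether the threshold applies to the
composite, to a single component, or to all components, so the responder
rule is configurable: the default `geom_gate` requires the index above the
threshold (1.0) **and** all three components above 1 — "a robust increase
in all three categories" — while `geom_only` applies the threshold to the
composite alone. The geometric mean is the natural composite for
multiplicative quantities: it is permutation-invariant and scales linearly
when all components are scaled.

`timecourse_summary` reduces a long-format panel table to mean ± SD fold
change versus baseline per subset per timepoint and marks the peak
timepoint per subset.

## Neoepitope chain

Only single amino-acid substitutions are in scope; indels and frameshifts
are rejected with a clear message (their window semantics are different
and not specified here). The filter chain keeps a variant when tumor depth
> 10, normal depth > 10, tumor VAF ≥ 0.10 and tumor/normal VAF ratio ≥ 5.
The ratio criterion is read with `normal VAF = 0` passing by definition —
the only reading under which germline-clean variants survive — and every
failed criterion is enumerated per rejected record, so the chain is
auditable and order-independent. Caller concordance keeps variants
reported by ≥ k of {MuTect, SomaticSniper, Strelka, VarScan}, default
k = 2.

Windows span 12 residues on each side of the substituted position (25-mer
when the protein allows; truncated at termini, never dropping the mutated
residue — centering maximizes the number of mutation-spanning peptides of
every length). Peptide enumeration yields all distinct 8–11mer substrings
containing the mutated index, ordered by (start, length): a fully flanked
mutation yields 8+9+10+11 = 38 peptides, a terminal mutation 4.

Transcript prioritization flags candidates whose FPKM strictly exceeds the
threshold (default 100). Binding ranking is delegated to a pluggable
scorer (any callable peptide → score, lower = stronger predicted binding);
a candidate survives when at least one peptide scores at or below the
cutoff. The default cutoff 0.5 is unit-agnostic — the same mechanism works
for an affinity in nM or a percentile rank, whichever the wired-in
predictor reports. The shipped `stub_scorer` is a deterministic
hash-based stand-in for tests and dry runs, not a binding model.
Population-database annotation (COSMIC/ExAC/1000G) is treated as optional
pass-through metadata, never computed.

## Tissue quantification

ROI aggregation is the arithmetic mean of per-image densities (cells/mm²;
the acquisition convention is six 0.36 mm² images per tissue sample) per
patient × timepoint × compartment × phenotype. Missing images are averaged
over, with the contributing count reported — a missing image is not an
observation of zero cells. A convenience converter turns raw per-ROI
counts into densities using the ROI area.

Flow–IHC concordance is ordinary least squares of flow percentages on IHC
densities with R² the squared Pearson correlation, computed on per-patient
means (one point per patient). Zero variance in either vector raises an
explicit undefined-statistic error. ELISpot positivity is strict:
> 100 spot-forming cells. Background (mock-well) subtraction is available
but off by default, since the plain threshold rule is the primary
contract.

## Survival

Kaplan–Meier estimation, the Mantel–Cox log-rank test, and confidence
intervals are computed through lifelines behind this module's interface;
the tests validate the results against hand-computed product-limit and
observed-minus-expected arithmetic. Conventions: events precede censorings
tied at the same time; times are months from the day of surgery (the
loader assumes inputs are already on that origin). Median follow-up uses
the reverse Kaplan–Meier method — the product-limit estimator with the
censoring indicator as the event — with a Greenwood log–log 95% CI; a
curve that never reaches 0.5 raises an explicit error instead of returning
infinity.

## Synthetic cohort generator

The generator's purpose is structural: produce inputs whose planted
properties the pipeline must recover. It emulates distributions and effect
sizes, not raw instrument output (no FCS events, reads, or pixels).

**Repertoires.** Clone abundances follow a rank-frequency power law
`p_k ∝ k^-α` (default α = 2), assigned over a shuffled rank order and
sampled by a multinomial at the configured depth (default 50 000
templates over 1 000 clones) — a simple heavy-tailed model under which the
top-30 clones dominate the repertoire, as observed in tumor-reactive TIL
subsets. The clone universe is partitioned into one shared pool (40%) and
five private pools (DN, SP, DP, blood, drLN). DN, SP, blood, and drLN mix
`shared_pool_fraction` (default 0.7) of shared-pool mass with private
mass; DP mixes `dp_private_fraction` (default 0.9) of DP-private mass
with the shared pool. The shared pool uses a single fixed probability
vector, so at `shared_pool_fraction = 1` DN and SP draw from the identical
distribution and their Morisita–Horn overlap approaches 1 with depth. The
defaults plant the ordering MH(DN,SP) > MH(DP,DN) ≈ MH(DP,SP) — the
bystander/tumor-reactive signature.

**Flow cohort.** Baselines are drawn lognormally around typical values
(20% CD8 of T, 8% DP of CD8, 10% Ki-67 of DP) with upper clips chosen so
that a lifted value cannot hit the 100% ceiling. Responders (default
fraction 0.25) receive multiplicative lifts: 3.4-fold on %DP and on
%Ki-67 of DP, 2-fold on %CD8 (the "modest" component — strong enough that
the all-components gate stays informative); non-responders receive fold 1.
Fold noise is a **single mean-one lognormal factor** at the configured CV
(default 0.2): baseline biological variability is already captured by the
baseline draw, and measurement noise enters the pre/post contrast once.
Under the default gate rule this noise model gives a non-responder
false-positive rate of Φ(−σ/2)³ ≈ 10% at CV 0.2 and an expected label
recovery around 92–93% at n = 200 — and exact recovery at CV 0. Planted
labels are emitted only in a sidecar table, keeping the measurement files
blind. The peripheral-blood timecourse plants its peak at D12
(CD4 Ki-67 6.8-fold, CD8 Ki-67 drawn from 4–6-fold, Treg Ki-67 2.6-fold,
plasmablasts 10-fold) decaying to ~baseline by D55.

**Variants.** Each record passes or fails by a coin flip at
`pass_fraction`; failing records receive one or two randomly chosen
violations (depths ≤ 10, tumor VAF < 0.10, VAF ratio < 5, single caller)
with the violated rules recorded in a sidecar column. Passing records are
drawn with margins wide enough that decimal rounding cannot cross a
threshold. Context lengths (15–120 aa) and uniform mutation positions
exercise both internal and terminus-truncated windows.

**Survival.** Exponential event times (analytically tractable: the KM
curve at the distribution median should be 0.5) with the `hazard_ratio`
parameter multiplying the *responder* group's hazard (so 0 plants an
event-free group), independent exponential censoring, and a 120-month
administrative horizon that keeps times finite in degenerate settings.

**Tissue.** ROI densities are lognormal around compartment/phenotype
means with stroma CD3 above tumor CD3, a patient-level scale factor, and
a tumor-confined responder lift (3.4-fold tumor vs 1.12-fold stroma) of
the proliferating CD8⁺CD103⁺Ki-67⁺ phenotype. Matched flow percentages
track the tumor (not stromal) densities, so concordance is high in tumor
and near zero in stroma. ELISpot wells plant DP-restricted reactivity to
one peptide.

What passing tests on this generator show: the pipeline recovers planted
structure under the stated noise models. What they do not show: robustness
to gating drift, batch effects, PCR amplification bias in template counts,
sampling variability of small biopsies, or non-exponential hazards — none
of which the generator emulates.

## Reporting and determinism

`run_all` executes exactly the stages whose inputs are configured, writes
per-stage CSVs, a JSON summary, a plain-text report, the resolved
configuration, and a SHA-256 manifest of every input file. No timestamps
or unordered collections are serialized, and all randomness flows from the
single configured seed, so identical config + seed reruns are
byte-identical. Unknown configuration keys are rejected rather than
ignored. Stage failures abort with the stage name and leave an
`INCOMPLETE` sentinel in the output directory.

## Problem sizes

Default problem sizes throughout (50 000-template repertoires, 200-patient
recovery cohorts, 100-variant tables, 500-per-group survival fixtures, 20
replicate seeds for expectation checks) were chosen so the full test suite
and the acceptance script each complete in seconds while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* Clonality uses the Shannon/Pielou form only; alternatives (Simpson,
  Gini) are not implemented.
* Indels and frameshift neoantigens are out of scope by design.
* The binding "scorer" contract is single-peptide and synchronous; batch
  predictors need a thin adapter.
* Survival is two-group nonparametric only — no Cox regression, competing
  risks, or repeated-measures modeling.
* The generator's noise models are multiplicative lognormal everywhere;
  heavy-tailed measurement artifacts are not simulated.
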