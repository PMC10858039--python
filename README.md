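# estrpipe

Somatic short-tandem-repeat (STR) mutation calling and expression-STR
(eSTR) analysis for matched tumour/normal cohorts, built around the
colorectal-cancer setting where microsatellite instability (MSI) makes STRs
hypermutable.

STRs — runs of a 1–6 bp motif — mutate by slippage, inserting or deleting
whole repeat units.  In mismatch-repair-deficient (MSI) tumours these
mutations are frequent and strongly deletion-biased, and because STR length
can modulate nearby gene expression, somatic STR mutations are a candidate
mechanism by which tumours rewire their transcriptome.  `estrpipe`
implements the full analysis chain for this question:

1. **Panel** — exhaustive detection of perfect STRs in gene-associated
   sequence (minimum 9/4/4/3/3/3 units for unit sizes 1–6), strand-independent
   motif canonicalization, redundancy/proximity filtering (50 bp), region
   annotation (CDS/UTR/intron/promoter, 5 kb window) and masking.
2. **Genotype QC** — biallelic length calls (TSV dialect or GangSTR-style
   VCF), depth bounds [20, 1000], low-call-sample exclusion (<10,000 loci),
   per-sample CNV-overlap removal.
3. **Mutation calling** — patient-matched healthy/tumour comparison;
   a locus is mutated when the allele multisets differ; tumour calls
   homozygous for an allele unseen in the healthy sample are excluded as
   allele dropout.
4. **Mutability statistics** — step-size histograms, per-patient insertion/
   deletion fractions, MSS/MSI contrasts by unit size and allele length
   (Fisher exact tests), deletion-ranking concordance with MSI labels.
5. **eSTR discovery** — per-gene rank inverse-normal expression, per
   STR–gene pair ordinary least squares of normalized expression on mean
   allele length, slope t-tests with Benjamini–Hochberg FDR at α = 0.05,
   and a permuted-genotype negative control:

   `ỹ_g = Φ⁻¹((rank − 0.5)/n)`,  `ỹ_g = α + β·x + ε`,  H₀: β = 0.

6. **Validation** — in held-out patients, `sign(β·Δ_l)` predicts the
   direction of expression change after a somatic eSTR mutation
   (`Δ_l` = tumour − healthy mean allele length); accuracy is tested
   against chance (one-sided binomial) and stratified by the expected
   impact `|β|·|Δ_l|`.
7. **eSTR mutability** — loci grouped into repeat types (unit size ×
   reference allele length); the fraction of types where eSTRs are more
   mutable (difference > 0.05, ≥ 25 observations per side) is compared with
   a 10,000-fold eSTR-label-permutation null, `p = (1+#{null≥obs})/(1+n)`.

A synthetic-cohort generator (`estrpipe.simulate`) produces matched
healthy/tumour genotypes with length-dependent mutation rates, an
MSI-specific deletion bias, planted linear eSTR effects and ground truth,
so the whole pipeline is testable without restricted-access patient data.

## Worked example

```python
import numpy as np
from estrpipe.simulate import SimulationConfig, generate_cohort
from estrpipe.discovery import discover_estrs, pair_str_gene
from estrpipe.validation import build_validation_records, summarize_validation

cfg = SimulationConfig(
    n_patients_mss=300, n_patients_msi=0,
    n_patients_validation=40, validation_msi_fraction=1.0,
    n_loci=2000, n_estr=150, seed=7,
)
cohort = generate_cohort(cfg)
pairs = pair_str_gene(cohort.panel, cohort.gene_models)
res = discover_estrs(cohort.calls, cohort.expression, cohort.metadata, pairs,
                     rng=np.random.default_rng(1))

planted = set(cohort.truth.planted_estr_ids)
print(len(res.estr_ids), len(planted & set(res.estr_ids)) / len(planted))
# 157 1.0        -> 157 significant eSTRs; all 150 planted loci recovered

recs = build_validation_records(res.associations, cohort.calls,
                                cohort.expression, cohort.metadata,
                                res.reference_quantiles)
s = summarize_validation(recs)
print(round(s.accuracy, 3), s.n_usable)
# 0.675 603      -> 67.5% of 603 eSTR mutations changed expression in the
#                   predicted direction
print(s.quartiles.accuracy.round(3).tolist())
# [0.503, 0.603, 0.728, 0.867]
#                -> accuracy rises monotonically with expected mutation
#                   impact |beta|*|delta_l|, from chance in the lowest
#                   quartile to 87% in the highest
```

The command-line interface exposes the same stages over one YAML config
(`estrpipe simulate|panel|filter-calls|call-mutations|mutability|discover|
validate|estr-mutability|all --config config.yaml`), writing per-stage
manifests with input hashes and seeds so reruns are bit-reproducible.

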