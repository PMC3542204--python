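# Desk-scale demonstration run: a small synthetic cohort with one planted
# direct-effect SNP, one perfect-LD block (redundancy) and nulls, analysed
# end to end.  Step counts are kept small for a fast demo; scale them up
# (or use --chain-scale) for production-quality posteriors.
seed: 7

cohort:
  n_cases: 300
  n_controls: 300
  male_fraction: 0.57
  n_null_snps: 6
  direct_effects:
    rsD1: 0.693          # per-allele log-odds (OR 2.0)
  redundant_groups:
    - loci: [rsR1, rsR2, rsR3]
      maf: 0.3
  gender_effect: 0.1
  with_subtypes: true
  with_survival: true

qc:
  call_rate_min: 0.90
  maf_min: 0.10
  hwe_p_min: 0.01

tags:
  r2_threshold: 0.80

freq:
  fdr_alpha: 0.01

sampler:
  n_chains: 4
  temperature_ladder: [1.0, 0.7, 0.49, 0.343]
  burn_in_steps: 5000
  sample_steps: 20000
  thinning: 10
  swap_interval: 10
  max_in_degree: 4
  n_replicates: 2

features:
  edge_posterior_min: 0.5
  ir_floor: 0.05
  ir_max_set_size: 2

subgroups:
  - name: ALL
  - name: B-ALL
    case_filter: {lineage: B}
  - name: OS
    target: os5
    mode: cases_only
    extra_covariates: [lineage, risk_group]
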