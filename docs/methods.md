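# Methods

## Model and scoring

All variables are discrete: genotypes as minor-allele counts (arity 3, or
2 after optional carrier recoding), categorical covariates, one designated
outcome. A hypothesis is a DAG `G` over the variables with at most 4
parents per node. Given complete-case data `D`, the marginal likelihood
factorises over families; for node `v` with arity `r`, parent
configuration `j` observed `N_j` times with per-state counts `N_jk`,

    log P(D|G) = Σ_v Σ_j [ ln Γ(r) − ln Γ(r + N_j) + Σ_k ln Γ(1 + N_jk) ]

— the Cooper–Herskovits closed form with every Dirichlet hyperparameter
equal to 1 (the K2 prior). All arithmetic is in log space via log-gamma;
unobserved parent configurations contribute nothing, so the empty dataset
scores 0 for every family. Note that K2 is *not* score-equivalent:
`X→Y` and `Y→X` may score differently when arities differ; the test suite
asserts this on a constructed example, since it is a real property of the
prior rather than a defect.

The structure prior is uniform over the allowed space (acyclic, in-degree
≤ 4): log-prior 0 inside, −∞ outside. A literal "uniform prior over
parent sets" is constant over the same space and therefore
indistinguishable from the uniform-over-DAGs prior inside an MCMC, so the
alternative exposed behind the `structure_prior="parent_set_size"` flag is
the standard cardinality prior `P(G) ∝ Π_v 1/C(n−1, |pa(v)|)` instead.

## Sampling

The posterior over structures is explored by Metropolis-coupled MCMC:

- **Proposal** — uniform over all valid single-edge moves
  {add, delete, reverse}; validity preserves acyclicity and the parent
  cap. Acceptance is `min{1, exp(β·Δ)·|moves(G)|/|moves(G′)|}` where Δ is
  the change in log score + log prior and the neighbourhood ratio is the
  Hastings correction for the asymmetric move sets.
- **Tempering** — 4 chains with a geometric inverse-temperature ladder
  (1, 0.7, 0.49, 0.343); every 10 steps a random adjacent pair proposes a
  state swap, accepted with `min{1, exp((β_i−β_j)(s_j−s_i))}`.
- **Defaults** — burn-in 5×10⁴ steps, 2×10⁵ sampling steps, thinning 10,
  three independent cold-chain replicates. These desk-scale counts give
  Monte-Carlo standard errors of a few 10⁻³ on the posteriors of the
  problem sizes the package targets (≤ ~50 tag variables); step counts in
  the tens of millions remain available through the config for
  production-scale runs.
- **Kernel** — the production sampler is a numba-compiled kernel holding
  graphs as per-node bitmasks (≤ 62 variables; tag-SNP reduction keeps
  realistic panels below that). It computes the identical family score as
  the pure-Python scoring module — asserted to 1e-10 by the tests — and
  memoises families in a dict keyed on (node, parent bitmask). The
  pure-Python `enumerate_moves` / `mh_step` / `swap_step` functions define
  the reference single-step semantics and are tested directly against the
  enumeration oracle. One seeded RNG stream drives each replicate, with
  chains drawn in fixed order, so runs are exactly reproducible.

Every recorded structure is checked online for acyclicity and the
in-degree bound. Convergence is judged *per feature*: Gelman–Rubin R
across the independent replicates (flagged at R ≥ 1.05, with the
conventions R = 1 for identical constant chains and R = ∞ for diverged
constant chains) and Geweke Z within each replicate (first 10% vs last
50%, Bartlett-windowed spectral variances, Z = 0 for constant traces).
Posterior Monte-Carlo standard errors use an autocorrelation-adjusted
effective sample size (Geyer initial positive sequence).

## Features and ratios

Pairwise features are computed by reachability on each sampled DAG: DCR is
adjacency in either orientation (edge orientation is only weakly
identified under Markov equivalence; an orientation-specific query kind
exists separately); TCR requires a directed path of length ≥ 2 in either
direction so that DCR and TCR are disjoint evidence types; ConfR is a
shared proper ancestor; PIR a shared child; A = DCR ∨ TCR ∨ ConfR and
SR = DCR ∨ PIR. SR(X, Y) is definitionally equivalent to membership of X
in the Markov blanket of Y (parents ∪ children ∪ co-parents of children),
which the suite asserts exhaustively over all 543 four-node DAGs.

The sub-relevance posterior of a set `s` is the fraction of samples whose
Markov blanket contains `s` — equivalently the MBS-identity posterior of
`s` plus those of all its supersets. The interaction/redundancy ratio is
`R = p̄(s|D) / Π_k p̄(x_k|D)`; `IR = ln R` when `R > 1`, `RR = −ln R` when
`R < 1`. A zero singleton posterior leaves R undefined and is flagged
rather than raised. Reports keep both raw posteriors alongside the ratio
so boundary cases (R ≈ 1) are auditable, enumerate sets up to size 2 by
default (configurable), and suppress |ln R| below a 0.05 floor.

Relevance classification follows the 0.5 (moderate) / 0.75 (convincing)
posterior thresholds.

## Exact oracle

For ≤ 5 variables, all DAGs are enumerated (3^(n choose 2) pair states,
filtered for acyclicity and the in-degree bound; counts verified against
the Robinson sequence 3, 25, 543, 29281) and feature posteriors computed
by full summation with the same `ScoreConfig` as the sampler — sharing the
config object is what makes sampler-vs-oracle comparisons valid. The core
correctness surface of the package is the requirement that every pairwise
feature posterior from MC³ agrees with exact enumeration within Monte-
Carlo error on seeded 4-variable cohorts.

## Synthetic cohorts

The generator emulates the statistical structure of a pediatric ALL
candidate-gene study without claiming biological realism:

- **LD blocks** — individuals draw two founder haplotypes from a declared
  pool and sum them, so within-block r² equals the founder-pool value in
  expectation (verified: a (0.4, 0.1, 0.1, 0.4) pool gives r² ≈ 0.36).
  Redundant groups use a shared two-founder pool (pairwise r² = 1).
  No recombination maps, mutation or population structure are modelled.
- **Disease model** — logistic link on per-allele main effects, carrier
  main effects, joint-carrier (AND) epistasis terms and covariate effects.
  A planted *pure interaction* adds compensating carrier main effects,
  solved numerically (Brent) from the expected-probability balance, so
  both loci are marginally independent of the outcome while the epistatic
  contrast survives within partner strata; the marginal null is verified
  empirically (ORs within [0.9, 1.1] at n = 50,000). Cases and controls
  are filled by rejection sampling, preserving case-control ascertainment.
- **Clinical layer** — gender Bernoulli(0.57 male); B/T lineage, ~14.5%
  hyperdiploidy and LR/MR/HR risk groups for cases at the proportions of a
  ~1,000-subject cohort; controls carry "na" labels, and subtype variables
  enter an analysis only where its subgroup declares them.
- **Survival** — exponential event times with multiplicative stratum
  hazards (risk-group defaults chosen so 5-year survival is ~92.6 / 87.0 /
  62.3% for OS and 90.4 / 82.6 / 60.4% for EFS), independent exponential
  censoring, administrative censoring at the 5-year horizon. The 5-year
  category is "died" on an event before the horizon, "survived" on
  event-free follow-up to the horizon, and excluded (complete case, count
  logged) when censored earlier — the discretization is a package
  decision, as is testing HWE in controls only.

All randomness descends from one master seed through fixed-index
`SeedSequence` substreams, so adding a stream never perturbs existing
ones and identical (config, seed) pairs yield byte-identical cohorts.

What passing recovery tests show is that the method finds planted
structure under the generator's assumptions (independent individuals,
exact logistic links, clean genotypes); they do not certify behaviour
under population stratification, genotyping batch effects or model
misspecification, none of which the generator emulates.

## Recovery experiment design

The recovery surface uses effect sizes chosen for informativeness at the
stated sample sizes:

- *Direct effect*: per-allele OR 2.0 at n = 1,000/1,000 — overwhelming
  evidence; the planted SNP must top the SR ranking at posterior ≥ 0.5.
- *Pure interaction*: joint-carrier OR 2.2 at MAF 0.25, n = 750/750, with
  carrier (dominant) coding for the BN input. Two considerations fix this
  regime: with 3-level coding the K2 complexity cost of two genotype
  parents (≈ 4·ln n nats) exceeds any plausible epistatic signal at this
  n, so carrier coding is the scientifically sensible configuration; and
  the interaction ratio is only informative when joint relevance is
  uncertain — a much stronger effect saturates the posterior at 1, where
  R degenerates to exactly 1, while a much weaker one leaves the pair
  undetected. OR ≈ 2 sits in the detectable-but-uncertain band for
  n = 1,500 designs.
- *Redundancy*: an exact duplicate column of an OR-2 causal SNP; the two
  proxies alternate in the Markov blanket, so the joint posterior falls
  well below the product of the singletons.
- *Null calibration*: 20 null SNPs at n = 500/500 keep the fraction of
  false strong-relevance calls (SR ≥ 0.5) at or below 10% on average —
  empirically it is near zero, since the K2 penalty strongly disfavours
  spurious parents at these sizes.

## QC, LD and frequentist conventions

- QC drops monomorphic SNPs, call rate < 0.90, MAF < 0.10, and HWE
  p < 0.01 in controls (1-df χ² goodness of fit; monomorphic input is in
  trivial equilibrium, p = 1), then removes incomplete samples
  (complete case; mode imputation exists behind an explicit flag, off by
  default). Rules are order-insensitive at the SNP level.
- Two-locus LD comes from EM over the 3×3 unphased genotype table
  (tolerance 1e-10, ≤ 1,000 sweeps; only the double heterozygote is phase
  ambiguous). Tag selection greedily prunes at r² ≥ 0.8, visiting SNPs by
  descending MAF with lexicographic tie-break; a pruned SNP is recorded
  as a proxy of its best-r² tag. Codes are taken as minor-allele counts
  on the reported alleles; no strand flipping is attempted.
- The frequentist track uses Woolf CIs with Haldane–Anscombe correction
  for zero cells, an in-package IRLS logistic regression (gradient
  max-norm < 1e-8; rank deficiency and separation raise rather than
  returning divergent estimates; Wald CIs, matching standard software)
  cross-checked against statsmodels, Benjamini–Hochberg FDR at α = 0.01
  with the family `m` = all SNP × subgroup tests of the run logged in the
  manifest (a printed FDR threshold alone does not identify `m`, so it is
  always reported explicitly), and lifelines for Kaplan–Meier /
  log-rank. Genotypic tests default to additive coding; carrier and
  homozygote contrasts are separate labelled models.

## Pipeline

Subgroup analyses follow the case-subtype-vs-all-controls construction
(B-lineage, T-lineage, hyperdiploid) and cases-only targets (risk group,
5-year OS/EFS, which include lineage and risk group as variables). One BN
target is analysed per run; categories unobserved after filtering are
re-coded away so arities reflect the data actually scored. Reports:
per-variable posterior tables per subgroup, IR/RR tables, averaged-
structure edge lists (edges kept only above posterior 0.5), survival-by-
risk-group summaries, per-feature convergence tables, and a JSON manifest
(config hash, seed, version, per-stage counts, max R). Identical config +
seed reproduce every report byte for byte.

## Known limitations

- The kernel's bitmask representation caps BN analyses at 62 variables;
  larger panels must be reduced to tag SNPs first (which the method wants
  anyway, as LD inflates redundancy and dilutes direct-edge posteriors).
- Posterior orientation of individual edges is not causally meaningful
  without interventions; DCR deliberately collapses orientation.
- The survival stage of the BN track uses the discretized 5-year category,
  not event times; Kaplan–Meier/log-rank operate on times only in the
  frequentist track.
- Exact enumeration is limited to 5 variables; sampler validation beyond
  that size is indirect (convergence diagnostics, planted-truth recovery).
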