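"""Synthetic case-control cohort generator with planted ground truth.

The generator emulates the statistical structure a candidate-gene
case-control study of childhood acute lymphoblastic leukemia presents to the
analysis: LD blocks of SNPs drawn from founder haplotype pools, a logistic
disease model with direct, epistatic and covariate effects, clinical
subtype labels (B/T lineage, hyperdiploidy, risk group) and censored
survival discretized at five years.  Because no individual-level data are
deposited for such cohorts, every recovery experiment in the package runs
against datasets from this module, whose :class:`PlantedTruth` labels what
the analysis should and should not find.

All randomness flows from one explicit master seed: named substreams are
spawned from ``np.random.SeedSequence((seed, k))`` with a fixed stream
index ``k`` per purpose, so adding streams never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import DiscreteDataset, dataset_from_frames

# fixed substream indices (never renumber)
_STREAM_GENO = 0
_STREAM_OUTCOME = 1
_STREAM_COVARIATES = 2
_STREAM_SUBTYPES = 3
_STREAM_SURVIVAL_OS = 4
_STREAM_SURVIVAL_EFS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDBlockSpec:
    """Founder haplotype pool for one LD block.

    Individuals draw two founder haplotypes independently and sum the allele
    vectors, so the expected pairwise r^2 inside the block equals the
    founder-pool value exactly.
    """

    locus_ids: tuple[str, ...]
    founder_haplotypes: tuple[tuple[int, ...], ...]
    founder_frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.founder_haplotypes) == 0:
            raise ValueError("empty founder pool")
        if len(self.founder_frequencies) != len(self.founder_haplotypes):
            raise ValueError("one frequency per founder haplotype required")
        freqs = np.asarray(self.founder_frequencies, dtype=float)
        if (freqs < 0).any():
            raise ValueError("founder frequencies must be nonnegative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"founder frequencies sum to {freqs.sum()}, not 1")
        lengths = {len(h) for h in self.founder_haplotypes}
        if lengths != {len(self.locus_ids)}:
            raise ValueError("founder haplotypes must match the number of loci")

    @staticmethod
    def two_founder(locus_ids: Sequence[str], maf: float) -> "LDBlockSpec":
        """Perfect-LD block: all loci carry the minor allele together."""
        k = len(locus_ids)
        return LDBlockSpec(
            locus_ids=tuple(locus_ids),
            founder_haplotypes=((0,) * k, (1,) * k),
            founder_frequencies=(1.0 - maf, maf),
        )

    @staticmethod
    def independent(locus_id: str, maf: float) -> "LDBlockSpec":
        return LDBlockSpec(
            locus_ids=(locus_id,),
            founder_haplotypes=((0,), (1,)),
            founder_frequencies=(1.0 - maf, maf),
        )


def generate_block_genotypes(
    spec: LDBlockSpec, n_individuals: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n_individuals`` diploid genotypes (0/1/2) from a founder pool."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_GENO)
    haps = np.asarray(spec.founder_haplotypes, dtype=np.int64)
    freqs = np.asarray(spec.founder_frequencies, dtype=float)
    idx = rng.choice(len(haps), size=(n_individuals, 2), p=freqs)
    geno = haps[idx[:, 0]] + haps[idx[:, 1]]
    return pd.DataFrame(geno, columns=list(spec.locus_ids))


# ---------------------------------------------------------------------------
# Disease model
# ---------------------------------------------------------------------------


@dataclass
class EffectModel:
    """Logistic disease model on genotypes and covariates.

    ``main_effects`` are per-minor-allele log-odds (additive in the 0/1/2
    code); ``carrier_main_effects`` apply once to carriers of >=1 minor
    allele; ``interaction_effects`` apply to a locus pair only when both
    loci carry >=1 minor allele (joint-carrier epistasis);
    ``covariate_effects`` are log-odds per unit of the covariate code.
    """

    intercept: float = 0.0
    main_effects: dict[str, float] = field(default_factory=dict)
    carrier_main_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, genotypes: pd.DataFrame, covariates: pd.DataFrame) -> np.ndarray:
        for locus in list(self.main_effects) + list(self.carrier_main_effects):
            if locus not in genotypes.columns:
                raise KeyError(f"effect references unknown locus {locus!r}")
        for pair in self.interaction_effects:
            for locus in pair:
                if locus not in genotypes.columns:
                    raise KeyError(f"interaction references unknown locus {locus!r}")
        for cov in self.covariate_effects:
            if cov not in covariates.columns:
                raise KeyError(f"effect references unknown covariate {cov!r}")
        eta = np.full(len(genotypes), float(self.intercept))
        for locus, beta in self.main_effects.items():
            eta += beta * genotypes[locus].to_numpy(dtype=float)
        for locus, beta in self.carrier_main_effects.items():
            eta += beta * (genotypes[locus].to_numpy() > 0)
        for (l1, l2), beta in self.interaction_effects.items():
            both = (genotypes[l1].to_numpy() > 0) & (genotypes[l2].to_numpy() > 0)
            eta += beta * both
        for cov, beta in self.covariate_effects.items():
            eta += beta * covariates[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite linear predictor")
        return eta


def simulate_case_control(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    model: EffectModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcomes with a logistic link on the model's linear predictor."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_OUTCOME)
    p = expit(model.linear_predictor(genotypes, covariates))
    return (rng.random(len(p)) < p).astype(np.int64)


def compensated_interaction_mains(
    beta: float, carrier_freq: float, intercept: float = 0.0
) -> float:
    """Carrier main effect that cancels the marginal effect of joint-carrier
    epistasis between two loci with equal carrier frequency.

    For the model ``logit P(Y) = a + m(c1 + c2) + beta*c1*c2`` with carriers
    ``c_i ~ Bernoulli(q)`` independent, solves for ``m`` such that
    ``P(Y | c1) = P(Y | c1 = 0)`` — i.e. both loci are marginally
    independent of the outcome while the joint-carrier stratum keeps its
    epistatic log-odds.  This is the "pure interaction" construction: no
    marginal association but genuine joint relevance.
    """
    q = float(carrier_freq)
    a = float(intercept)

    def imbalance(m: float) -> float:
        with_c1 = (1 - q) * expit(a + m) + q * expit(a + 2 * m + beta)
        without = (1 - q) * expit(a) + q * expit(a + m)
        return with_c1 - without

    lo, hi = (-abs(beta) - 6.0, abs(beta) + 6.0)
    return float(brentq(imbalance, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalModel:
    """Exponential event/censoring model with multiplicative stratum hazards.

    ``hazard_ratios`` maps a stratum column name to ``{value: multiplier}``;
    multipliers across columns combine multiplicatively.  Follow-up is
    administratively censored at ``horizon_years``.
    """

    baseline_hazard: float  # events per year
    hazard_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    censoring_rate: float = 0.01  # losses to follow-up per year
    horizon_years: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")

    def hazard(self, strata: pd.DataFrame) -> np.ndarray:
        h = np.full(len(strata), self.baseline_hazard)
        for col, ratios in self.hazard_ratios.items():
            if col not in strata.columns:
                raise KeyError(f"hazard stratum column {col!r} missing")
            values = strata[col].astype(str)
            unknown = set(values.unique()) - set(map(str, ratios))
            if unknown:
                raise KeyError(f"no hazard ratio for strata {unknown} of {col!r}")
            h *= values.map({str(k): float(v) for k, v in ratios.items()}).to_numpy()
        return h


def simulate_survival(
    strata: pd.DataFrame,
    model: SurvivalModel,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Simulate (time, event) pairs plus the discretized 5-year category.

    Event times are exponential with the stratum hazard; independent
    exponential censoring competes with administrative censoring at the
    horizon.  Discretization: event before the horizon -> ``died``;
    followed event-free to the horizon -> ``survived``; censored earlier ->
    ``na`` (excluded from complete-case BN input downstream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_SURVIVAL_OS)
    h = model.hazard(strata)
    t_event = rng.exponential(1.0 / h)
    if model.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / model.censoring_rate, size=len(h))
    else:
        t_cens = np.full(len(h), np.inf)
    t_cens = np.minimum(t_cens, model.horizon_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)
    category = np.where(
        event == 1,
        "died",
        np.where(time >= model.horizon_years, "survived", "na"),
    )
    return time, event, pd.Series(category)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """Ground-truth labels for recovery tests."""

    direct_loci: set[str] = field(default_factory=set)
    pure_interaction_pairs: set[tuple[str, str]] = field(default_factory=set)
    redundant_groups: list[set[str]] = field(default_factory=list)
    confounder_loci: set[str] = field(default_factory=set)
    null_loci: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "direct_loci": sorted(self.direct_loci),
                "pure_interaction_pairs": sorted(map(list, self.pure_interaction_pairs)),
                "redundant_groups": [sorted(g) for g in self.redundant_groups],
                "confounder_loci": sorted(self.confounder_loci),
                "null_loci": sorted(self.null_loci),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "PlantedTruth":
        d = json.loads(text)
        return PlantedTruth(
            direct_loci=set(d["direct_loci"]),
            pure_interaction_pairs={tuple(p) for p in d["pure_interaction_pairs"]},
            redundant_groups=[set(g) for g in d["redundant_groups"]],
            confounder_loci=set(d["confounder_loci"]),
            null_loci=set(d["null_loci"]),
        )


# defaults follow the composition of a ~1,000-subject pediatric ALL
# case-control study: 543/529 cases/controls, 57% male, B/T lineage split,
# ~14.5% hyperdiploid, risk groups LR/MR/HR, and 5-year survival around 85%
# stratified by risk group.
_RISK_GROUPS = ("LR", "MR", "HR")
_RISK_PROBS = (0.209, 0.671, 0.120)
_LINEAGE = ("B", "T")
_LINEAGE_PROBS = (0.833, 0.167)
_OS_HR = {"LR": 0.552, "MR": 1.0, "HR": 3.391}
_EFS_HR = {"LR": 0.652, "MR": 1.0, "HR": 3.290}


@dataclass
class CohortConfig:
    """Declarative description of a synthetic cohort.

    Convenience fields (``n_null_snps``, ``direct_effects``,
    ``pure_interactions``, ``redundant_groups``) expand into LD blocks and
    an :class:`EffectModel`; explicit ``blocks`` may be given as well.
    """

    n_cases: int = 543
    n_controls: int = 529
    seed: int = 0
    male_fraction: float = 0.57
    blocks: list[LDBlockSpec] = field(default_factory=list)
    n_null_snps: int = 0
    null_maf_range: tuple[float, float] = (0.10, 0.40)
    direct_effects: dict[str, float] = field(default_factory=dict)  # locus -> per-allele log-odds
    direct_maf: float = 0.30
    pure_interactions: list[dict] = field(default_factory=list)  # {loci: [a, b], beta, maf}
    redundant_groups: list[dict] = field(default_factory=list)  # {loci: [...], maf}
    gender_effect: float = 0.0
    intercept: float = 0.0
    with_subtypes: bool = True
    with_survival: bool = True
    survival_os: SurvivalModel | None = None
    survival_efs: SurvivalModel | None = None
    survival_locus_effects: dict[str, float] = field(default_factory=dict)  # locus -> carrier HR

    @staticmethod
    def from_yaml(path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return CohortConfig.from_dict(doc.get("cohort", doc))

    @staticmethod
    def from_dict(d: Mapping) -> "CohortConfig":
        cfg = CohortConfig()
        blocks = []
        for b in d.get("blocks", []):
            blocks.append(
                LDBlockSpec(
                    locus_ids=tuple(b["locus_ids"]),
                    founder_haplotypes=tuple(tuple(h) for h in b["founder_haplotypes"]),
                    founder_frequencies=tuple(b["founder_frequencies"]),
                )
            )
        known = {f for f in CohortConfig.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        for key, value in d.items():
            if key == "blocks":
                continue
            if key in ("survival_os", "survival_efs") and isinstance(value, Mapping):
                value = SurvivalModel(**value)
            if key == "pure_interactions":
                value = [dict(v) for v in value]
            if key == "redundant_groups":
                value = [dict(v) for v in value]
            if key == "direct_effects":
                value = {str(k): float(v) for k, v in value.items()}
            if key == "null_maf_range":
                value = tuple(value)
            setattr(cfg, key, value)
        cfg.blocks = blocks
        return cfg


def _expand_blocks(config: CohortConfig, rng: np.random.Generator) -> tuple[list[LDBlockSpec], PlantedTruth, EffectModel]:
    blocks = list(config.blocks)
    truth = PlantedTruth()
    model = EffectModel(intercept=config.intercept)
    declared: set[str] = set()
    for b in blocks:
        declared |= set(b.locus_ids)

    for locus, beta in config.direct_effects.items():
        if locus not in declared:
            blocks.append(LDBlockSpec.independent(locus, config.direct_maf))
            declared.add(locus)
        model.main_effects[locus] = float(beta)
        truth.direct_loci.add(locus)

    for spec in config.pure_interactions:
        a, b = spec["loci"]
        beta = float(spec.get("beta", np.log(3.0)))
        maf = float(spec.get("maf", 0.30))
        for locus in (a, b):
            if locus not in declared:
                blocks.append(LDBlockSpec.independent(locus, maf))
                declared.add(locus)
        carrier_freq = 1.0 - (1.0 - maf) ** 2
        m = compensated_interaction_mains(beta, carrier_freq, config.intercept)
        model.interaction_effects[(a, b)] = beta
        model.carrier_main_effects[a] = model.carrier_main_effects.get(a, 0.0) + m
        model.carrier_main_effects[b] = model.carrier_main_effects.get(b, 0.0) + m
        truth.pure_interaction_pairs.add((a, b))

    for spec in config.redundant_groups:
        loci = list(spec["loci"])
        maf = float(spec.get("maf", 0.30))
        blocks.append(LDBlockSpec.two_founder(loci, maf))
        declared |= set(loci)
        truth.redundant_groups.append(set(loci))
        causal = spec.get("causal")
        if causal:
            model.main_effects[causal] = float(spec.get("beta", np.log(2.0)))
            truth.direct_loci.add(causal)

    for k in range(config.n_null_snps):
        maf = rng.uniform(*config.null_maf_range)
        locus = f"rsN{k + 1:03d}"
        blocks.append(LDBlockSpec.independent(locus, maf))
        declared.add(locus)

    if config.gender_effect:
        model.covariate_effects["gender"] = float(config.gender_effect)

    effect_loci = truth.direct_loci | {l for p in truth.pure_interaction_pairs for l in p}
    redundant = {l for g in truth.redundant_groups for l in g}
    truth.null_loci = declared - effect_loci - redundant - truth.confounder_loci
    return blocks, truth, model


def generate_cohort(config: CohortConfig, seed: int | None = None) -> tuple[DiscreteDataset, PlantedTruth]:
    """Assemble a full synthetic cohort and its ground-truth labels.

    Cases are oversampled by rejection: candidates are generated under the
    disease model until ``n_cases`` cases and ``n_controls`` controls are
    collected, preserving case-control ascertainment.  Deterministic for a
    given ``(config, seed)``.
    """
    seed = config.seed if seed is None else seed
    rng_geno = _rng(seed, _STREAM_GENO)
    rng_out = _rng(seed, _STREAM_OUTCOME)
    rng_cov = _rng(seed, _STREAM_COVARIATES)
    rng_sub = _rng(seed, _STREAM_SUBTYPES)

    blocks, truth, model = _expand_blocks(config, _rng(seed, _STREAM_GENO + 100))
    n_needed = config.n_cases + config.n_controls

    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    n_cases = n_controls = 0
    # generate in batches until both arms are filled
    batch = max(2 * n_needed, 1000)
    for _ in range(200):
        geno = pd.concat(
            [generate_block_genotypes(b, batch, rng_geno) for b in blocks], axis=1
        )
        cov = pd.DataFrame({"gender": (rng_cov.random(batch) < config.male_fraction).astype(int)})
        y = simulate_case_control(geno, cov, model, rng_out)
        frame = pd.concat([geno, cov], axis=1)
        frame["outcome"] = np.where(y == 1, "case", "control")
        need_cases = config.n_cases - n_cases
        need_controls = config.n_controls - n_controls
        new_cases = frame[frame["outcome"] == "case"].head(need_cases)
        new_controls = frame[frame["outcome"] == "control"].head(need_controls)
        cases.append(new_cases)
        controls.append(new_controls)
        n_cases += len(new_cases)
        n_controls += len(new_controls)
        if n_cases >= config.n_cases and n_controls >= config.n_controls:
            break
    else:
        raise RuntimeError("cohort generation failed to fill both arms")

    cohort = pd.concat(cases + controls, ignore_index=True)
    is_case = (cohort["outcome"] == "case").to_numpy()
    n = len(cohort)

    phenotypes = pd.DataFrame({"outcome": cohort["outcome"]})
    phenotypes["gender"] = np.where(cohort["gender"] == 1, "male", "female")
    labels: dict[str, list[str]] = {
        "outcome": ["control", "case"],
        "gender": ["female", "male"],
    }

    if config.with_subtypes:
        lineage = np.full(n, "na", dtype=object)
        lineage[is_case] = rng_sub.choice(_LINEAGE, size=is_case.sum(), p=_LINEAGE_PROBS)
        hyperdiploid = np.full(n, "na", dtype=object)
        hd_case = rng_sub.random(is_case.sum()) < 0.145
        hyperdiploid[is_case] = np.where(hd_case & (lineage[is_case] == "B"), "HD", "nonHD")
        risk = np.full(n, "na", dtype=object)
        risk[is_case] = rng_sub.choice(_RISK_GROUPS, size=is_case.sum(), p=_RISK_PROBS)
        phenotypes["lineage"] = lineage
        phenotypes["hyperdiploid"] = hyperdiploid
        phenotypes["risk_group"] = risk
        labels["lineage"] = ["na", "B", "T"]
        labels["hyperdiploid"] = ["na", "nonHD", "HD"]
        labels["risk_group"] = ["na", "LR", "MR", "HR"]

    if config.with_survival and config.with_subtypes:
        os_model = config.survival_os or SurvivalModel(
            baseline_hazard=0.0279, hazard_ratios={"risk_group": dict(_OS_HR)}
        )
        efs_model = config.survival_efs or SurvivalModel(
            baseline_hazard=0.0383, hazard_ratios={"risk_group": dict(_EFS_HR)}
        )
        for locus, hr in config.survival_locus_effects.items():
            carrier = {"0": 1.0, "1": float(hr), "2": float(hr)}
            os_model.hazard_ratios[locus] = dict(carrier)
            efs_model.hazard_ratios[locus] = dict(carrier)
        strata = phenotypes.loc[is_case, ["risk_group"]].copy()
        for locus in config.survival_locus_effects:
            strata[locus] = cohort.loc[is_case, locus].to_numpy()
        _, _, os_cat = simulate_survival(strata, os_model, _rng(seed, _STREAM_SURVIVAL_OS))
        _, _, efs_cat = simulate_survival(strata, efs_model, _rng(seed, _STREAM_SURVIVAL_EFS))
        os5 = np.full(n, "na", dtype=object)
        efs5 = np.full(n, "na", dtype=object)
        os5[is_case] = os_cat.to_numpy()
        efs5[is_case] = efs_cat.to_numpy()
        phenotypes["os5"] = os5
        phenotypes["efs5"] = efs5
        labels["os5"] = ["na", "survived", "died"]
        labels["efs5"] = ["na", "survived", "died"]

    snp_cols = [c for c in cohort.columns if c not in ("gender", "outcome")]
    genotypes = cohort[snp_cols].reset_index(drop=True).astype(np.int64)
    dataset = dataset_from_frames(
        genotypes, phenotypes.reset_index(drop=True), target_name="outcome", category_labels=labels
    )
    for c in snp_cols:  # genotype arity is 3 even if no homozygote was drawn
        dataset.arities[c] = 3
    return dataset, truth


# ---------------------------------------------------------------------------
# On-disk round trip (delimited text + truth sidecar)
# ---------------------------------------------------------------------------


def write_cohort(dataset: DiscreteDataset, truth: PlantedTruth, prefix: str | Path) -> tuple[Path, Path]:
    """Write the cohort as delimited text plus a JSON truth sidecar."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    truth_path = prefix.with_suffix(".truth.json")
    out = pd.DataFrame({"sample_id": [f"S{i:05d}" for i in range(dataset.n_samples)]})
    for v in dataset.variable_names:
        if dataset.variable_roles[v] == "snp":
            out[v] = dataset.data[v]
        else:
            labels = dataset.category_labels.get(v)
            col = dataset.data[v]
            out[v] = col.map(dict(enumerate(labels))) if labels else col
    # header layout: sample_id, outcome/covariates, then genotype columns
    pheno = [v for v in dataset.variable_names if dataset.variable_roles[v] != "snp"]
    snps = [v for v in dataset.variable_names if dataset.variable_roles[v] == "snp"]
    out = out[["sample_id"] + pheno + snps]
    out.to_csv(data_path, sep="\t", index=False)
    truth_path.write_text(truth.to_json())
    return data_path, truth_path
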