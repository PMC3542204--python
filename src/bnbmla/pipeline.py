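"""Config-driven end-to-end analysis runs.

One run reproduces the full study design on a dataset (simulated or read
from disk): QC -> LD/tag-SNP reduction -> frequentist track per phenotype
subgroup -> structure MCMC with feature posteriors per subgroup ->
posterior, interaction/redundancy, survival and convergence reports, plus
a reproducibility manifest.  All report files are deterministic for a
given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import DiscreteDataset, RawGenotypeTable, read_genotype_table
from .features import (
    FeatureQuery,
    RelevancePosterior,
    interaction_ratio,
    posterior,
)
from .freq import bh_fdr, cohort_summary, kaplan_meier, logistic_fit, logrank_test
from .ld import select_tag_snps
from .qc import apply_qc
from .sampler import SamplerConfig, run_mc3
from .simulate import CohortConfig, PlantedTruth, generate_cohort, write_cohort

log = logging.getLogger("bnbmla")

PAIRWISE_REPORT_KINDS = ("SR", "DCR", "TCR", "ConfR", "A", "PIR")


@dataclass
class SubgroupSpec:
    """One analysis subgroup: row filter, target and extra covariates.

    ``mode`` selects the row construction: ``case_control`` keeps all rows
    (optionally restricting cases to a subtype value), ``cases_only`` drops
    controls and uses a clinical target.
    """

    name: str
    target: str = "outcome"
    mode: str = "case_control"
    case_filter: dict[str, str] = field(default_factory=dict)  # column -> required label
    extra_covariates: tuple[str, ...] = ()


DEFAULT_SUBGROUPS = [
    SubgroupSpec("ALL"),
    SubgroupSpec("B-ALL", case_filter={"lineage": "B"}),
    SubgroupSpec("T-ALL", case_filter={"lineage": "T"}),
    SubgroupSpec("HD-ALL", case_filter={"hyperdiploid": "HD"}),
    SubgroupSpec("risk", target="risk_group", mode="cases_only"),
    SubgroupSpec("OS", target="os5", mode="cases_only", extra_covariates=("lineage", "risk_group")),
    SubgroupSpec("EFS", target="efs5", mode="cases_only", extra_covariates=("lineage", "risk_group")),
]


@dataclass
class AnalysisPlan:
    """Everything a full run needs beyond the data itself.

    Defaults carry the study's QC and reporting conventions: call rate
    0.90, MAF 0.10, HWE p 0.01, tag r^2 0.80, FDR alpha 0.01, parent limit
    4, relevance thresholds 0.5/0.75, Gelman-Rubin flag 1.05, and an
    |ln R| reporting floor of 0.05 for interactions/redundancies.
    """

    subgroups: list[SubgroupSpec] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    call_rate_min: float = 0.90
    maf_min: float = 0.10
    hwe_p_min: float = 0.01
    tag_r2: float = 0.80
    fdr_alpha: float = 0.01
    edge_posterior_min: float = 0.5
    ir_floor: float = 0.05
    ir_max_set_size: int = 2
    genotype_coding: str = "additive"  # or "dominant" for BN input


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    convergence: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Subgroup construction
# ---------------------------------------------------------------------------


def _compress_categories(dataset: DiscreteDataset) -> DiscreteDataset:
    """Drop unused category codes so arities reflect the observed data."""
    data = dataset.data.copy()
    arities = dict(dataset.arities)
    labels = {k: list(v) for k, v in dataset.category_labels.items()}
    for v in dataset.variable_names:
        observed = np.sort(data[v].unique())
        if dataset.variable_roles.get(v) == "snp":
            continue  # genotype coding is fixed
        if len(observed) < arities[v]:
            remap = {int(old): i for i, old in enumerate(observed)}
            data[v] = data[v].map(remap).astype(np.int64)
            arities[v] = len(observed)
            if v in labels:
                labels[v] = [labels[v][int(old)] for old in observed]
    return DiscreteDataset(
        data=data,
        arities=arities,
        target_name=dataset.target_name,
        variable_roles=dict(dataset.variable_roles),
        category_labels=labels,
    )


def build_subgroups(
    dataset: DiscreteDataset, plan: AnalysisPlan, tag_snps: list[str] | None = None
) -> dict[str, DiscreteDataset]:
    """Construct each subgroup's complete-case discrete dataset.

    Case-control subgroups keep the matching cases plus every control and
    target the case/control outcome; cases-only subgroups drop controls
    (and rows lacking the clinical target, e.g. censored before 5 years,
    with the exclusion count logged).  Gender is always retained; subtype
    variables enter only where declared in the subgroup spec.
    """
    tags = tag_snps if tag_snps is not None else dataset.snp_names
    out: dict[str, DiscreteDataset] = {}
    labels = dataset.category_labels
    for spec in plan.subgroups:
        if spec.target not in dataset.variable_names:
            continue  # dataset lacks this clinical variable (e.g. no survival)
        sub = dataset
        outcome_code = {lab: i for i, lab in enumerate(labels.get("outcome", []))}
        is_case = sub.data["outcome"].to_numpy() == outcome_code.get("case", 1)
        if spec.mode == "case_control":
            mask = ~is_case
            case_mask = is_case.copy()
            for col, needed in spec.case_filter.items():
                if col not in sub.variable_names:
                    raise StageError("subgroups", f"{spec.name}: filter column {col!r} missing")
                code = labels.get(col, []).index(needed)
                case_mask &= sub.data[col].to_numpy() == code
            mask = mask | case_mask
        elif spec.mode == "cases_only":
            mask = is_case.copy()
            na_code = labels.get(spec.target, []).index("na") if "na" in labels.get(spec.target, []) else None
            if na_code is not None:
                known = sub.data[spec.target].to_numpy() != na_code
                dropped = int((mask & ~known).sum())
                if dropped:
                    log.info("%s: excluded %d cases without %s", spec.name, dropped, spec.target)
                mask &= known
        else:
            raise StageError("subgroups", f"unknown subgroup mode {spec.mode!r}")
        if not mask.any():
            raise StageError("subgroups", f"{spec.name}: empty subgroup")
        keep_vars = list(tags) + ["gender"] + [c for c in spec.extra_covariates] + [spec.target]
        if spec.mode == "case_control":
            keep_vars.append("outcome")
        keep_vars = list(dict.fromkeys(v for v in keep_vars if v in sub.variable_names))
        built = sub.select_rows(mask).select_variables(keep_vars, target=spec.target)
        built = _compress_categories(built)
        if built.arities[spec.target] < 2:
            raise StageError("subgroups", f"{spec.name}: target has a single category")
        out[spec.name] = built
    return out


# ---------------------------------------------------------------------------
# Frequentist track
# ---------------------------------------------------------------------------


def frequentist_subgroup(sub: DiscreteDataset, plan: AnalysisPlan) -> pd.DataFrame:
    """Gender-adjusted additive logistic regression per SNP (binary targets)."""
    target = sub.target_name
    if sub.arities[target] != 2:
        return pd.DataFrame()
    y = sub.data[target].to_numpy()
    rows = []
    adjust = ["gender"] if "gender" in sub.variable_names and target != "gender" else []
    for snp in sub.snp_names:
        X_cols = [sub.data[snp].to_numpy(dtype=float)]
        names = [snp]
        for a in adjust:
            X_cols.append(sub.data[a].to_numpy(dtype=float))
            names.append(a)
        X = np.column_stack(X_cols)
        try:
            fit = logistic_fit(X, y, names=names)
        except Exception as exc:  # separation / non-convergence on a SNP
            rows.append({"rs_id": snp, "model": "additive", "error": str(exc)})
            continue
        rows.append(
            {
                "rs_id": snp,
                "model": "additive",
                "odds_ratio": fit.odds_ratios[1],
                "ci_low": fit.ci95[1, 0],
                "ci_high": fit.ci95[1, 1],
                "p_value": fit.p_values[1],
                "adjusted_for": ",".join(adjust),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian track
# ---------------------------------------------------------------------------


def bmla_subgroup(
    sub: DiscreteDataset, plan: AnalysisPlan, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Run MC3 on one subgroup; returns posterior, IR/RR and edge tables."""
    if plan.genotype_coding == "dominant":
        sub = sub.recode_dominant()
    from dataclasses import replace

    sampler = replace(plan.sampler, seed=seed)
    target = sub.target_name
    predictors = [v for v in sub.variable_names if v != target]
    queries = [
        FeatureQuery(kind=kind, variables=(v,), target=target)
        for v in predictors
        for kind in PAIRWISE_REPORT_KINDS
    ]
    sample, traces, report = run_mc3(sub, sampler, queries)

    post_rows = []
    for v in predictors:
        row: dict[str, object] = {"variable": v}
        for kind in PAIRWISE_REPORT_KINDS:
            rp = posterior(sample, FeatureQuery(kind=kind, variables=(v,), target=target))
            row[kind] = round(rp.posterior, 4)
            if kind == "SR":
                row["SR_se"] = round(rp.mc_standard_error, 4)
                row["classification"] = rp.classification
        post_rows.append(row)
    post = pd.DataFrame(post_rows).sort_values("SR", ascending=False).reset_index(drop=True)

    ir_rows = []
    from itertools import combinations

    sizes = range(2, plan.ir_max_set_size + 1)
    for k in sizes:
        for combo in combinations(predictors, k):
            res = interaction_ratio(sample, combo, target)
            if res.undefined or res.ratio is None:
                continue
            log_r = float(np.log(res.ratio)) if res.ratio > 0 else float("-inf")
            if abs(log_r) < plan.ir_floor:
                continue
            ir_rows.append(
                {
                    "variables": "+".join(combo),
                    "joint_posterior": round(res.joint_posterior, 4),
                    "ratio": round(res.ratio, 4),
                    "IR": round(res.interaction_ratio, 4),
                    "RR": round(res.redundancy_ratio, 4),
                }
            )
    ir = pd.DataFrame(ir_rows, columns=["variables", "joint_posterior", "ratio", "IR", "RR"])

    edge_p = sample.edge_posteriors()
    edge_rows = []
    for u in range(len(sample.names)):
        for v in range(len(sample.names)):
            if edge_p[u, v] > plan.edge_posterior_min:
                edge_rows.append(
                    {
                        "parent": sample.names[u],
                        "child": sample.names[v],
                        "posterior": round(float(edge_p[u, v]), 4),
                    }
                )
    edges = pd.DataFrame(edge_rows, columns=["parent", "child", "posterior"])
    conv = {f: r for f, r in report.r_scores.items()}
    return post, ir, edges, conv


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    cohort: CohortConfig | None = None
    input_table: str | None = None
    input_dialect: str = "delimited"
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        cfg = PipelineConfig()
        known = {"cohort", "input_table", "input_dialect", "seed", "qc", "tags", "freq", "sampler", "features", "subgroups"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if "cohort" in doc:
            cfg.cohort = CohortConfig.from_dict(doc["cohort"])
        cfg.input_table = doc.get("input_table")
        cfg.input_dialect = doc.get("input_dialect", "delimited")
        cfg.seed = int(doc.get("seed", 0))
        plan = AnalysisPlan()
        qc = doc.get("qc", {})
        plan.call_rate_min = float(qc.get("call_rate_min", plan.call_rate_min))
        plan.maf_min = float(qc.get("maf_min", plan.maf_min))
        plan.hwe_p_min = float(qc.get("hwe_p_min", plan.hwe_p_min))
        plan.tag_r2 = float(doc.get("tags", {}).get("r2_threshold", plan.tag_r2))
        plan.fdr_alpha = float(doc.get("freq", {}).get("fdr_alpha", plan.fdr_alpha))
        feats = doc.get("features", {})
        plan.edge_posterior_min = float(feats.get("edge_posterior_min", plan.edge_posterior_min))
        plan.ir_floor = float(feats.get("ir_floor", plan.ir_floor))
        plan.ir_max_set_size = int(feats.get("ir_max_set_size", plan.ir_max_set_size))
        plan.genotype_coding = feats.get("genotype_coding", plan.genotype_coding)
        samp = doc.get("sampler", {})
        if samp:
            defaults = SamplerConfig()
            ladder = tuple(samp.get("temperature_ladder", defaults.temperature_ladder))
            plan.sampler = SamplerConfig(
                n_chains=int(samp.get("n_chains", len(ladder))),
                temperature_ladder=ladder,
                burn_in_steps=int(samp.get("burn_in_steps", defaults.burn_in_steps)),
                sample_steps=int(samp.get("sample_steps", defaults.sample_steps)),
                thinning=int(samp.get("thinning", defaults.thinning)),
                swap_interval=int(samp.get("swap_interval", defaults.swap_interval)),
                max_in_degree=int(samp.get("max_in_degree", defaults.max_in_degree)),
                n_replicates=int(samp.get("n_replicates", defaults.n_replicates)),
                structure_prior=samp.get("structure_prior", defaults.structure_prior),
            )
        if "subgroups" in doc:
            plan.subgroups = [
                SubgroupSpec(
                    name=s["name"],
                    target=s.get("target", "outcome"),
                    mode=s.get("mode", "case_control"),
                    case_filter=dict(s.get("case_filter", {})),
                    extra_covariates=tuple(s.get("extra_covariates", ())),
                )
                for s in doc["subgroups"]
            ]
        cfg.plan = plan
        return cfg


def run_full_analysis(
    config: PipelineConfig | str | Path,
    output_dir: str | Path,
    seed: int | None = None,
    chain_scale: float = 1.0,
    run_freq: bool = True,
    run_bn: bool = True,
) -> RunManifest:
    """Execute every stage and write the report bundle.

    Raises a :class:`StageError` naming the failing stage; report files are
    tab-separated tables, the manifest is JSON.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    seed = config.seed if seed is None else seed
    plan = config.plan
    if chain_scale != 1.0:
        plan.sampler = plan.sampler.scaled(chain_scale)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(_config_fingerprint(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=config_hash, seed=seed, version=__version__)

    # -- stage: data ------------------------------------------------------
    truth: PlantedTruth | None = None
    if config.cohort is not None:
        dataset, truth = generate_cohort(config.cohort, seed=seed)
        write_cohort(dataset, truth, out / "cohort")
        raw = _raw_from_dataset(dataset)
    elif config.input_table:
        raw = read_genotype_table(config.input_table, dialect=config.input_dialect)
    else:
        raise StageError("data", "config provides neither a cohort nor an input table")
    manifest.stage_counts["data"] = {"rows": len(raw.sample_ids), "snps": len(raw.snp_names)}

    # -- stage: qc --------------------------------------------------------
    try:
        dataset, qc_report = apply_qc(
            raw,
            call_rate_min=plan.call_rate_min,
            maf_min=plan.maf_min,
            hwe_p_min=plan.hwe_p_min,
        )
    except Exception as exc:
        raise StageError("qc", str(exc)) from exc
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest.stage_counts["qc"] = {
        "snps_in": qc_report.input_count,
        "snps_out": qc_report.retained_count,
        "samples_removed": qc_report.samples_removed_incomplete,
    }

    # -- stage: tags ------------------------------------------------------
    tags = select_tag_snps(dataset, r2_threshold=plan.tag_r2)
    pd.DataFrame(
        [{"tag": t, "proxies": ",".join(sorted(tags.proxy_map()[t]))} for t in tags.tags]
    ).to_csv(out / "tag_snps.tsv", sep="\t", index=False)
    manifest.stage_counts["tags"] = {"tags": len(tags.tags)}

    cohort_summary(dataset).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

    # -- stage: subgroups -------------------------------------------------
    subgroups = build_subgroups(dataset, plan, tag_snps=tags.tags)
    manifest.stage_counts["subgroups"] = {name: len(ds.data) for name, ds in subgroups.items()}

    # -- stage: frequentist ----------------------------------------------
    freq_frames = []
    for name, sub in subgroups.items() if run_freq else []:
        frame = frequentist_subgroup(sub, plan)
        if not frame.empty:
            frame.insert(0, "subgroup", name)
            freq_frames.append(frame)
    if freq_frames:
        freq = pd.concat(freq_frames, ignore_index=True)
        ok = freq["p_value"].notna() if "p_value" in freq else pd.Series(dtype=bool)
        if ok.any():
            sig, threshold = bh_fdr(freq.loc[ok, "p_value"].to_numpy(), alpha=plan.fdr_alpha)
            freq.loc[ok, "fdr_significant"] = sig
            freq.attrs["fdr_m"] = int(ok.sum())
            freq.attrs["fdr_threshold"] = threshold
            manifest.stage_counts["fdr"] = {"m": int(ok.sum()), "significant": int(sig.sum())}
        freq.to_csv(out / "frequentist.tsv", sep="\t", index=False)

    # survival track on cases with known 5-year outcome
    _survival_reports(dataset, out, manifest)

    # -- stage: BN-BMLA ---------------------------------------------------
    max_r_overall = 0.0
    for i, (name, sub) in enumerate(subgroups.items() if run_bn else []):
        sub_seed = int((seed * 97 + i) % (2**31 - 1))
        post, ir, edges, conv = bmla_subgroup(sub, plan, sub_seed)
        safe = name.replace("/", "_")
        post.to_csv(out / f"posteriors_{safe}.tsv", sep="\t", index=False)
        ir.to_csv(out / f"interactions_{safe}.tsv", sep="\t", index=False)
        edges.to_csv(out / f"averaged_structure_{safe}.tsv", sep="\t", index=False)
        finite = [r for r in conv.values() if np.isfinite(r)]
        if finite:
            manifest.convergence[name] = round(float(max(finite)), 4)
            max_r_overall = max(max_r_overall, max(finite))
        pd.DataFrame(
            [{"feature": f, "gelman_rubin_R": round(r, 4)} for f, r in sorted(conv.items())]
        ).to_csv(out / f"convergence_{safe}.tsv", sep="\t", index=False)
    manifest.convergence["max_R"] = round(float(max_r_overall), 4)

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _survival_reports(dataset: DiscreteDataset, out: Path, manifest: RunManifest) -> None:
    # Kaplan-Meier needs times; the discrete dataset only carries the 5-year
    # category, so the KM report is expressed on the category scale: per-arm
    # survivor fractions by risk group, with a log-rank on the discrete data
    # when a time column is unavailable this stage is skipped.
    if "os5" not in dataset.variable_names or "risk_group" not in dataset.variable_names:
        return
    labels = dataset.category_labels
    os_labels = labels.get("os5", [])
    rg_labels = labels.get("risk_group", [])
    if "survived" not in os_labels:
        return
    survived = os_labels.index("survived")
    died = os_labels.index("died")
    rows = []
    for code, rg in enumerate(rg_labels):
        if rg == "na":
            continue
        mask = dataset.data["risk_group"] == code
        n_known = int(dataset.data.loc[mask, "os5"].isin([survived, died]).sum())
        n_surv = int((dataset.data.loc[mask, "os5"] == survived).sum())
        if n_known:
            rows.append(
                {"risk_group": rg, "n": n_known, "five_year_survival_pct": round(100 * n_surv / n_known, 1)}
            )
    pd.DataFrame(rows).to_csv(out / "survival_by_risk_group.tsv", sep="\t", index=False)


def _raw_from_dataset(dataset: DiscreteDataset) -> RawGenotypeTable:
    snps = dataset.snp_names
    pheno_cols = [v for v in dataset.variable_names if v not in snps]
    pheno = pd.DataFrame()
    for v in pheno_cols:
        labels = dataset.category_labels.get(v)
        col = dataset.data[v]
        pheno[v] = col.map(dict(enumerate(labels))) if labels else col.astype(str)
    return RawGenotypeTable(
        sample_ids=[f"S{i:05d}" for i in range(dataset.n_samples)],
        genotypes=dataset.data[snps].copy(),
        phenotypes=pheno,
        variable_roles={**{s: "snp" for s in snps}, **{v: dataset.variable_roles[v] for v in pheno_cols}},
        target_name=dataset.target_name,
        category_labels={v: list(l) for v, l in dataset.category_labels.items()},
    )


def _config_fingerprint(config: PipelineConfig) -> dict:
    def clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set)):
            return [clean(v) for v in obj]
        return obj

    return {
        "cohort": clean(config.cohort) if config.cohort else None,
        "input_table": config.input_table,
        "plan": clean(config.plan),
        "seed": config.seed,
    }
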