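"""Genotype quality control: Hardy-Weinberg test and SNP/sample filtering.

QC mirrors standard candidate-gene practice: drop monomorphic SNPs, SNPs
with poor call rates, low-MAF SNPs and SNPs out of Hardy-Weinberg
equilibrium in controls, then reduce to complete cases so the downstream
Dirichlet-multinomial scoring sees no missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, DiscreteDataset, RawGenotypeTable, dataset_from_frames


class EmptyDatasetError(ValueError):
    """All SNPs (or all samples) were removed by QC."""


@dataclass
class QCReport:
    """Itemized record of what QC removed and why."""

    input_count: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    retained_count: int = 0
    samples_input: int = 0
    samples_removed_incomplete: int = 0

    def removed_union(self) -> set[str]:
        out: set[str] = set()
        for ids in self.removed.values():
            out |= set(ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "rs_id": rs}
            for rule, ids in sorted(self.removed.items())
            for rs in ids
        ]
        return pd.DataFrame(rows, columns=["rule", "rs_id"])


def hwe_chi2_of_counts(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected genotype counts derive from the sample allele frequency.  A
    monomorphic sample is in trivial equilibrium: returns ``(0.0, 1.0)``.

    Returns
    -------
    (chi2, p)
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * counts[0] + counts[1]) / (2 * n)  # frequency of allele A
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    observed = column[column != MISSING]
    return (
        int((observed == 0).sum()),
        int((observed == 1).sum()),
        int((observed == 2).sum()),
    )


def apply_qc(
    raw: RawGenotypeTable,
    call_rate_min: float = 0.90,
    maf_min: float = 0.10,
    hwe_p_min: float = 0.01,
    control_mask: np.ndarray | None = None,
    impute_mode: bool = False,
) -> tuple[DiscreteDataset, QCReport]:
    """Filter SNPs, then samples, returning a complete-case dataset.

    SNP-level rules (order-insensitive, applied to the raw table):

    - ``monomorphic``: no variation among observed calls;
    - ``call_rate``: fraction of non-missing calls below ``call_rate_min``;
    - ``low_maf``: minor allele frequency below ``maf_min``;
    - ``hwe``: Hardy-Weinberg p-value below ``hwe_p_min``, tested in controls
      only (case frequencies are distorted by true association).

    ``control_mask`` marks control rows for the HWE test; when omitted, rows
    whose binary target equals the category labelled ``control`` (falling
    back to the first category) are used, otherwise all rows.

    After SNP filtering, samples with any remaining missing genotype are
    dropped (complete-case) unless ``impute_mode`` is set, in which case
    missing calls are replaced by the SNP's most frequent genotype.
    """
    report = QCReport(input_count=len(raw.snp_names), samples_input=len(raw.sample_ids))
    geno = raw.genotypes.to_numpy(dtype=np.int64)
    call_rates = raw.call_rates()
    mafs = raw.minor_allele_frequencies()

    if control_mask is None:
        control_mask = _default_control_mask(raw)
    control_mask = np.asarray(control_mask, dtype=bool)

    removed: dict[str, list[str]] = {"monomorphic": [], "call_rate": [], "low_maf": [], "hwe": []}
    for j, snp in enumerate(raw.snp_names):
        observed = geno[:, j][geno[:, j] != MISSING]
        if observed.size == 0 or np.all(observed == observed[0]):
            removed["monomorphic"].append(snp)
        if call_rates[snp] < call_rate_min:
            removed["call_rate"].append(snp)
        if observed.size and not np.all(observed == observed[0]) and mafs[snp] < maf_min:
            removed["low_maf"].append(snp)
        n_AA, n_Aa, n_aa = _genotype_counts(geno[control_mask, j])
        if n_AA + n_Aa + n_aa > 0:
            _, p = hwe_chi2_of_counts(n_AA, n_Aa, n_aa)
            if p < hwe_p_min:
                removed["hwe"].append(snp)
    report.removed = {rule: ids for rule, ids in removed.items() if ids}

    keep = [s for s in raw.snp_names if s not in report.removed_union()]
    report.retained_count = len(keep)
    if not keep:
        raise EmptyDatasetError("QC removed every SNP")

    genotypes = raw.genotypes[keep].copy()
    phenotypes = raw.phenotypes.copy()
    if impute_mode:
        for s in keep:
            col = genotypes[s].to_numpy()
            observed = col[col != MISSING]
            mode = np.bincount(observed, minlength=3).argmax()
            genotypes[s] = np.where(col == MISSING, mode, col)
        complete = np.ones(len(genotypes), dtype=bool)
    else:
        complete = (genotypes.to_numpy() != MISSING).all(axis=1)
    report.samples_removed_incomplete = int((~complete).sum())
    if not complete.any():
        raise EmptyDatasetError("complete-case filtering removed every sample")
    genotypes = genotypes.loc[complete].reset_index(drop=True)
    phenotypes = phenotypes.loc[complete].reset_index(drop=True)
    dataset = dataset_from_frames(
        genotypes, phenotypes, target_name=raw.target_name, category_labels=raw.category_labels
    )
    return dataset, report


def _default_control_mask(raw: RawGenotypeTable) -> np.ndarray:
    if raw.target_name in raw.phenotypes.columns:
        col = raw.phenotypes[raw.target_name].astype(str)
        cats = sorted(col.unique())
        if len(cats) == 2:
            for label in ("control", "controls", "0"):
                if label in cats:
                    return (col == label).to_numpy()
            return (col == cats[0]).to_numpy()
    return np.ones(len(raw.sample_ids), dtype=bool)
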