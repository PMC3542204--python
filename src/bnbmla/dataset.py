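"""Discrete case-control dataset container and delimited-text genotype I/O.

The whole analysis operates on complete-case matrices of categorical
variables: SNP genotypes coded as minor-allele counts (0/1/2), categorical
covariates (gender, lineage, risk group, ...) and one designated outcome
column.  :class:`DiscreteDataset` is the sole input to Bayesian-network
scoring, so it enforces the assumptions the closed-form marginal likelihood
requires: no missing cells and every observed code below the variable's
arity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  #: internal sentinel for a missing genotype in raw tables

VALID_ROLES = ("snp", "covariate", "outcome")


class GenotypeParseError(ValueError):
    """Raised when a genotype table violates the documented format."""


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP annotation row (rs id, gene, alleles, call rate, MAF)."""

    rs_id: str
    gene: str = ""
    alleles: tuple[str, str] = ("A", "a")
    position: str = ""
    call_rate: float = 1.0
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate out of [0, 1]: {self.call_rate}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf out of [0, 0.5]: {self.maf}")


@dataclass
class RawGenotypeTable:
    """Parsed genotype table that may still contain missing genotypes.

    ``genotypes`` holds integer codes with :data:`MISSING` for absent calls;
    covariate/outcome columns are kept as pandas categoricals.
    """

    sample_ids: list[str]
    genotypes: pd.DataFrame  # int codes, MISSING allowed
    phenotypes: pd.DataFrame  # categorical covariate/outcome columns
    variable_roles: dict[str, str]
    target_name: str
    category_labels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def snp_names(self) -> list[str]:
        return list(self.genotypes.columns)

    def call_rates(self) -> pd.Series:
        present = (self.genotypes.to_numpy() != MISSING).mean(axis=0)
        return pd.Series(present, index=self.genotypes.columns)

    def minor_allele_frequencies(self) -> pd.Series:
        """Allele-counting MAF per SNP, ignoring missing calls."""
        g = self.genotypes.to_numpy(dtype=float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(g, axis=0) / 2.0
        freq = np.minimum(freq, 1.0 - freq)
        return pd.Series(freq, index=self.genotypes.columns)


@dataclass
class DiscreteDataset:
    """Complete-case matrix of categorical variables for BN scoring.

    Parameters
    ----------
    data:
        ``n x p`` integer-coded DataFrame; every column is a variable and
        every value must satisfy ``0 <= value < arity`` for its column.
    arities:
        Number of categories per variable, aligned with ``data`` columns.
    target_name:
        The designated outcome variable (must be a column of ``data``).
    variable_roles:
        Mapping variable name -> ``snp`` / ``covariate`` / ``outcome``.
    category_labels:
        Optional mapping variable -> sequence of human-readable labels
        indexed by code (used when writing reports).
    """

    data: pd.DataFrame
    arities: dict[str, int]
    target_name: str
    variable_roles: dict[str, str]
    category_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if set(cols) != set(self.arities):
            raise ValueError("arities must cover exactly the data columns")
        if self.target_name not in cols:
            raise ValueError(f"target {self.target_name!r} not in dataset")
        for name, role in self.variable_roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for {name!r}")
        values = self.data.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("dataset contains missing/negative codes")
        for j, name in enumerate(cols):
            if values.size and values[:, j].max() >= self.arities[name]:
                raise ValueError(
                    f"variable {name!r} has a code >= arity {self.arities[name]}"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def snp_names(self) -> list[str]:
        return [v for v in self.variable_names if self.variable_roles.get(v) == "snp"]

    def arity_vector(self) -> np.ndarray:
        return np.array([self.arities[v] for v in self.variable_names], dtype=np.int64)

    def matrix(self) -> np.ndarray:
        """Observations as an ``n x p`` int64 array (column order preserved)."""
        cached = self.__dict__.get("_matrix_cache")
        if cached is None or cached.shape != self.data.shape:
            cached = np.ascontiguousarray(self.data.to_numpy(dtype=np.int64))
            self.__dict__["_matrix_cache"] = cached
        return cached

    def target_index(self) -> int:
        return self.variable_names.index(self.target_name)

    # -- transformations -------------------------------------------------

    def select_variables(self, names: Sequence[str], target: str | None = None) -> "DiscreteDataset":
        target = target or self.target_name
        if target not in names:
            names = list(names) + [target]
        return DiscreteDataset(
            data=self.data[list(names)].reset_index(drop=True),
            arities={v: self.arities[v] for v in names},
            target_name=target,
            variable_roles={v: self.variable_roles.get(v, "covariate") for v in names},
            category_labels={v: l for v, l in self.category_labels.items() if v in names},
        )

    def select_rows(self, mask: np.ndarray) -> "DiscreteDataset":
        return replace(self, data=self.data.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def with_target(self, target: str) -> "DiscreteDataset":
        if target not in self.variable_names:
            raise ValueError(f"target {target!r} not in dataset")
        roles = dict(self.variable_roles)
        return replace(self, target_name=target, variable_roles=roles)

    def recode_dominant(self, snps: Iterable[str] | None = None) -> "DiscreteDataset":
        """Collapse genotype columns to carrier (>=1 minor allele) / non-carrier.

        The BN default is 3-level genotypes; dominant recoding is the option
        used when carrier-level effects are of interest.
        """
        snps = list(snps) if snps is not None else self.snp_names
        data = self.data.copy()
        arities = dict(self.arities)
        for s in snps:
            data[s] = (data[s] > 0).astype(np.int64)
            arities[s] = 2
        return replace(self, data=data, arities=arities)


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Documented header layout: sample_id, <outcome>, <covariates...>, rs...
# Genotype columns are coded 0/1/2 with "NA" (delimited dialect) or the PLINK
# additive-export convention ("NA" / "-9") for missing calls.
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"delimited": {"NA", ""}, "plink": {"NA", "-9"}}


def _is_genotype_column(name: str) -> bool:
    return name.startswith("rs") or name.startswith("snp")


def read_genotype_table(
    path: str | Path,
    dialect: str = "delimited",
    target_name: str | None = None,
    sep: str = "\t",
) -> RawGenotypeTable:
    """Read a delimited genotype table into a :class:`RawGenotypeTable`.

    Columns whose names start with ``rs``/``snp`` are genotype columns and
    must contain only ``0``, ``1``, ``2`` or the dialect's missing markers;
    all other columns (besides ``sample_id``) are phenotype columns.  Column
    order is preserved.
    """
    path = Path(path)
    if dialect not in _MISSING_TOKENS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise GenotypeParseError(f"{path}: malformed header (no sample_id column)")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Series(sample_ids)
        name = dup[dup.duplicated()].iloc[0]
        raise GenotypeParseError(f"{path}: duplicated sample ID {name!r}")

    missing_tokens = _MISSING_TOKENS[dialect]
    geno_cols = [c for c in df.columns if _is_genotype_column(c)]
    pheno_cols = [c for c in df.columns if c != "sample_id" and c not in geno_cols]
    if not geno_cols:
        raise GenotypeParseError(f"{path}: no genotype (rs*/snp*) columns found")

    geno = np.empty((len(df), len(geno_cols)), dtype=np.int64)
    for j, col in enumerate(geno_cols):
        for i, token in enumerate(df[col]):
            token = token.strip()
            if token in missing_tokens:
                geno[i, j] = MISSING
            elif token in ("0", "1", "2"):
                geno[i, j] = int(token)
            else:
                raise GenotypeParseError(
                    f"{path}: invalid genotype token {token!r} at row {i + 2}, column {col!r}"
                )

    phenotypes = df[pheno_cols].copy()
    roles = {c: "snp" for c in geno_cols}
    if target_name is None:
        target_name = pheno_cols[0] if pheno_cols else geno_cols[0]
    for c in pheno_cols:
        roles[c] = "outcome" if c == target_name else "covariate"
    return RawGenotypeTable(
        sample_ids=sample_ids,
        genotypes=pd.DataFrame(geno, columns=geno_cols),
        phenotypes=phenotypes,
        variable_roles=roles,
        target_name=target_name,
    )


def write_genotype_table(raw: RawGenotypeTable, path: str | Path, sep: str = "\t") -> None:
    """Write a raw table back to delimited text (inverse of the reader)."""
    geno = raw.genotypes.astype(object).where(raw.genotypes != MISSING, "NA")
    out = pd.concat(
        [pd.Series(raw.sample_ids, name="sample_id"), raw.phenotypes.reset_index(drop=True), geno],
        axis=1,
    )
    out.to_csv(path, sep=sep, index=False)


def dataset_from_frames(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    target_name: str,
    category_labels: Mapping[str, list[str]] | None = None,
) -> DiscreteDataset:
    """Assemble a complete-case :class:`DiscreteDataset` from coded frames.

    Phenotype columns are label-encoded (sorted unique values) unless a label
    list is supplied, in which case codes follow that list's order.
    """
    category_labels = dict(category_labels or {})
    data = genotypes.copy()
    arities = {c: max(int(genotypes[c].max()) + 1, 2) if len(genotypes) else 3 for c in genotypes}
    roles = {c: "snp" for c in genotypes}
    labels_out: dict[str, list[str]] = {}
    for c in phenotypes.columns:
        col = phenotypes[c].astype(str)
        labels = category_labels.get(c) or sorted(col.unique())
        # case-control columns always encode control = 0, case = 1
        if c not in category_labels and set(col.unique()) <= {"control", "case"}:
            labels = ["control", "case"]
        lookup = {lab: i for i, lab in enumerate(labels)}
        unknown = set(col.unique()) - set(labels)
        if unknown:
            raise ValueError(f"column {c!r}: values {unknown} missing from labels")
        data[c] = col.map(lookup).astype(np.int64)
        arities[c] = len(labels)
        roles[c] = "outcome" if c == target_name else "covariate"
        labels_out[c] = list(labels)
    return DiscreteDataset(
        data=data.reset_index(drop=True),
        arities=arities,
        target_name=target_name,
        variable_roles=roles,
        category_labels=labels_out,
    )
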