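"""Two-locus linkage disequilibrium from unphased genotypes and tag-SNP pruning.

Haplotype frequencies for a pair of biallelic loci are estimated by EM over
the 3x3 unphased genotype table (only the double heterozygote is phase
ambiguous).  D, D' and r^2 follow from the converged frequencies.  Tag
selection is the usual greedy r^2 pruning, iterating SNPs by descending MAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DiscreteDataset


class MonomorphicLocusError(ValueError):
    """LD is undefined for a locus with no variation."""


@dataclass(frozen=True)
class LDResult:
    D: float
    D_prime: float
    r2: float
    haplotype_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)


def _check_polymorphic(g: np.ndarray, name: str) -> None:
    if g.size == 0 or np.all(g == g[0]):
        raise MonomorphicLocusError(f"{name}: monomorphic locus, LD undefined")


def pairwise_ld(
    geno_x: np.ndarray,
    geno_y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """EM estimate of two-locus LD from unphased 0/1/2 genotype vectors.

    Alleles are labelled so that ``A``/``B`` are the major (code-0) alleles
    at each locus.  Iteration stops when the largest haplotype-frequency
    change falls below ``tol`` or after ``max_iter`` sweeps.
    """
    x = np.asarray(geno_x, dtype=np.int64)
    y = np.asarray(geno_y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("genotype vectors differ in length")
    _check_polymorphic(x, "geno_x")
    _check_polymorphic(y, "geno_y")

    # 3x3 joint genotype counts; n[i, j] = #individuals with i copies of the
    # minor allele at locus X and j copies at locus Y.
    n = np.zeros((3, 3), dtype=float)
    np.add.at(n, (x, y), 1.0)
    total = 2.0 * n.sum()

    # Haplotypes over (allele at X, allele at Y) with 0 = major: order
    # AB (0,0), Ab (0,1), aB (1,0), ab (1,1).  Every cell except the double
    # heterozygote contributes phase-known haplotypes.
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = n[i, j]
            if c == 0:
                continue
            if i == 1:
                yall = 0 if j == 0 else 1  # j in {0, 2}
                base[0 * 2 + yall] += c  # chromosome with major X allele
                base[1 * 2 + yall] += c  # chromosome with minor X allele
            elif j == 1:
                xall = 0 if i == 0 else 1
                base[xall * 2 + 0] += c
                base[xall * 2 + 1] += c
            else:
                xall = 0 if i == 0 else 1
                yall = 0 if j == 0 else 1
                base[xall * 2 + yall] += 2 * c
    n_dh = n[1, 1]

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        # E step: split double heterozygotes between AB/ab and Ab/aB phases
        if n_dh > 0:
            p_cis = freqs[0] * freqs[3]
            p_trans = freqs[1] * freqs[2]
            denom = p_cis + p_trans
            w = 0.5 if denom == 0 else p_cis / denom
        else:
            w = 0.0
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        new = counts / total
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new

    p_AB, p_Ab, p_aB, p_ab = freqs
    p_A = p_AB + p_Ab
    p_B = p_AB + p_aB
    D = p_AB - p_A * p_B
    if D >= 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    D_prime = 0.0 if d_max == 0 else abs(D) / d_max
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    r2 = 0.0 if denom == 0 else D * D / denom
    return LDResult(D=float(D), D_prime=float(D_prime), r2=float(r2), haplotype_freqs=tuple(freqs))


@dataclass
class TagSelection:
    """Greedy tag-SNP pruning outcome."""

    tags: list[str]
    proxies: dict[str, str] = field(default_factory=dict)  # pruned SNP -> its tag
    r2_threshold: float = 0.80

    def proxy_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.tags}
        for snp, tag in self.proxies.items():
            out[tag].append(snp)
        return out


def select_tag_snps(dataset: DiscreteDataset, r2_threshold: float = 0.80) -> TagSelection:
    """Greedy r^2 pruning of SNPs into tags and proxies.

    SNPs are visited by descending MAF (ties broken by ascending rs id).  A
    SNP becomes a tag unless its r^2 with an existing tag reaches the
    threshold, in which case it is recorded as a proxy of the tag with the
    highest r^2.  Idempotent: rerunning on the tags changes nothing.
    """
    snps = dataset.snp_names
    g = {s: dataset.data[s].to_numpy(dtype=np.int64) for s in snps}
    mafs = {}
    for s in snps:
        freq = g[s].mean() / 2.0
        mafs[s] = min(freq, 1.0 - freq)
    order = sorted(snps, key=lambda s: (-mafs[s], s))

    tags: list[str] = []
    proxies: dict[str, str] = {}
    for s in order:
        best_tag, best_r2 = None, -1.0
        for t in tags:
            try:
                r2 = pairwise_ld(g[s], g[t]).r2
            except MonomorphicLocusError:
                continue
            if r2 >= r2_threshold and r2 > best_r2:
                best_tag, best_r2 = t, r2
        if best_tag is None:
            tags.append(s)
        else:
            proxies[s] = best_tag
    return TagSelection(tags=tags, proxies=proxies, r2_threshold=r2_threshold)
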