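"""Synthetic quantitative-trait GWAS generator for the method comparison.

The generator reproduces the study design used to measure type-I error
and power of the competitive tests: N unrelated individuals typed at K
biallelic SNPs, one SNP per gene (so SNPs and genes are interchangeable
here).  Per SNP, a minor allele frequency q ~ Uniform(0, 0.5) and
genotypes 0/1/2 drawn under Hardy-Weinberg equilibrium with probabilities
(1-q)^2, 2q(1-q), q^2.  A sparse effect vector beta (M non-zero entries)
defines an additive quantitative phenotype

    y_i = sum_j beta_j * g_ij  (+ optional iid Normal noise),

so the M-1 other effect SNPs form the noise background for any one SNP.
Association is the per-SNP two-sided t-test of the slope in simple linear
regression of y on the genotype column.

Null scenarios draw the pathway and the effect SNPs independently;
alternative (enrichment) scenarios give a proportion pi of pathway genes
effects of variance sigma1_sq and place the remaining effects outside
the pathway with smaller variance sigma2_sq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .ranks import GeneScores

__all__ = [
    "Scenario",
    "SimulatedStudy",
    "sample_maf",
    "genotype_matrix",
    "assign_effects",
    "phenotype",
    "single_snp_pvalues",
    "simulate_study",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration.

    Defaults follow the comparison study: N=100 individuals, K=20000
    SNPs/genes, pathway sizes 20/60/100, total effect counts 50/100/200,
    null effect variances 1/2/4 and alternative variance pairs with the
    pathway variance the larger one.
    """

    L: int                      # pathway size
    M: int                      # total SNPs with effects
    kind: str = "null"          # null | alternative
    N: int = 100
    K: int = 20000
    sigma2_null: float = 1.0    # effect variance under the null
    pi: float | None = None     # proportion of pathway genes with effects
    sigma1_sq: float | None = None  # pathway effect variance (alternative)
    sigma2_sq: float | None = None  # non-pathway effect variance (alternative)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("null", "alternative"):
            raise ValueError("kind must be 'null' or 'alternative'")
        if not (1 <= self.L <= self.K and 1 <= self.M <= self.K):
            raise ValueError("L and M must lie in [1, K]")
        if self.kind == "alternative":
            if self.pi is None or self.sigma1_sq is None or self.sigma2_sq is None:
                raise ValueError("alternative scenarios need pi, sigma1_sq, sigma2_sq")
            if not (0 < self.pi <= 1):
                raise ValueError("pi must lie in (0, 1]")
            if self.n_pathway_effects > self.M:
                raise ValueError(
                    f"round(pi*L)={self.n_pathway_effects} exceeds M={self.M}"
                )
            if self.sigma1_sq <= self.sigma2_sq:
                raise ValueError("enrichment requires sigma1_sq > sigma2_sq")

    @property
    def n_pathway_effects(self) -> int:
        return int(round(self.pi * self.L)) if self.pi is not None else 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "Scenario":
        """Read a scenario from a YAML or JSON config file."""
        with open(path) as fh:
            text = fh.read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class SimulatedStudy:
    """One simulated GWAS: genotypes, effects, pathway and p-values."""

    genotypes: np.ndarray       # N x K over {0,1,2}
    maf: np.ndarray             # length K
    beta: np.ndarray            # length K, M non-zero entries
    pathway_idx: np.ndarray     # L gene indices
    phenotype: np.ndarray       # length N
    pvalues: np.ndarray         # length K

    def gene_scores(self) -> GeneScores:
        return GeneScores.from_pvalues(self.pvalues)

    def to_pvalue_table(self, path=None) -> pd.DataFrame:
        """Export (gene_id, pvalue) TSV consumable by the enrichment tests."""
        df = pd.DataFrame(
            {
                "gene_id": [f"g{j:06d}" for j in range(self.pvalues.size)],
                "pvalue": self.pvalues,
            }
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def sample_maf(K: int, seed=None) -> np.ndarray:
    """Minor allele frequencies: K iid Uniform(0, 0.5) draws."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return _as_rng(seed).uniform(0.0, 0.5, size=K)


def genotype_matrix(N: int, K: int, maf, seed=None) -> np.ndarray:
    """N x K genotype matrix under Hardy-Weinberg equilibrium.

    Column j is iid over {0, 1, 2} with probabilities (1-q)^2, 2q(1-q),
    q^2 for q = maf[j], realised by cutting a single uniform draw at the
    cumulative genotype probabilities.
    """
    q = np.asarray(maf, dtype=float)
    if q.size != K:
        raise ValueError("maf length must equal K")
    if (q <= 0).any() or (q > 0.5).any():
        raise ValueError("maf entries must lie in (0, 0.5]")
    U = _as_rng(seed).random((N, K))
    p0 = (1.0 - q) ** 2
    p01 = p0 + 2.0 * q * (1.0 - q)
    return (U >= p0).astype(np.int8) + (U >= p01).astype(np.int8)


def assign_effects(scenario: Scenario, seed=None):
    """Draw the effect vector and the pathway membership for one scenario.

    Null: M effect SNPs uniformly from the K genes with beta ~
    N(0, sigma2_null); the pathway is an independent uniform draw of L
    genes.  Alternative: the pathway is drawn first; round(pi*L) of its
    genes get beta ~ N(0, sigma1_sq) and the remaining M - round(pi*L)
    effects fall outside the pathway with beta ~ N(0, sigma2_sq).  All
    draws are without replacement.

    Returns ``(beta, pathway_idx)``.
    """
    rng = _as_rng(seed)
    K, L, M = scenario.K, scenario.L, scenario.M
    beta = np.zeros(K)
    if scenario.kind == "null":
        effect_idx = rng.choice(K, size=M, replace=False)
        beta[effect_idx] = rng.normal(0.0, np.sqrt(scenario.sigma2_null), size=M)
        pathway_idx = rng.choice(K, size=L, replace=False)
    else:
        pathway_idx = rng.choice(K, size=L, replace=False)
        m_in = scenario.n_pathway_effects
        in_idx = rng.choice(pathway_idx, size=m_in, replace=False)
        outside = np.setdiff1d(np.arange(K), pathway_idx, assume_unique=False)
        out_idx = rng.choice(outside, size=M - m_in, replace=False)
        beta[in_idx] = rng.normal(0.0, np.sqrt(scenario.sigma1_sq), size=m_in)
        beta[out_idx] = rng.normal(0.0, np.sqrt(scenario.sigma2_sq), size=M - m_in)
    return beta, np.sort(pathway_idx)


def phenotype(genotypes, beta, noise_sd: float = 0.0, seed=None) -> np.ndarray:
    """Additive quantitative phenotype y = G @ beta (+ optional noise).

    With the default ``noise_sd = 0`` the phenotype is exactly the genetic
    value, so the other effect SNPs provide the stochastic background.
    """
    G = np.asarray(genotypes)
    b = np.asarray(beta, dtype=float)
    if G.shape[1] != b.size:
        raise ValueError("beta length must match the number of SNP columns")
    nz = np.flatnonzero(b)
    y = G[:, nz].astype(float) @ b[nz] if nz.size else np.zeros(G.shape[0])
    if noise_sd > 0:
        y = y + _as_rng(seed).normal(0.0, noise_sd, size=G.shape[0])
    return y


def single_snp_pvalues(genotypes, y) -> np.ndarray:
    """Two-sided per-SNP p-values from simple linear regression of y on G.

    The slope t-test with N-2 degrees of freedom, identical to the
    Pearson-correlation t-test.  Monomorphic columns receive p = 1.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    N = G.shape[0]
    if N < 3:
        raise ValueError("need N >= 3 individuals")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ValueError("phenotype is constant")
    Gc = G - G.mean(axis=0)
    ss_g = np.einsum("ij,ij->j", Gc, Gc)
    mono = ss_g <= 0.0
    denom = np.sqrt(np.where(mono, 1.0, ss_g) * ss_y)
    r = np.clip((yc @ Gc) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((N - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=N - 2)
    p[mono] = 1.0
    return np.minimum(p, 1.0)


def simulate_study(scenario: Scenario, seed=None) -> SimulatedStudy:
    """Run the full generator for one scenario: genotypes to p-values.

    Deterministic for fixed (scenario, seed): the same configuration and
    seed always yield a bit-identical study.
    """
    rng = _as_rng(scenario.seed if seed is None else seed)
    maf = sample_maf(scenario.K, rng)
    G = genotype_matrix(scenario.N, scenario.K, maf, rng)
    beta, pathway_idx = assign_effects(scenario, rng)
    y = phenotype(G, beta, scenario.noise_sd, rng)
    p = single_snp_pvalues(G, y)
    return SimulatedStudy(
        genotypes=G, maf=maf, beta=beta, pathway_idx=pathway_idx,
        phenotype=y, pvalues=p,
    )
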