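"""The five competitive pathway tests and their null-calibration schemes.

All tests evaluate the competitive null hypothesis — that the L pathway
genes are no more associated with the phenotype than the K - L genes
outside it — using the scaled ranks u_k = rank(p_k)/K of the study-wide
gene p-values (GSEA additionally uses the -ln p magnitudes):

* Fisher's method (FM):  T = -2 * sum(ln u_k), chi-square with 2L df
  under a continuous-uniform reference, or calibrated by gene-label
  permutation.
* Hypergeometric test:  one-sided over-representation of pathway genes in
  a fixed list of the n most significant genes.
* Tail strength measure (TSM):  mean standardized deviation of the
  ordered u's from their uniform expectations; normal, empirical-uniform
  or permutation null.
* GSEA:  weighted Kolmogorov-Smirnov running-sum enrichment score on the
  genes ranked by -ln p, calibrated by gene-label permutation.
* Rank truncated product (RTP/ARTP):  product of the j smallest scaled
  ranks with the truncation point chosen adaptively to minimise the
  estimated p-value; significance via Ge's single-level permutation
  scheme, against either gene-label permutations or iid Uniform(0,1)
  draws (the "empirical" ARTP_E variant).

Gene-label permutation here means drawing random same-size gene subsets
from the study universe, the standard competitive null device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ranks import GeneScores

__all__ = [
    "NullDistribution",
    "EnrichmentResult",
    "permutation_pvalue",
    "fisher_statistic",
    "fisher_pvalue",
    "hypergeometric_test",
    "significant_gene_list",
    "tsm_statistic",
    "tsm_variance",
    "tsm_pvalue",
    "make_tsm_null",
    "gsea_es",
    "gsea_pvalue",
    "rtp_statistic",
    "artp_pvalue",
    "ArtpNull",
    "results_to_frame",
    "write_results",
]

# default permutation count (B) and empirical-null sample size (R)
DEFAULT_B = 1000
DEFAULT_R = 100_000
MIN_NULL_SIZE = 100


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_rank_rows(rng, B: int, L: int, K: int) -> np.ndarray:
    """B independent draws of L distinct integers from 0..K-1, rows sorted.

    Rejection-samples whole rows on collision, which is fast for L << K;
    falls back to per-row choice without replacement when L is a large
    fraction of K.
    """
    if L > K:
        raise ValueError(f"cannot draw {L} distinct values from {K}")
    if L > K // 2:
        out = np.empty((B, L), dtype=np.int64)
        for b in range(B):
            out[b] = np.sort(rng.choice(K, size=L, replace=False))
        return out
    X = rng.integers(0, K, size=(B, L))
    X.sort(axis=1)
    bad = (np.diff(X, axis=1) == 0).any(axis=1) if L > 1 else np.zeros(B, bool)
    while bad.any():
        n_bad = int(bad.sum())
        Y = rng.integers(0, K, size=(n_bad, L))
        Y.sort(axis=1)
        X[bad] = Y
        bad = (np.diff(X, axis=1) == 0).any(axis=1)
    return X


# ---------------------------------------------------------------------------
# null distributions and permutation p-values
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """A sorted reference sample of a statistic under a stated null scheme.

    ``direction`` records whether large ("large") or small ("small")
    statistic values indicate enrichment.
    """

    values: np.ndarray
    scheme: str  # permutation | empirical_uniform | analytic
    direction: str = "large"

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.direction not in ("large", "small"):
            raise ValueError("direction must be 'large' or 'small'")

    @property
    def size(self) -> int:
        return self.values.size


def permutation_pvalue(observed: float, nulls: NullDistribution) -> float:
    """Permutation p-value with add-one correction: (1 + c) / (1 + B).

    ``c`` counts null values at least as extreme as ``observed`` in the
    null's stated direction, ties included; the result is never 0 and is
    bounded below by 1/(B+1).
    """
    if nulls.size == 0:
        raise ValueError("empty null sample")
    B = nulls.size
    if nulls.direction == "large":
        c = B - np.searchsorted(nulls.values, observed, side="left")
    else:
        c = np.searchsorted(nulls.values, observed, side="right")
    return (1.0 + float(c)) / (1.0 + B)


@dataclass
class EnrichmentResult:
    """Per-pathway outcome of one competitive test."""

    pathway: str
    L: int
    method: str
    statistic: float
    pvalue: float
    extras: dict = field(default_factory=dict)


def _pathway_ranks(scores: GeneScores, pathway) -> np.ndarray:
    """Scaled ranks of the pathway members, accepting ids or positions."""
    pw = np.asarray(list(pathway) if isinstance(pathway, (set, frozenset)) else pathway)
    if pw.dtype.kind in "iu" and scores.gene_ids.dtype.kind in "iu":
        # integer ids over an integer universe: treat as positions when the
        # universe is the default 0..K-1 identity labelling
        if np.array_equal(scores.gene_ids, np.arange(scores.K)):
            return scores.scaled_ranks[pw]
    u = scores.pathway_ranks(pw)
    if u.size == 0:
        raise ValueError("pathway has no genes in the study universe")
    return u


# ---------------------------------------------------------------------------
# Fisher's method
# ---------------------------------------------------------------------------

def fisher_statistic(u_pathway) -> float:
    """FM statistic T = -2 * sum(ln u_k) over the L pathway scaled ranks."""
    u = np.asarray(u_pathway, dtype=float)
    if u.size < 1:
        raise ValueError("need at least one scaled rank")
    if (u <= 0).any() or (u > 1).any():
        raise ValueError("scaled ranks must lie in (0, 1]")
    return float(-2.0 * np.log(u).sum())


def fisher_pvalue(
    scores: GeneScores,
    pathway,
    mode: str = "asymptotic",
    B: int = DEFAULT_B,
    seed=None,
    pathway_name: str = "",
) -> EnrichmentResult:
    """FM competitive test of one pathway.

    ``asymptotic`` refers T to chi-square with 2L degrees of freedom (the
    exact reference for continuous-uniform inputs, a close approximation
    for the discrete scaled ranks); ``permutation`` compares T to B
    gene-label-randomised statistics (L of the K scaled ranks drawn
    without replacement per replicate).
    """
    u = _pathway_ranks(scores, pathway)
    L = u.size
    T = fisher_statistic(u)
    if mode == "asymptotic":
        p = float(stats.chi2.sf(T, df=2 * L))
        p = max(p, np.finfo(float).tiny)
        extras = {}
    elif mode == "permutation":
        if B < MIN_NULL_SIZE:
            raise ValueError(f"permutation mode needs B >= {MIN_NULL_SIZE}")
        rng = _as_rng(seed)
        rows = sample_rank_rows(rng, B, L, scores.K)
        null_T = -2.0 * np.log((rows + 1) / scores.K).sum(axis=1)
        nulls = NullDistribution(null_T, scheme="permutation", direction="large")
        p = permutation_pvalue(T, nulls)
        extras = {"B": B}
    else:
        raise ValueError("mode must be 'asymptotic' or 'permutation'")
    return EnrichmentResult(pathway_name, L, f"fm_{mode}", T, p, extras)


# ---------------------------------------------------------------------------
# Hypergeometric over-representation test
# ---------------------------------------------------------------------------

def hypergeometric_test(K: int, L: int, n: int, k: int) -> float:
    """One-sided upper-tail hypergeometric p-value.

    Probability of observing k or more pathway genes in a random
    significant-gene list of length n, for a pathway of size L within a
    universe of K genes.
    """
    if not (0 <= L <= K and 0 <= n <= K):
        raise ValueError(f"inconsistent counts: K={K}, L={L}, n={n}")
    if not (0 <= k <= min(L, n)):
        raise ValueError(f"k={k} outside [0, min(L={L}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, K, L, n))


def significant_gene_list(scores: GeneScores, alpha=None, top_n=None):
    """Select the significant-gene list for the hypergeometric test.

    Exactly one rule applies: ``alpha`` keeps genes with p < alpha;
    ``top_n`` keeps the n genes with the smallest p-values (ties broken
    by input order, consistent with the rank transform).

    Returns ``(genes, n)`` with n the realised list length.
    """
    if (alpha is None) == (top_n is None):
        raise ValueError("specify exactly one of alpha or top_n")
    if alpha is not None:
        mask = scores.pvalues < alpha
        genes = scores.gene_ids[mask]
    else:
        if not (1 <= top_n <= scores.K):
            raise ValueError(f"top_n={top_n} outside [1, K={scores.K}]")
        mask = scores.scaled_ranks <= top_n / scores.K
        genes = scores.gene_ids[mask]
    return set(np.asarray(genes).tolist()), int(mask.sum())


def hypergeometric_pvalue(
    scores: GeneScores,
    pathway,
    alpha=None,
    top_n: int = 2000,
    pathway_name: str = "",
) -> EnrichmentResult:
    """Hypergeometric test of one pathway against a significant-gene list.

    Default list rule is the 2000 smallest gene p-values, the calibrated
    variant; pass ``alpha`` for a fixed p-value threshold instead.
    """
    u = _pathway_ranks(scores, pathway)
    L = u.size
    if alpha is not None:
        genes, n = significant_gene_list(scores, alpha=alpha)
        # pathway hits: members with p < alpha == scaled rank within list
        k = int(np.count_nonzero(u <= n / scores.K)) if n else 0
    else:
        n = min(top_n, scores.K)
        k = int(np.count_nonzero(u <= n / scores.K))
    p = hypergeometric_test(scores.K, L, n, k)
    return EnrichmentResult(
        pathway_name, L, "hypergeometric", float(k), p, {"n": n, "k": k}
    )


# ---------------------------------------------------------------------------
# Tail strength measure
# ---------------------------------------------------------------------------

def tsm_statistic(u_pathway) -> float:
    """TS = (1/L) * sum_k [1 - u_(k) * (L+1)/k] over the sorted ranks.

    Each term standardises the k-th order statistic by its uniform
    expectation k/(L+1); an excess of small pathway ranks makes TS
    positive.
    """
    u = np.sort(np.asarray(u_pathway, dtype=float))
    L = u.size
    if L < 1:
        raise ValueError("need at least one scaled rank")
    k = np.arange(1, L + 1)
    return float(np.mean(1.0 - u * (L + 1) / k))


def tsm_variance(L: int) -> float:
    """Large-sample variance of TS under the null, approximately 1/L."""
    return 1.0 / L


def make_tsm_null(L: int, R: int = DEFAULT_R, seed=None) -> NullDistribution:
    """Empirical TS null from R draws of L iid Uniform(0,1) p-values."""
    if R < MIN_NULL_SIZE:
        raise ValueError(f"need R >= {MIN_NULL_SIZE}")
    rng = _as_rng(seed)
    k = np.arange(1, L + 1)
    # chunk to bound memory at large R
    vals = np.empty(R)
    step = max(1, int(2e7) // max(L, 1))
    for lo in range(0, R, step):
        hi = min(R, lo + step)
        u = np.sort(rng.random((hi - lo, L)), axis=1)
        vals[lo:hi] = np.mean(1.0 - u * (L + 1) / k, axis=1)
    return NullDistribution(vals, scheme="empirical_uniform", direction="large")


def tsm_pvalue(
    scores: GeneScores,
    pathway,
    mode: str = "normal",
    R_or_B: int = DEFAULT_R,
    seed=None,
    null: NullDistribution | None = None,
    pathway_name: str = "",
) -> EnrichmentResult:
    """TSM competitive test of one pathway.

    Modes: ``normal`` (one-sided upper tail of N(0, v(L)), v(L) ~ 1/L —
    known to be conservative for the pathway sizes met in practice),
    ``empirical`` (TS null from iid Uniform(0,1) draws; a precomputed
    ``null`` may be supplied), ``permutation`` (gene-label randomisation).
    """
    u = _pathway_ranks(scores, pathway)
    L = u.size
    TS = tsm_statistic(u)
    extras = {}
    if mode == "normal":
        p = float(stats.norm.sf(TS, scale=np.sqrt(tsm_variance(L))))
    elif mode == "empirical":
        if null is None:
            null = make_tsm_null(L, R_or_B, seed)
        elif null.size < MIN_NULL_SIZE:
            raise ValueError(f"empirical null needs >= {MIN_NULL_SIZE} values")
        p = permutation_pvalue(TS, null)
        extras = {"R": null.size}
    elif mode == "permutation":
        if R_or_B < MIN_NULL_SIZE:
            raise ValueError(f"permutation mode needs B >= {MIN_NULL_SIZE}")
        rng = _as_rng(seed)
        rows = sample_rank_rows(rng, R_or_B, L, scores.K)
        k = np.arange(1, L + 1)
        null_ts = np.mean(1.0 - ((rows + 1) / scores.K) * (L + 1) / k, axis=1)
        p = permutation_pvalue(
            TS, NullDistribution(null_ts, scheme="permutation", direction="large")
        )
        extras = {"B": R_or_B}
    else:
        raise ValueError("mode must be 'normal', 'empirical' or 'permutation'")
    return EnrichmentResult(pathway_name, L, f"tsm_{mode}", TS, p, extras)


# ---------------------------------------------------------------------------
# GSEA (weighted Kolmogorov-Smirnov running sum)
# ---------------------------------------------------------------------------

def _gene_stats(scores: GeneScores) -> np.ndarray:
    """Gene statistics t_k = -ln p_k; p clamped away from 0 for the log."""
    p = np.maximum(scores.pvalues, np.finfo(float).tiny)
    return -np.log(p)


def _es_from_positions(pos_sorted: np.ndarray, t_desc: np.ndarray, K: int) -> np.ndarray:
    """Enrichment scores from pathway positions in the ranked gene list.

    ``pos_sorted``: (..., L) ascending 0-based positions of the pathway
    genes within the list ranked by decreasing statistic; ``t_desc``: the
    statistics in that ranked order.  Because all weights |t|^w are
    non-negative, the running-sum maximum over positions 1..K is attained
    at a hit, so only hit positions need evaluating.
    """
    pos = np.atleast_2d(pos_sorted)
    L = pos.shape[-1]
    w = t_desc[pos]
    NR = w.sum(axis=1, keepdims=True)
    hit = np.where(NR > 0, np.cumsum(w, axis=1) / np.where(NR > 0, NR, 1.0),
                   np.cumsum(np.ones_like(w), axis=1) / L)
    miss = (pos - np.arange(L)) / (K - L)
    es = (hit - miss).max(axis=1)
    return es if pos_sorted.ndim > 1 else float(es[0])


def gsea_es(scores: GeneScores, pathway, weight_exponent: float = 1.0):
    """GSEA enrichment score of one pathway.

    Genes are ranked by decreasing t_k = -ln p_k; the running sum gains
    |t_j|^weight_exponent / N_R at pathway hits (N_R the sum of hit
    weights) and loses 1/(K - N_H) at misses; ES is the maximum of the
    running sum — a one-sided, enrichment-at-top score.  Ties in t are
    ordered by input index.  Returns ``(ES, hit_positions)`` with 0-based
    positions of the pathway genes in the ranked list.
    """
    u = _pathway_ranks(scores, pathway)
    L = u.size
    K = scores.K
    if L >= K:
        raise ValueError("pathway must leave at least one non-member in universe")
    t = _gene_stats(scores) ** weight_exponent
    # ranking by decreasing -ln p == increasing p == the scaled-rank order
    order = np.argsort(scores.scaled_ranks)
    t_desc = t[order]
    # pathway positions in the ranked list are (scaled rank * K) - 1
    pos = np.sort((u * K).round().astype(np.int64) - 1)
    es = _es_from_positions(pos, t_desc, K)
    return es, pos


def gsea_pvalue(
    scores: GeneScores,
    pathway,
    B: int = DEFAULT_B,
    seed=None,
    weight_exponent: float = 1.0,
    pathway_name: str = "",
) -> EnrichmentResult:
    """Gene-label permutation p-value of the GSEA enrichment score.

    The null ES sample comes from B random same-size gene subsets of the
    universe, evaluated against the same ranked statistics.
    """
    if B < MIN_NULL_SIZE:
        raise ValueError(f"need B >= {MIN_NULL_SIZE}")
    es, pos = gsea_es(scores, pathway, weight_exponent)
    L = pos.size
    rng = _as_rng(seed)
    t_desc = (_gene_stats(scores) ** weight_exponent)[np.argsort(scores.scaled_ranks)]
    rows = sample_rank_rows(rng, B, L, scores.K)
    null_es = _es_from_positions(rows, t_desc, scores.K)
    p = permutation_pvalue(
        es, NullDistribution(null_es, scheme="permutation", direction="large")
    )
    return EnrichmentResult(
        pathway_name, L, "gsea", float(es), p,
        {"B": B, "hit_positions": pos.tolist()},
    )


# ---------------------------------------------------------------------------
# Rank truncated product / ARTP
# ---------------------------------------------------------------------------

def rtp_statistic(u_pathway_sorted, j: int) -> float:
    """RTP statistic W(j): product of the j smallest scaled ranks.

    Smaller values indicate stronger enrichment.  W(L) is a monotone
    transform of the FM statistic: -2 ln W(L) = T.
    """
    u = np.asarray(u_pathway_sorted, dtype=float)
    if not (1 <= j <= u.size):
        raise ValueError(f"truncation point j={j} outside [1, {u.size}]")
    if (np.diff(u) < 0).any():
        raise ValueError("input must be sorted ascending")
    return float(np.prod(u[:j]))


def _ge_min_pvalues(log_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ge's single-level reduction: pooled per-truncation p-hats and minima.

    ``log_w``: (B+1, J) log RTP statistics, row 0 the observed replicate.
    For each column j, p-hat of row b is the pooled fraction of rows
    (self included) with W(j) <= W_b(j); returns (min-p statistic per row,
    p-hat row of the observed replicate).
    """
    n, J = log_w.shape
    phat = np.empty_like(log_w)
    for j in range(J):
        col = log_w[:, j]
        s = np.sort(col)
        phat[:, j] = np.searchsorted(s, col, side="right") / n
    return phat.min(axis=1), phat[0]


def artp_pvalue(
    scores: GeneScores,
    pathway,
    B: int = DEFAULT_B,
    null_source: str = "permutation",
    seed=None,
    truncation_points=None,
    pathway_name: str = "",
) -> EnrichmentResult:
    """Adaptive rank truncated product p-value via Ge's single-level scheme.

    B null replicate rank-vectors of length L are drawn — by gene-label
    permutation (L of the K scaled ranks without replacement) or, for the
    ARTP_E variant, as L iid Uniform(0,1) values — and W(j) is evaluated
    for every replicate (observed included) at every truncation point
    j = 1..L.  Each (replicate, j) pair receives a pooled p-hat over all
    B+1 replicates; a replicate's ARTP statistic is its minimum p-hat over
    j, and the final p-value is the pooled proportion of replicates whose
    ARTP statistic is at most the observed one.  ``extras`` reports the
    selected truncation point j_hat (smallest j on ties) and the observed
    p-hat vector.
    """
    if B < MIN_NULL_SIZE:
        raise ValueError(f"need B >= {MIN_NULL_SIZE}")
    u = np.sort(_pathway_ranks(scores, pathway))
    L = u.size
    rng = _as_rng(seed)
    if null_source == "permutation":
        if L > scores.K:
            raise ValueError("pathway larger than universe")
        rows = sample_rank_rows(rng, B, L, scores.K)
        null_u = (rows + 1) / scores.K
    elif null_source == "empirical_uniform":
        null_u = np.sort(rng.random((B, L)), axis=1)
    else:
        raise ValueError("null_source must be 'permutation' or 'empirical_uniform'")
    jpts = np.arange(1, L + 1) if truncation_points is None else np.asarray(
        sorted(truncation_points), dtype=int
    )
    if jpts.size == 0 or jpts[0] < 1 or jpts[-1] > L:
        raise ValueError(f"truncation points must lie in [1, {L}]")
    all_u = np.vstack([u[None, :], null_u])
    log_w = np.cumsum(np.log(np.maximum(all_u, np.finfo(float).tiny)), axis=1)
    log_w = log_w[:, jpts - 1]
    min_stat, phat_obs = _ge_min_pvalues(log_w)
    p = float(np.count_nonzero(min_stat <= min_stat[0])) / (B + 1)
    j_hat = int(jpts[int(np.argmin(phat_obs))])
    return EnrichmentResult(
        pathway_name, L,
        "artp" if null_source == "permutation" else "artp_e",
        float(min_stat[0]), p,
        {"j_hat": j_hat, "phat": phat_obs.tolist(), "B": B},
    )


class ArtpNull:
    """Precomputed ARTP null for repeated testing at fixed (K or U(0,1), L, B).

    Builds the B null replicate rank-vectors once and freezes, per
    truncation point, the sorted null log-W values together with the null
    replicates' own min-p statistics.  Observed pathways are then scored
    by searchsorted lookups.  Relative to :func:`artp_pvalue` the null
    replicates' p-hats omit the observed replicate's contribution, a
    deviation of at most 1/(B+1) per p-hat; the observed p-hat and the
    final pooled p-value keep the add-one convention.
    """

    def __init__(self, null_u: np.ndarray):
        null_u = np.asarray(null_u, dtype=float)
        self.B, self.L = null_u.shape
        log_w = np.cumsum(np.log(np.maximum(null_u, np.finfo(float).tiny)), axis=1)
        self.log_w_sorted = np.sort(log_w, axis=0)  # per column j
        phat = np.empty_like(log_w)
        for j in range(self.L):
            phat[:, j] = (
                np.searchsorted(self.log_w_sorted[:, j], log_w[:, j], side="right")
                / (self.B + 1)
            )
        self.null_min_sorted = np.sort(phat.min(axis=1))

    @classmethod
    def from_permutation(cls, K: int, L: int, B: int = DEFAULT_B, seed=None):
        """Gene-label permutation null: L of the K scaled ranks per replicate."""
        rows = sample_rank_rows(_as_rng(seed), B, L, K)
        return cls((rows + 1) / K)

    @classmethod
    def from_uniform(cls, L: int, B: int = DEFAULT_B, seed=None):
        """Empirical-uniform (ARTP_E) null: L iid Uniform(0,1) per replicate."""
        return cls(np.sort(_as_rng(seed).random((B, L)), axis=1))

    def pvalue(self, u_pathway) -> tuple[float, int]:
        """ARTP p-value and selected truncation point for one pathway."""
        u = np.sort(np.asarray(u_pathway, dtype=float))
        if u.size != self.L:
            raise ValueError(f"pathway size {u.size} != null size {self.L}")
        lw = np.cumsum(np.log(np.maximum(u, np.finfo(float).tiny)))
        cnt = np.array([
            np.searchsorted(self.log_w_sorted[:, j], lw[j], side="right")
            for j in range(self.L)
        ])
        phat_obs = (1.0 + cnt) / (self.B + 1)
        min_obs = float(phat_obs.min())
        j_hat = int(np.argmin(phat_obs)) + 1
        c = np.searchsorted(self.null_min_sorted, min_obs, side="right")
        return (1.0 + float(c)) / (self.B + 1), j_hat


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def results_to_frame(results) -> pd.DataFrame:
    """Tabulate EnrichmentResults: one row per (pathway, method)."""
    return pd.DataFrame(
        {
            "pathway": r.pathway,
            "method": r.method,
            "L": r.L,
            "statistic": r.statistic,
            "pvalue": r.pvalue,
            "extras": json.dumps(r.extras),
        }
        for r in results
    )


def write_results(results, path) -> None:
    """Write EnrichmentResults as a TSV (extras JSON-encoded)."""
    results_to_frame(results).to_csv(path, sep="\t", index=False)
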