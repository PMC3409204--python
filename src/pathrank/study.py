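"""Scenario grids, replicate loops and type-I-error / power estimation.

Each replicate simulates a full GWAS, converts the per-gene p-values to
scaled ranks and applies the configured competitive tests to the
scenario's pathway; the rejection rate at the nominal level estimates the
type-I error (null scenarios) or the power (alternative scenarios).

Method labels
-------------
``fm``          Fisher's method, asymptotic chi-square(2L) reference
``fm_perm``     Fisher's method, gene-label permutation
``hyper``       hypergeometric, significant list = 2000 smallest p-values
``hyper_thresh`` hypergeometric, significant list = {p < alpha_t}
``tsm_normal``  tail strength, N(0, 1/L) approximation
``tsm_e``       tail strength, empirical Uniform(0,1) null
``gsea``        GSEA, gene-label permutation
``artp``        ARTP, gene-label permutation (Ge single-level)
``artp_e``      ARTP, empirical Uniform(0,1) null

The study driver caches every null object that depends only on the
pathway size: the TSM empirical null, the ARTP empirical-uniform null
and — because ordinal ranking makes the scaled-rank universe the fixed
grid {1/K, ..., 1} — the ARTP gene-label permutation null as well.  This
is what makes thousand-replicate grids desk-scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import enrich
from .enrich import ArtpNull, NullDistribution, make_tsm_null
from .simulate import Scenario, simulate_study

__all__ = [
    "StudyResult",
    "METHOD_LABELS",
    "null_grid",
    "alternative_grid",
    "run_scenario",
    "run_grid",
    "summarize",
    "results_to_frame",
    "read_results",
]

METHOD_LABELS = (
    "fm", "fm_perm", "hyper", "hyper_thresh",
    "tsm_normal", "tsm_e", "gsea", "artp", "artp_e",
)

#: the five variants carried into the power comparison
POWER_METHODS = ("fm", "hyper", "tsm_e", "gsea", "artp_e")

DEFAULT_ALPHA_T = 0.001  # threshold for the hyper_thresh variant


@dataclass(frozen=True)
class StudyResult:
    """Rejection-rate estimate for one (scenario, method) cell."""

    scenario: Scenario
    method: str
    n_reps: int
    rejections: int
    alpha: float

    @property
    def rate(self) -> float:
        return self.rejections / self.n_reps

    @property
    def se(self) -> float:
        """Binomial standard error sqrt(rate * (1 - rate) / n_reps)."""
        return float(np.sqrt(self.rate * (1.0 - self.rate) / self.n_reps))


def null_grid(N: int = 100, K: int = 20000) -> list[Scenario]:
    """The 27 null scenarios: L x M x effect variance, full factorial.

    L in {20, 60, 100}, M in {50, 100, 200}, sigma^2 in {1, 2, 4}; the
    ordering is deterministic (itertools.product of the sorted axes).
    """
    return [
        Scenario(L=L, M=M, kind="null", sigma2_null=s2, N=N, K=K)
        for L, M, s2 in itertools.product((20, 60, 100), (50, 100, 200), (1.0, 2.0, 4.0))
    ]


def alternative_grid(
    N: int = 100,
    K: int = 20000,
    pathway_sizes=(20, 60, 100),
    effect_totals=(50, 100, 200),
    proportions=(0.4, 0.6, 1.0),
    variance_pairs=((4.0, 2.0), (4.0, 1.0), (2.0, 1.0)),
) -> list[Scenario]:
    """Alternative (enrichment) scenarios over the published axes.

    Combinations with round(pi * L) > M are infeasible and skipped.
    """
    out = []
    for L, M, pi, (s1, s2) in itertools.product(
        pathway_sizes, effect_totals, proportions, variance_pairs
    ):
        if round(pi * L) > M:
            continue
        out.append(
            Scenario(L=L, M=M, kind="alternative", pi=pi,
                     sigma1_sq=s1, sigma2_sq=s2, N=N, K=K)
        )
    return out


class NullCache:
    """Per-(K, L, B/R) cache of the reusable null objects."""

    def __init__(self, B: int = enrich.DEFAULT_B, R: int = enrich.DEFAULT_R, seed=0):
        self.B, self.R = B, R
        self._seed = seed
        self._store: dict = {}

    def _get(self, key, builder):
        if key not in self._store:
            self._store[key] = builder()
        return self._store[key]

    def tsm_null(self, L: int) -> NullDistribution:
        return self._get(
            ("tsm", L),
            lambda: make_tsm_null(L, self.R, np.random.default_rng([self._seed, 1, L])),
        )

    def artp_perm(self, K: int, L: int) -> ArtpNull:
        return self._get(
            ("artp", K, L),
            lambda: ArtpNull.from_permutation(
                K, L, self.B, np.random.default_rng([self._seed, 2, L])
            ),
        )

    def artp_uniform(self, L: int) -> ArtpNull:
        return self._get(
            ("artp_e", L),
            lambda: ArtpNull.from_uniform(
                L, self.B, np.random.default_rng([self._seed, 3, L])
            ),
        )


def _replicate_pvalues(
    ranks: np.ndarray,
    pvalues: np.ndarray,
    pathway_idx: np.ndarray,
    methods,
    cache: NullCache,
    rng: np.random.Generator,
    alpha_t: float,
) -> dict:
    """Pathway p-value per method for one simulated replicate.

    Operates on raw arrays for speed; semantically identical to calling
    the per-method functions in :mod:`pathrank.enrich` (tests assert so).
    """
    K = ranks.size
    u = np.sort(ranks[pathway_idx])
    L = u.size
    out = {}
    for m in methods:
        if m == "fm":
            T = -2.0 * np.log(u).sum()
            out[m] = float(stats.chi2.sf(T, df=2 * L))
        elif m == "fm_perm":
            rows = enrich.sample_rank_rows(rng, cache.B, L, K)
            null_T = -2.0 * np.log((rows + 1) / K).sum(axis=1)
            T = -2.0 * np.log(u).sum()
            out[m] = (1.0 + np.count_nonzero(null_T >= T)) / (1.0 + cache.B)
        elif m == "hyper":
            n = min(2000, K)
            k = int(np.count_nonzero(u <= n / K))
            out[m] = float(stats.hypergeom.sf(k - 1, K, L, n))
        elif m == "hyper_thresh":
            n = int(np.count_nonzero(pvalues < alpha_t))
            k = int(np.count_nonzero(u <= n / K)) if n else 0
            out[m] = float(stats.hypergeom.sf(k - 1, K, L, n))
        elif m == "tsm_normal":
            TS = np.mean(1.0 - u * (L + 1) / np.arange(1, L + 1))
            out[m] = float(stats.norm.sf(TS, scale=np.sqrt(1.0 / L)))
        elif m == "tsm_e":
            TS = np.mean(1.0 - u * (L + 1) / np.arange(1, L + 1))
            out[m] = enrich.permutation_pvalue(TS, cache.tsm_null(L))
        elif m == "gsea":
            t_desc = -np.log(np.maximum(np.sort(pvalues), np.finfo(float).tiny))
            pos = (u * K).round().astype(np.int64) - 1
            es = enrich._es_from_positions(pos, t_desc, K)
            rows = enrich.sample_rank_rows(rng, cache.B, L, K)
            null_es = enrich._es_from_positions(rows, t_desc, K)
            out[m] = (1.0 + np.count_nonzero(null_es >= es)) / (1.0 + cache.B)
        elif m == "artp":
            out[m] = cache.artp_perm(K, L).pvalue(u)[0]
        elif m == "artp_e":
            out[m] = cache.artp_uniform(L).pvalue(u)[0]
        else:
            raise ValueError(
                f"unknown method {m!r}; valid labels: {', '.join(METHOD_LABELS)}"
            )
    return out


def run_scenario(
    scenario: Scenario,
    methods,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scenario_index: int = 0,
    cache: NullCache | None = None,
    alpha_t: float = DEFAULT_ALPHA_T,
) -> list[StudyResult]:
    """Estimate the rejection rate of each method under one scenario.

    Per-replicate RNG streams derive from (seed, scenario_index,
    replicate index), so any scenario of a grid can be reproduced in
    isolation.  ``cache`` may be shared across scenarios to reuse
    size-dependent null distributions.
    """
    if n_reps < 50:
        raise ValueError("need n_reps >= 50")
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be nonempty")
    for m in methods:
        if m not in METHOD_LABELS:
            raise ValueError(
                f"unknown method {m!r}; valid labels: {', '.join(METHOD_LABELS)}"
            )
    if cache is None:
        cache = NullCache(seed=seed)
    # ranking by p is identical for ordinal ties; scaled ranks computed inline
    rejections = {m: 0 for m in methods}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, scenario_index, rep])
        study = simulate_study(scenario, rng)
        ranks = stats.rankdata(study.pvalues, method="ordinal") / scenario.K
        pvals = _replicate_pvalues(
            ranks, study.pvalues, study.pathway_idx, methods, cache, rng, alpha_t
        )
        for m, p in pvals.items():
            if p <= alpha:
                rejections[m] += 1
    return [
        StudyResult(scenario, m, n_reps, rejections[m], alpha) for m in methods
    ]


def run_grid(
    scenarios,
    methods,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    cache: NullCache | None = None,
) -> list[StudyResult]:
    """Run every scenario of a grid with a shared null cache."""
    if cache is None:
        cache = NullCache(seed=seed)
    out = []
    for i, sc in enumerate(scenarios):
        out.extend(
            run_scenario(sc, methods, n_reps, alpha, seed, scenario_index=i, cache=cache)
        )
    return out


_SCENARIO_COLS = (
    "kind", "N", "K", "L", "M", "sigma2_null", "pi", "sigma1_sq", "sigma2_sq",
)


def results_to_frame(results) -> pd.DataFrame:
    """Flatten StudyResults to one row per (scenario, method)."""
    rows = []
    for r in results:
        d = {c: getattr(r.scenario, c) for c in _SCENARIO_COLS}
        d.update(
            method=r.method, n_reps=r.n_reps, rejections=r.rejections,
            alpha=r.alpha, rate=r.rate, se=r.se,
        )
        rows.append(d)
    return pd.DataFrame(rows)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def summarize(results, group_by=("method",)) -> pd.DataFrame:
    """Unweighted mean rejection rate within each (method x group) cell.

    ``results`` is a list of StudyResults or an already-flattened frame.
    Every scenario contributes equally to its cell; the cell count is
    reported alongside the mean.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise ValueError("no results to summarize")
    keys = ["method"] + [g for g in group_by if g != "method"]
    out = (
        df.groupby(keys, dropna=False)["rate"]
        .agg(mean_rate="mean", n_cells="count")
        .reset_index()
    )
    return out
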