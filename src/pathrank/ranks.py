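"""Study-wide gene scores and the scaled-rank gene statistic.

A competitive (enrichment) test asks whether the genes of a pathway are
more associated with the phenotype than the genes outside it.  Any
association test that combines per-gene statistics can be turned into a
competitive test by feeding it *scaled ranks*: gene k with the r-th
smallest p-value among the K study genes receives the statistic

    u_k = r / K,

which under the competitive null (pathway membership independent of
association signal) follows a discrete uniform distribution on
{1/K, 2/K, ..., 1} regardless of how the per-gene p-values were obtained.
This module holds the study-wide score container, the rank transform and
the gene-set machinery shared by every downstream test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pathrank")

__all__ = [
    "GeneScores",
    "GeneSetCollection",
    "scaled_ranks",
    "restrict_to_universe",
    "read_gene_pvalues",
    "read_gmt",
    "write_gene_pvalues",
]

#: smallest pathway size kept after intersecting with the study universe
DEFAULT_MIN_SET_SIZE = 2


def scaled_ranks(pvalues) -> np.ndarray:
    """Scaled ranks u_k = rank(p_k)/K of a vector of p-values.

    Ranks run from the smallest p-value (rank 1) to the largest (rank K);
    ties are broken by input order (ordinal ranking), so the result is
    always an exact permutation of {1/K, 2/K, ..., 1}.

    Parameters
    ----------
    pvalues : array-like of float
        Per-gene association p-values, length K >= 2, entries in [0, 1].

    Returns
    -------
    numpy.ndarray
        Scaled ranks aligned with the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-d vector of at least 2 p-values")
    bad = ~np.isfinite(p) | (p < 0.0) | (p > 1.0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid p-value at index {idx}: {p[idx]!r} (must be finite and in [0, 1])"
        )
    ranks = stats.rankdata(p, method="ordinal")
    return ranks / p.size


@dataclass(frozen=True)
class GeneScores:
    """Per-gene p-values and scaled ranks for a whole study.

    The full study acts as the competitive background: every test in
    :mod:`pathrank.enrich` evaluates a pathway against these K genes.
    """

    gene_ids: np.ndarray
    pvalues: np.ndarray
    scaled_ranks: np.ndarray

    @property
    def K(self) -> int:
        """Total number of genes in the study."""
        return self.pvalues.size

    @classmethod
    def from_pvalues(cls, pvalues, gene_ids=None) -> "GeneScores":
        """Build scores from raw p-values, computing the scaled ranks.

        ``gene_ids`` defaults to the integer positions 0..K-1.
        """
        u = scaled_ranks(pvalues)
        p = np.asarray(pvalues, dtype=float)
        if gene_ids is None:
            ids = np.arange(p.size)
        else:
            ids = np.asarray(gene_ids)
            if ids.size != p.size:
                raise ValueError("gene_ids and pvalues lengths differ")
            if pd.unique(ids).size != ids.size:
                raise ValueError("gene_ids contains duplicates")
        return cls(gene_ids=ids, pvalues=p, scaled_ranks=u)

    def positions(self, genes) -> np.ndarray:
        """Integer positions of ``genes`` within the study universe.

        Genes absent from the universe are silently dropped; ids are
        matched verbatim (no aliasing).
        """
        index = pd.Index(self.gene_ids)
        pos = index.get_indexer(pd.Index(list(genes)))
        return np.sort(pos[pos >= 0])

    def pathway_ranks(self, genes) -> np.ndarray:
        """Scaled ranks of the universe genes belonging to ``genes``."""
        return self.scaled_ranks[self.positions(genes)]


@dataclass
class GeneSetCollection:
    """Named pathways as plain gene-id sets (GMT-backed).

    ``sets`` maps pathway name to a frozenset of gene ids; ``source`` is
    free-text provenance such as the database name.  Membership is only
    meaningful relative to a study universe, which is intersected at test
    time via :func:`restrict_to_universe`.
    """

    sets: dict
    source: str = ""
    dropped_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, source=None) -> GeneSetCollection:
    """Read gene sets from a GMT file (MSigDB dialect).

    One set per tab-separated line: name, description, then member gene
    ids.  Duplicate ids within a line are de-duplicated; duplicate set
    names raise.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, genes = fields[0], fields[2:]
            genes = frozenset(g for g in genes if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=source or str(path))


def restrict_to_universe(
    collection: GeneSetCollection,
    scores: GeneScores,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> GeneSetCollection:
    """Intersect every set with the study universe.

    Genes absent from ``scores.gene_ids`` are dropped (counts recorded in
    ``dropped_genes``); sets falling below ``min_size`` members are removed
    entirely, with a warning.
    """
    universe = set(np.asarray(scores.gene_ids).tolist())
    kept, dropped_genes = {}, {}
    for name, genes in collection.sets.items():
        inside = genes & universe
        n_dropped = len(genes) - len(inside)
        if n_dropped:
            dropped_genes[name] = n_dropped
        if len(inside) < min_size:
            logger.warning(
                "dropping gene set %r: %d of %d members in universe (< min_size=%d)",
                name, len(inside), len(genes), min_size,
            )
            continue
        kept[name] = frozenset(inside)
    if dropped_genes:
        logger.info(
            "restricted %d sets to universe of %d genes; dropped %d gene memberships",
            len(collection), len(universe), sum(dropped_genes.values()),
        )
    return GeneSetCollection(
        sets=kept, source=collection.source, dropped_genes=dropped_genes
    )


def read_gene_pvalues(path) -> GeneScores:
    """Read a per-gene p-value table (TSV with columns gene_id, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return GeneScores.from_pvalues(df["pvalue"].to_numpy(), df["gene_id"].to_numpy())


def write_gene_pvalues(scores: GeneScores, path) -> None:
    """Write a GeneScores universe as a two-column TSV (gene_id, pvalue)."""
    pd.DataFrame(
        {"gene_id": scores.gene_ids, "pvalue": scores.pvalues}
    ).to_csv(path, sep="\t", index=False)
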