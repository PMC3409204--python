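"""Front-end for real (or realistically simulated) GWAS inputs.

Takes per-SNP association p-values to pathway-level results in four
steps: map each SNP to the closest gene (by distance to the gene's
coding start, within a window), summarise each gene by the minimum
p-value of its SNPs, remove the resulting gene-size bias with
phenotype-permutation adjustment, and run the competitive tests over a
gene-set database.

The permutation adjustment exists because a gene with many SNPs is more
likely to receive a small minimum p-value by chance alone; calibrating
each gene's observed minimum against its own permutation distribution
makes the adjusted p-values comparable across genes:

    adjusted p_g = (1 + #{b : min-p_g^(b) <= min-p_g}) / (1 + B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enrich
from .ranks import GeneScores, GeneSetCollection, restrict_to_universe

__all__ = [
    "SnpGeneMap",
    "map_snps_to_genes",
    "gene_min_p",
    "adjusted_gene_p",
    "run_database",
]


@dataclass
class SnpGeneMap:
    """SNP-to-gene assignments within a distance window."""

    assignments: dict          # snp_id -> gene_id
    window_bp: int
    unmapped: int = 0


def _coding_start(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware coding start: `start` on '+', `end` on '-' strands.

    Falls back to `start` when no strand column is present.
    """
    if "strand" in genes.columns:
        return genes["end"].where(genes["strand"] == "-", genes["start"])
    return genes["start"]


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 10_000,
    bed_input: bool = False,
) -> SnpGeneMap:
    """Assign each SNP to the closest gene coding start within ``window_bp``.

    ``snps`` needs columns (snp_id, chrom, pos) with 1-based positions;
    ``genes`` needs (gene_id, chrom, start, end[, strand]).  With
    ``bed_input`` the gene table is interpreted as BED (0-based
    half-open) and converted on read.  Distance ties go to the
    lexicographically smaller gene id; SNPs on chromosomes absent from
    the gene table, or with no coding start in range, stay unmapped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    genes = genes.copy()
    if bed_input:
        genes["start"] = genes["start"] + 1  # BED 0-based half-open -> 1-based
    assignments: dict = {}
    unmapped = 0
    gene_chroms = set(genes["chrom"])
    for chrom, snp_chunk in snps.groupby("chrom", sort=False):
        if chrom not in gene_chroms:
            unmapped += len(snp_chunk)
            continue
        sub = genes[genes["chrom"] == chrom]
        # sort by (coding start, gene_id): at equal starts the first entry
        # is the lexicographically smallest id
        cs = _coding_start(sub).to_numpy()
        order = np.lexsort((sub["gene_id"].to_numpy(), cs))
        starts = cs[order]
        ids = sub["gene_id"].to_numpy()[order]
        pos = snp_chunk["pos"].to_numpy()
        right = np.searchsorted(starts, pos, side="left")
        left = right - 1
        for sid, p, lo, hi in zip(snp_chunk["snp_id"], pos, left, right):
            best_id, best_d = None, window_bp + 1
            for i in (lo, hi):
                if 0 <= i < starts.size:
                    d = abs(int(starts[i]) - int(p))
                    # walk over genes sharing this start (sorted ids: first wins)
                    if d < best_d or (d == best_d and best_id is not None
                                      and str(ids[i]) < str(best_id)):
                        best_id, best_d = ids[i], d
            if best_id is None or best_d > window_bp:
                unmapped += 1
            else:
                assignments[sid] = best_id
    return SnpGeneMap(assignments=assignments, window_bp=window_bp, unmapped=unmapped)


def gene_min_p(snp_pvalues, mapping: SnpGeneMap) -> pd.Series:
    """Per-gene minimum p-value over the SNPs mapped to each gene.

    ``snp_pvalues`` maps snp_id -> p-value (dict or Series).  Genes with
    no mapped SNP are absent from the output.
    """
    sp = pd.Series(snp_pvalues)
    mapped = {s: g for s, g in mapping.assignments.items() if s in sp.index}
    missing = set(mapping.assignments) - set(mapped)
    if missing:
        raise ValueError(f"{len(missing)} mapped SNPs lack p-values, e.g. {sorted(missing)[:3]}")
    if not mapped:
        return pd.Series(dtype=float)
    df = pd.DataFrame({
        "gene": [mapped[s] for s in mapped],
        "p": sp.loc[list(mapped)].to_numpy(),
    })
    return df.groupby("gene")["p"].min()


def adjusted_gene_p(observed: pd.Series, permuted: pd.DataFrame) -> pd.Series:
    """Phenotype-permutation adjustment of per-gene minimum p-values.

    ``permuted`` holds one row per phenotype permutation (B >= 100) and
    one column per gene, aligned with ``observed``; the adjusted value of
    gene g is (1 + #{b : permuted_g^(b) <= observed_g}) / (1 + B), which
    is calibrated per gene and therefore free of the gene-size bias of
    the raw minimum p-value.
    """
    B = len(permuted)
    if B < 100:
        raise ValueError("need >= 100 phenotype permutations")
    if set(permuted.columns) != set(observed.index):
        raise ValueError("permuted columns do not match the observed genes")
    perm = permuted[observed.index].to_numpy()
    counts = (perm <= observed.to_numpy()[None, :]).sum(axis=0)
    return pd.Series((1.0 + counts) / (1.0 + B), index=observed.index)


def run_database(
    gene_pvalues,
    collection: GeneSetCollection,
    methods=("fm",),
    B: int = enrich.DEFAULT_B,
    R: int = enrich.DEFAULT_R,
    alpha_t: float | None = None,
    top_n: int = 2000,
    min_size: int = 2,
    seed: int = 0,
    out_path=None,
) -> pd.DataFrame:
    """Test every pathway of one database with the configured methods.

    ``gene_pvalues`` is a GeneScores or a mapping gene_id -> p-value; the
    scaled ranks are computed once over that universe.  Returns the
    results table (one row per pathway x method) and logs the count of
    pathways at nominal p < 0.05 per method; the table is also written to
    ``out_path`` when given.  Method labels follow :mod:`pathrank.study`.
    """
    if isinstance(gene_pvalues, GeneScores):
        scores = gene_pvalues
    else:
        gp = pd.Series(gene_pvalues)
        scores = GeneScores.from_pvalues(gp.to_numpy(), gp.index.to_numpy())
    restricted = restrict_to_universe(collection, scores, min_size=min_size)
    if len(restricted) == 0:
        raise ValueError("no gene sets remain after universe restriction")
    if not methods:
        raise ValueError("need at least one method")

    cache: dict = {}

    def _tsm_null(L):
        if ("tsm", L) not in cache:
            cache[("tsm", L)] = enrich.make_tsm_null(
                L, R, np.random.default_rng([seed, 1, L]))
        return cache[("tsm", L)]

    def _artp_null(L, source):
        key = (source, L)
        if key not in cache:
            rng = np.random.default_rng([seed, 2, L])
            cache[key] = (
                enrich.ArtpNull.from_permutation(scores.K, L, B, rng)
                if source == "artp" else enrich.ArtpNull.from_uniform(L, B, rng)
            )
        return cache[key]

    results = []
    for i, (name, genes) in enumerate(sorted(restricted, key=lambda kv: kv[0])):
        u = scores.pathway_ranks(genes)
        L = u.size
        rng = np.random.default_rng([seed, 3, i])
        for m in methods:
            if m == "fm":
                r = enrich.fisher_pvalue(scores, genes, "asymptotic", pathway_name=name)
            elif m == "fm_perm":
                r = enrich.fisher_pvalue(scores, genes, "permutation", B, rng, name)
            elif m == "hyper":
                r = enrich.hypergeometric_pvalue(scores, genes, top_n=top_n,
                                                pathway_name=name)
            elif m == "hyper_thresh":
                r = enrich.hypergeometric_pvalue(
                    scores, genes, alpha=alpha_t or 0.001, pathway_name=name)
            elif m == "tsm_normal":
                r = enrich.tsm_pvalue(scores, genes, "normal", pathway_name=name)
            elif m == "tsm_e":
                r = enrich.tsm_pvalue(scores, genes, "empirical",
                                      null=_tsm_null(L), pathway_name=name)
            elif m == "gsea":
                r = enrich.gsea_pvalue(scores, genes, B, rng, pathway_name=name)
            elif m in ("artp", "artp_e"):
                p, j_hat = _artp_null(L, m).pvalue(u)
                r = enrich.EnrichmentResult(name, L, m, p, p, {"j_hat": j_hat, "B": B})
            else:
                raise ValueError(f"unknown method {m!r}")
            results.append(r)

    df = enrich.results_to_frame(results)
    summary = df[df["pvalue"] < 0.05].groupby("method").size()
    import logging
    logging.getLogger("pathrank").info(
        "pathways at nominal p < 0.05 per method: %s", summary.to_dict()
    )
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
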