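"""Structure analyses of the suppression matrix.

Rows of the matrix are TS alleles (each mapping to one gene), columns are
wild strains, entries are suppression scores (NaN where a cross was not
estimated). Provides strain trees on phenotype/genotype distances, the
group-consistency permutation test for functional gene sets, same-gene
allele concordance, and the deleterious-load comparison.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("supmap.consistency")


@dataclass
class ConsistencyResult:
    group_id: str
    n_alleles: int
    n_pairs: int
    n_same_gene_pairs: int
    mean_pairwise_correlation: float
    p_perm: float
    p_fdr: float = np.nan
    consistent: bool = False


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _upgma_newick(dist: pd.DataFrame) -> str:
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.average(condensed)
    tree = TreeNode.from_linkage_matrix(linkage, list(dist.index))
    return str(tree).strip()


def phenotype_tree(matrix: pd.DataFrame) -> str:
    """UPGMA tree of strains on 1 − Pearson correlation of suppression
    profiles (pairwise-complete rows). Returns Newick."""
    mat = matrix.dropna(axis=1, how="all")
    dropped = set(matrix.columns) - set(mat.columns)
    if dropped:
        logger.warning("strains with all-missing profiles excluded: %s", dropped)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 strains with data")
    corr = mat.corr(min_periods=3)
    dist = (1.0 - corr).clip(lower=0.0)
    np.fill_diagonal(dist.values, 0.0)
    return _upgma_newick(dist)


def genotype_tree(variant_sets: dict[str, set]) -> str:
    """UPGMA tree of strains on the symmetric difference of their called
    variant sets (variants present in either strain but not both)."""
    strains = list(variant_sets)
    if len(strains) < 3:
        raise ValueError("need >= 3 strains")
    n = len(strains)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = len(variant_sets[strains[i]] ^ variant_sets[strains[j]])
    return _upgma_newick(pd.DataFrame(d, index=strains, columns=strains))


# ---------------------------------------------------------------------------
# Group consistency permutation test
# ---------------------------------------------------------------------------


def _pairwise_correlations(matrix: pd.DataFrame, min_shared: int = 3
                           ) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between allele rows."""
    return matrix.T.corr(min_periods=min_shared)


def group_consistency(matrix: pd.DataFrame, genes: pd.Series,
                      gene_sets: dict[str, set[str]], B: int = 1000,
                      seed: int = 0, corr_threshold: float = 0.25,
                      fdr_threshold: float = 0.25) -> list[ConsistencyResult]:
    """Test whether alleles of genes in each set share suppression profiles.

    The statistic for a set with N alleles is the mean Pearson correlation
    over its N(N−1)/2 allele pairs. The null resamples the same number of
    pairs from the whole matrix B times, matching the number of pairs that
    come from the same gene. p = (1 + #{null ≥ observed})/(B + 1), with
    Benjamini–Hochberg correction across sets; a set is consistent when the
    mean correlation exceeds ``corr_threshold`` and the corrected p is below
    ``fdr_threshold``.
    """
    corr = _pairwise_correlations(matrix)
    # sorted allele order and sorted pair pools make the permutation draws,
    # and hence the p-values, invariant to matrix row/column order
    alleles = sorted(matrix.index, key=str)
    gene_of = genes.to_dict()

    same_gene_vals, diff_gene_vals = [], []
    for a, b in itertools.combinations(alleles, 2):
        r = corr.loc[a, b]
        if np.isnan(r):
            continue
        (same_gene_vals if gene_of[a] == gene_of[b] else diff_gene_vals).append(r)
    same_gene_vals = np.sort(np.asarray(same_gene_vals))
    diff_gene_vals = np.sort(np.asarray(diff_gene_vals))

    results = []
    for group_id, members in gene_sets.items():
        rng = np.random.default_rng([seed, zlib.crc32(group_id.encode())])
        group_alleles = [a for a in alleles if gene_of[a] in members]
        pair_vals, n_same = [], 0
        for a, b in itertools.combinations(group_alleles, 2):
            r = corr.loc[a, b]
            if np.isnan(r):
                logger.debug("degenerate pair (%s, %s) skipped in %s", a, b,
                             group_id)
                continue
            pair_vals.append(r)
            if gene_of[a] == gene_of[b]:
                n_same += 1
        if len(group_alleles) < 2 or not pair_vals:
            continue
        observed = float(np.mean(pair_vals))
        n_pairs = len(pair_vals)
        n_diff = n_pairs - n_same
        if n_same > len(same_gene_vals) or n_diff > len(diff_gene_vals):
            logger.warning("not enough matrix pairs to match %s; skipped", group_id)
            continue
        null = np.empty(B)
        for b_i in range(B):
            draw = []
            if n_same:
                draw.append(rng.choice(same_gene_vals, size=n_same, replace=False))
            if n_diff:
                draw.append(rng.choice(diff_gene_vals, size=n_diff, replace=False))
            null[b_i] = np.concatenate(draw).mean()
        p_perm = (1.0 + np.sum(null >= observed)) / (B + 1.0)
        results.append(ConsistencyResult(group_id, len(group_alleles), n_pairs,
                                         n_same, observed, float(p_perm)))
    if results:
        _, p_fdr, *_ = multipletests([r.p_perm for r in results], method="fdr_bh")
        for r, q in zip(results, p_fdr):
            r.p_fdr = float(q)
            r.consistent = bool(r.mean_pairwise_correlation > corr_threshold
                                and r.p_fdr < fdr_threshold)
    return results


# ---------------------------------------------------------------------------
# Same-gene allele concordance
# ---------------------------------------------------------------------------


def same_gene_concordance(matrix: pd.DataFrame, genes: pd.Series,
                          called: set[tuple[str, str]], B: int = 1000,
                          seed: int = 0) -> dict:
    """Concordance of suppression between alleles of the same gene.

    For every called (allele, strain) pair whose gene has another assayed
    allele, take the maximum suppression score among the gene's other
    alleles in the same strain; the observed statistic is the mean of these.
    The expectation permutes gene labels among alleles B times. One-sided p.
    """
    rng = np.random.default_rng(seed)
    gene_of = genes.to_dict()

    def statistic(assignment: dict[str, str]) -> float:
        by_gene: dict[str, list[str]] = {}
        for a, g in assignment.items():
            by_gene.setdefault(g, []).append(a)
        vals = []
        for allele, strain in called:
            siblings = [a for a in by_gene.get(assignment.get(allele, ""), [])
                        if a != allele]
            if not siblings:
                continue
            scores = matrix.loc[siblings, strain].dropna()
            if len(scores):
                vals.append(scores.max())
        return float(np.mean(vals)) if vals else np.nan

    observed = statistic(gene_of)
    if np.isnan(observed):
        return {"observed": np.nan, "expected": np.nan, "p": np.nan,
                "note": "no multi-allele genes among called pairs"}
    alleles = sorted(gene_of, key=str)
    labels = [gene_of[a] for a in alleles]
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(labels)
        null[b] = statistic(dict(zip(alleles, perm)))
    null = null[~np.isnan(null)]
    expected = float(null.mean()) if len(null) else np.nan
    p = (1.0 + np.sum(null >= observed)) / (len(null) + 1.0)
    return {"observed": observed, "expected": expected, "p": float(p)}


# ---------------------------------------------------------------------------
# Deleterious load
# ---------------------------------------------------------------------------


def deleterious_load(counts: pd.DataFrame,
                     suppressed_pairs: set[tuple[str, str]], B: int = 1000,
                     seed: int = 0) -> dict:
    """Average count of deleterious mutations in suppressed vs other
    gene/strain combinations, with a permutation p for the difference.

    ``counts`` is a gene × strain frame of deleterious-mutation counts.
    """
    rng = np.random.default_rng(seed)
    stacked = counts.stack()
    labels = np.array([(g, s) in suppressed_pairs for g, s in stacked.index])
    values = stacked.to_numpy(dtype=float)
    if labels.sum() == 0 or labels.sum() == len(labels):
        return {"mean_suppressed": np.nan, "mean_other": np.nan, "p": np.nan,
                "note": "one of the groups is empty"}
    mean_sup = float(values[labels].mean())
    mean_other = float(values[~labels].mean())
    observed = mean_sup - mean_other
    null = np.empty(B)
    n_sup = int(labels.sum())
    for b in range(B):
        perm = rng.permutation(len(values))
        null[b] = values[perm[:n_sup]].mean() - values[perm[n_sup:]].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (B + 1.0)
    return {"mean_suppressed": mean_sup, "mean_other": mean_other,
            "difference": observed, "p": float(p)}


def matrix_from_scores(scores: pd.DataFrame, gene_of: dict[str, str] | None = None
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a per-(query, strain) score table into a suppression matrix and
    an allele → gene map (gene defaults to the allele id up to the last '-')."""
    matrix = scores.pivot_table(index="query_id", columns="strain_id",
                                values="score", aggfunc="first")
    if gene_of is None:
        gene_of = {q: q.rsplit("-", 1)[0] for q in matrix.index}
    genes = pd.Series({q: gene_of.get(q, q) for q in matrix.index})
    return matrix, genes
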