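"""Gene-set enrichment by the weighted Kolmogorov–Smirnov running sum.

Genes are ranked by the log2 ratio of class means on the CPM scale (a
pseudo-mean guards zero denominators). Walking down the ranking, set members
("hits") advance the running sum in proportion to |metric|^w normalized by
the summed hit weights, non-members retreat by 1/(N - N_hits); the
enrichment score ES is the signed extremum of the walk. The null is built
by re-drawing random gene sets of the same size from the ranked universe
(gene-set permutation, not phenotype permutation); NES divides ES by the
mean |null ES| among null scores of the same sign, and the permutation p is
the same-sign exceedance fraction with an add-one correction, so p is never
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GeneSet
from .qc import ExpressionMatrix


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    n_permutations: int
    seed: int
    n_hits: int


def rank_genes(
    X: ExpressionMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    pseudo_mean: float = 1.0,
) -> list[tuple[str, float]]:
    """Rank genes by log2((mean_A + c) / (mean_B + c)) of group-mean CPM.

    Decreasing metric; ties break lexicographically on gene id.
    """
    if X.scale != "cpm":
        raise ValueError(f"ranking expects cpm input, got {X.scale!r}")
    groups = X.groups
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, found {groups}")
        group_a, group_b = groups
    mask_a, mask_b = X.group_mask(group_a), X.group_mask(group_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = X.values[:, mask_a].mean(axis=1)
    mean_b = X.values[:, mask_b].mean(axis=1)
    metric = np.log2((mean_a + pseudo_mean) / (mean_b + pseudo_mean))
    order = sorted(range(len(X.gene_ids)), key=lambda i: (-metric[i], X.gene_ids[i]))
    return [(X.gene_ids[i], float(metric[i])) for i in order]


def enrichment_score(
    ranked: list[tuple[str, float]],
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set."""
    names = [g for g, _ in ranked]
    metric = np.array([m for _, m in ranked], dtype=float)
    hit = np.array([g in gene_set.members for g in names])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranking")
    profile = _running_sum(metric, hit, weight_exponent)
    es = profile[np.argmax(np.abs(profile))]
    return float(es), profile


def _running_sum(metric: np.ndarray, hit: np.ndarray, w: float) -> np.ndarray:
    n = metric.size
    n_hits = int(hit.sum())
    weights = np.abs(metric) ** w
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total
    if n_hits < n:
        steps = steps - np.where(hit, 0.0, 1.0 / (n - n_hits))
    else:  # degenerate all-hit set: net-zero walk against uniform expectation
        steps = steps - 1.0 / n
    return np.cumsum(steps)


def _null_es(
    metric: np.ndarray, set_size: int, n_perm: int, w: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null ES from random same-size gene sets of the universe.

    Only hit positions matter: between consecutive hits the walk falls
    linearly, so the extremum is attained immediately after or immediately
    before some hit; both candidate sets are evaluated from sorted hit
    positions and cumulative hit weights.
    """
    n = metric.size
    weights = np.abs(metric) ** w
    keys = rng.random((n_perm, n))
    hits = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    hits.sort(axis=1)
    hw = weights[hits]
    totals = hw.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if np.any(zero):  # unweighted fallback mirrors _running_sum
        hw[zero] = 1.0
        totals = hw.sum(axis=1, keepdims=True)
    cum = np.cumsum(hw, axis=1) / totals
    miss = 1.0 / (n - set_size)
    j = np.arange(1, set_size + 1)
    after = cum - (hits + 1 - j) * miss  # value just after each hit
    before = (cum - hw / totals) - (hits - (j - 1)) * miss  # just before
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def gsea_permutation(
    ranked: list[tuple[str, float]],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Gene-set permutation NES and p for one set against a fixed ranking."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    names = [g for g, _ in ranked]
    metric = np.array([m for _, m in ranked], dtype=float)
    hit = np.array([g in gene_set.members for g in names])
    set_size = int(hit.sum())
    if set_size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranking")
    if set_size >= len(names):
        raise ValueError("gene set covers the whole universe")
    es, _ = enrichment_score(ranked, gene_set, weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es(metric, set_size, n_perm, weight_exponent, rng)
    same_sign = null > 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same:
        nes = es / np.abs(null[same_sign]).mean()
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
    else:
        nes = np.sign(es) * np.inf if es != 0 else 0.0
        n_extreme = 0
    p_perm = (1 + n_extreme) / (1 + n_same) if n_same else 1.0 / (1 + n_perm)
    return GseaResult(
        set_name=gene_set.name,
        es=float(es),
        nes=float(nes),
        p_perm=float(p_perm),
        n_permutations=n_perm,
        seed=seed,
        n_hits=set_size,
    )
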