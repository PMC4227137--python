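"""Weighted running-sum gene set enrichment with a phenotype-permutation FWER.

Genes are ranked by the pooled-variance two-sample t statistic of the parous
vs nulliparous comparison (coefficient divided by its standard error),
descending. Walking down the ranked list, the running sum rises by
|t_i|^p / sum_hits |t_j|^p at signature genes and falls by 1/(N - N_hits)
elsewhere; the enrichment score (ES) is the running sum's maximum deviation
from zero, so |ES| <= 1 and the walk returns to zero at the end. Phenotype
labels are permuted to build the null ES distribution; the normalised score
NES divides ES by the mean magnitude of same-sign permuted scores, and the
single-set family-wise error rate is the fraction of permutations whose
|NES| is at least the observed one. FWER <= 15% is called significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import impute_missing
from .sam import _aligned_labels, _group_indices, _permutation_memberships, _pooled_stats
from .signature import GeneSignature, SignatureEntry
from ._utils import parous_mask

logger = logging.getLogger(__name__)

FWER_SIGNIFICANCE_THRESHOLD = 0.15


@dataclass
class RankedList:
    """Genes ordered by a signed ranking metric, descending."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RunningSum:
    """Result of one running-sum walk."""

    es: float
    hit_positions: np.ndarray  # 0-based ranks of signature genes
    peak_index: int  # 0-based rank where |running sum| peaks
    running: np.ndarray


@dataclass
class EnrichmentResult:
    """One signature x dataset enrichment test."""

    es: float
    nes: float
    fwer: float
    n_permutations: int
    leading_edge: list[str]
    hit_positions: np.ndarray
    peak_index: int
    es_permuted: np.ndarray = field(repr=False)

    @property
    def significant(self) -> bool:
        return self.fwer <= FWER_SIGNIFICANCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "es": self.es,
            "nes": self.nes,
            "fwer": self.fwer,
            "fwer_percent": int(round(self.fwer * 100)),
            "significant": bool(self.significant),
            "n_permutations": int(self.n_permutations),
            "leading_edge": list(self.leading_edge),
        }


def _t_statistics(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, welch: bool) -> np.ndarray:
    if welch:
        n1, n2 = len(idx1), len(idx2)
        m1 = X[:, idx1].mean(axis=1)
        m2 = X[:, idx2].mean(axis=1)
        v1 = X[:, idx1].var(axis=1, ddof=1)
        v2 = X[:, idx2].var(axis=1, ddof=1)
        se = np.sqrt(v1 / n1 + v2 / n2)
        r = m1 - m2
    else:
        r, se = _pooled_stats(X, idx1, idx2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r / se
    t[np.isnan(t)] = 0.0
    return t


def _cap_infinite(t: np.ndarray) -> np.ndarray:
    """Replace infinite metrics (zero pooled SE) with the largest finite rank."""
    inf = ~np.isfinite(t)
    if inf.any():
        finite = np.abs(t[~inf])
        cap = finite.max() if finite.size else 1.0
        logger.warning("%d genes with zero pooled SE capped at |t|=%g", inf.sum(), cap)
        t = t.copy()
        t[inf] = np.sign(t[inf]) * cap
    return t


def rank_genes(matrix: pd.DataFrame, groups, welch: bool = False) -> RankedList:
    """Rank genes by the parous-minus-nulliparous t statistic, descending.

    Ties are broken by gene symbol (ascending), making the order fully
    deterministic.
    """
    matrix = impute_missing(matrix)
    idx1, idx2 = _group_indices(_aligned_labels(matrix, groups))
    t = _cap_infinite(_t_statistics(matrix.to_numpy(dtype=float), idx1, idx2, welch))
    genes = np.asarray(matrix.index.astype(str))
    order = np.lexsort((genes, -t))
    return RankedList(genes[order], t[order])


def running_es(ranked: RankedList, gene_set, weight_p: float = 1.0) -> RunningSum:
    """Walk the ranked list and return the maximum-deviation enrichment score.

    A tie between a positive and a negative extremum of equal magnitude
    resolves to the positive one.
    """
    if weight_p < 0:
        raise ValueError("weight exponent must be non-negative")
    genes = ranked.genes
    hits = np.isin(genes, np.asarray(list(gene_set)))
    n_hits = int(hits.sum())
    N = len(genes)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == N:
        raise ValueError("gene set covers the whole ranked list; miss penalty undefined")
    weights = np.abs(ranked.metric) ** weight_p
    hit_total = weights[hits].sum()
    if hit_total == 0:
        # degenerate all-zero metrics among hits: fall back to equal weights
        increments = np.where(hits, 1.0 / n_hits, -1.0 / (N - n_hits))
    else:
        increments = np.where(hits, weights / hit_total, -1.0 / (N - n_hits))
    running = np.cumsum(increments)
    mx = running.max()
    mn = running.min()
    if mx >= -mn:
        es = float(mx)
        peak = int(np.argmax(running))
    else:
        es = float(mn)
        peak = int(np.argmin(running))
    return RunningSum(es, np.flatnonzero(hits), peak, running)


def leading_edge(run: RunningSum, ranked: RankedList) -> list[str]:
    """Signature genes at or before the ES peak (after it for negative ES)."""
    if run.es >= 0:
        positions = run.hit_positions[run.hit_positions <= run.peak_index]
    else:
        positions = run.hit_positions[run.hit_positions >= run.peak_index]
    return [str(g) for g in ranked.genes[positions]]


def _permuted_es(
    X: np.ndarray,
    memb: np.ndarray,
    n1: int,
    hit_mask: np.ndarray,
    weight_p: float,
    welch_unused: bool = False,
    block: int = 250,
) -> np.ndarray:
    """ES for every permutation column (pooled-t ranking), vectorised."""
    G, _ = X.shape
    n = X.shape[1]
    n2 = n - n1
    n_hits = int(hit_mask.sum())
    miss_pen = 1.0 / (G - n_hits)
    out = np.empty(memb.shape[1])
    Xsq = X ** 2
    T = X.sum(axis=1, keepdims=True)
    Q = Xsq.sum(axis=1, keepdims=True)
    for start in range(0, memb.shape[1], block):
        mb = memb[:, start : start + block].astype(float)
        S1 = X @ mb
        Q1 = Xsq @ mb
        m1 = S1 / n1
        m2 = (T - S1) / n2
        ss1 = np.maximum(Q1 - n1 * m1 ** 2, 0.0)
        ss2 = np.maximum((Q - Q1) - n2 * m2 ** 2, 0.0)
        se = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / se
        t[np.isnan(t)] = 0.0
        t[np.isinf(t)] = np.sign(t[np.isinf(t)]) * 1e12
        order = np.argsort(-t, axis=0, kind="stable")
        w = np.take_along_axis(np.abs(t), order, axis=0) ** weight_p
        h = hit_mask[order]
        hit_w = np.where(h, w, 0.0)
        denom = hit_w.sum(axis=0)
        safe = denom > 0
        inc = np.where(h, 0.0, -miss_pen)
        inc = inc + np.where(
            h, np.where(safe[None, :], hit_w / np.where(safe, denom, 1.0), 1.0 / n_hits), 0.0
        )
        run = np.cumsum(inc, axis=0)
        mx = run.max(axis=0)
        mn = run.min(axis=0)
        out[start : start + mb.shape[1]] = np.where(mx >= -mn, mx, mn)
    return out


def permutation_fwer(
    matrix: pd.DataFrame,
    groups,
    sig: GeneSignature,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    welch: bool = False,
) -> EnrichmentResult:
    """Observed ES plus its phenotype-permutation NES and FWER.

    The signature is matched against the matrix genes (exact symbols; align
    first for case-insensitive matching). When fewer distinct relabellings
    than ``n_permutations`` exist they are enumerated exhaustively.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    matrix = impute_missing(matrix)
    labels = _aligned_labels(matrix, groups)
    idx1, idx2 = _group_indices(labels)
    ranked = rank_genes(matrix, labels, welch=welch)
    run = running_es(ranked, sig.genes, weight_p)

    X = matrix.to_numpy(dtype=float)
    hit_mask = np.isin(np.asarray(matrix.index.astype(str)), np.asarray(sig.genes))
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    total = math.comb(n, len(idx1))
    if total <= n_permutations:
        memb, n_used = _permutation_memberships(rng, idx1, idx2, n, n_permutations)
    else:
        memb = np.zeros((n, n_permutations), dtype=bool)
        par = parous_mask(labels)
        for b in range(n_permutations):
            memb[rng.permutation(n)[: len(idx1)], b] = True
        n_used = n_permutations
    es_perm = _permuted_es(X, memb, len(idx1), hit_mask, weight_p, welch)

    pos = es_perm[es_perm > 0]
    neg = -es_perm[es_perm < 0]
    fallback = np.abs(es_perm).mean() if np.abs(es_perm).mean() > 0 else 1.0
    mean_pos = pos.mean() if pos.size else fallback
    mean_neg = neg.mean() if neg.size else fallback
    nes = run.es / (mean_pos if run.es >= 0 else mean_neg)
    nes_perm = es_perm / np.where(es_perm >= 0, mean_pos, mean_neg)
    fwer = float(np.mean(np.abs(nes_perm) >= abs(nes)))

    return EnrichmentResult(
        es=run.es,
        nes=float(nes),
        fwer=fwer,
        n_permutations=n_used,
        leading_edge=leading_edge(run, ranked),
        hit_positions=run.hit_positions,
        peak_index=run.peak_index,
        es_permuted=es_perm,
    )


def refine_signature(core_sets, name: str = "core") -> GeneSignature:
    """Intersect leading-edge gene lists, keeping the first list's order.

    This is the refinement step that reduces a discovery signature to the
    genes consistently driving enrichment across several analyses.
    """
    core_sets = [list(s) for s in core_sets]
    if len(core_sets) < 2:
        raise ValueError("need at least two gene lists to intersect")
    if any(len(s) == 0 for s in core_sets):
        raise ValueError("core gene lists must be nonempty")
    common = set(core_sets[0])
    for s in core_sets[1:]:
        common &= set(s)
    ordered = [g for g in core_sets[0] if g in common]
    if not ordered:
        logger.warning("core sets have empty intersection; returning empty signature")
    return GeneSignature(name, tuple(SignatureEntry(g, "up", None) for g in ordered))


class GseaPermutationTest(BaseEstimator):
    """Estimator-shaped wrapper: ``fit(X, y)`` with samples x genes input.

    Parameters mirror :func:`permutation_fwer`; fitted attributes are
    ``es_``, ``nes_``, ``fwer_``, ``significant_``, ``leading_edge_``.
    """

    def __init__(
        self,
        gene_set=None,
        weight_p: float = 1.0,
        n_permutations: int = 1000,
        welch: bool = False,
        random_state: int = 0,
    ):
        self.gene_set = gene_set
        self.weight_p = weight_p
        self.n_permutations = n_permutations
        self.welch = welch
        self.random_state = random_state

    def fit(self, X, y):
        if self.gene_set is None:
            raise ValueError("gene_set must be provided")
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            raise TypeError("GseaPermutationTest needs a DataFrame with gene columns")
        sig = (
            self.gene_set
            if isinstance(self.gene_set, GeneSignature)
            else GeneSignature(
                "gene_set", tuple(SignatureEntry(g, "up", None) for g in self.gene_set)
            )
        )
        res = permutation_fwer(
            matrix,
            np.asarray(y),
            sig,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            weight_p=self.weight_p,
            welch=self.welch,
        )
        self.result_ = res
        self.es_ = res.es
        self.nes_ = res.nes
        self.fwer_ = res.fwer
        self.significant_ = res.significant
        self.leading_edge_ = res.leading_edge
        self.n_features_in_ = matrix.shape[0]
        return self
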