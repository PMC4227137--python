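"""SAM-style two-class differential expression with permutation FDR.

The moderated statistic for gene *g* is

    d_g = (mean_parous - mean_nulliparous) / (s_g + s0)

where ``s_g`` is the pooled two-sample standard error and ``s0`` the "fudge
factor" that stabilises low-variance genes. The nulliparous group is the
reference, so positive ``d`` means upregulation with parity.

Selection thresholds form the canonical one-parameter family: for a
deviation threshold Delta, genes are called whose sorted statistic deviates
from its permutation-expected order statistic by at least Delta (upper and
lower tails jointly). The false discovery rate of a threshold is estimated
from the permutation null built by relabelling samples:
FDR = (1 + pooled permuted count beyond the cuts) / (B + 1) / (observed
count), a plus-one-corrected mean false-call count that stays strictly
positive whenever anything is called. Per-gene q-values are the lowest
estimated FDR at which each gene would be called, so selections at nested
FDR targets are nested.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import impute_missing
from .signature import GeneSignature, SignatureEntry
from ._utils import parous_mask

logger = logging.getLogger(__name__)

S0_PERCENTILE_CANDIDATES = np.arange(0, 101, 5)


@dataclass
class SamParams:
    """Tuning parameters of the SAM run.

    Exactly one of ``delta`` (fixed threshold on the deviation of the sorted
    statistics from their permutation-expected order statistics) or
    ``target_fdr`` (select the loosest threshold whose estimated FDR stays
    below the target) must be set.
    """

    s0_mode: str = "percentile_auto"
    s0_value: float = 0.0
    n_permutations: int = 1000
    delta: float | None = None
    target_fdr: float | None = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0_mode not in ("percentile_auto", "fixed"):
            raise ValueError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed" and self.s0_value < 0:
            raise ValueError("s0_value must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if (self.delta is None) == (self.target_fdr is None):
            raise ValueError("set exactly one of delta / target_fdr")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.target_fdr is not None and not 0 < self.target_fdr < 1:
            raise ValueError("target_fdr must lie in (0, 1)")


@dataclass
class SamResult:
    """Per-gene SAM output plus the achieved selection threshold."""

    table: pd.DataFrame  # columns: d, fold_change, q_value, p_value, selected
    achieved_fdr: float  # NaN when nothing was selected
    s0: float
    n_permutations_used: int
    delta_used: float | None = None

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _group_indices(labels) -> tuple[np.ndarray, np.ndarray]:
    par = parous_mask(labels)
    idx1 = np.flatnonzero(par)
    idx2 = np.flatnonzero(~par)
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError(
            f"each parity group needs >= 2 samples (got {len(idx1)} parous, "
            f"{len(idx2)} nulliparous)"
        )
    return idx1, idx2


def _pooled_stats(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    """Numerator (mean difference) and pooled standard error per gene."""
    n1, n2 = len(idx1), len(idx2)
    m1 = X[:, idx1].mean(axis=1)
    m2 = X[:, idx2].mean(axis=1)
    ss1 = ((X[:, idx1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, idx2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return m1 - m2, s


def _safe_ratio(r: np.ndarray, denom: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r / denom
    d[np.isnan(d)] = 0.0  # 0/0: no difference, no variance
    return d


def sam_statistic(matrix: pd.DataFrame, groups, s0: float = 0.0) -> pd.Series:
    """The SAM d-statistic per gene (parous minus nulliparous)."""
    matrix = impute_missing(matrix)
    idx1, idx2 = _group_indices(_aligned_labels(matrix, groups))
    r, s = _pooled_stats(matrix.to_numpy(dtype=float), idx1, idx2)
    return pd.Series(_safe_ratio(r, s + s0), index=matrix.index, name="d")


def _aligned_labels(matrix: pd.DataFrame, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.reindex(matrix.columns).to_numpy()
    if isinstance(groups, pd.DataFrame):
        return groups.reindex(matrix.columns)["parity"].to_numpy()
    groups = np.asarray(groups)
    if len(groups) != matrix.shape[1]:
        raise ValueError("group labels do not match the number of samples")
    return groups


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher-style percentile search for the fudge factor.

    Candidates are the 0th-100th percentiles of the s distribution in steps
    of five. The objective is the coefficient of variation, across contiguous
    s-quantile bins, of the median absolute deviation of d; the candidate
    minimising it wins, ties going to the smallest candidate.
    """
    if np.all(s == 0):
        logger.warning("all pooled standard errors are zero; s0 set to 0")
        return 0.0
    candidates = np.percentile(s, S0_PERCENTILE_CANDIDATES)
    n_bins = min(100, max(2, len(s) // 5))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    objective = np.empty(len(candidates))
    for i, alpha in enumerate(candidates):
        d = _safe_ratio(r, s + alpha)
        mads = np.array(
            [np.median(np.abs(d[b] - np.median(d[b]))) * 1.4826 for b in bins]
        )
        mean = mads.mean()
        objective[i] = np.inf if mean == 0 else mads.std() / mean
    if not np.isfinite(objective).any():
        return float(candidates[0])
    return float(candidates[int(np.argmin(objective))])


def choose_s0(matrix: pd.DataFrame, groups) -> float:
    """Search the fudge factor on observed data; see :func:`_choose_s0`."""
    matrix = impute_missing(matrix)
    if matrix.shape[0] < 50:
        logger.warning("s0 search with only %d genes is unstable", matrix.shape[0])
    idx1, idx2 = _group_indices(_aligned_labels(matrix, groups))
    r, s = _pooled_stats(matrix.to_numpy(dtype=float), idx1, idx2)
    return _choose_s0(r, s)


def _permutation_memberships(
    rng: np.random.Generator,
    idx1: np.ndarray,
    idx2: np.ndarray,
    n_samples: int,
    n_perm: int,
) -> tuple[np.ndarray, int]:
    """Boolean samples x B matrix; column b marks the pseudo-parous group.

    When the number of distinct relabellings is at most ``n_perm`` they are
    enumerated completely; otherwise balanced random relabellings are drawn
    (each pseudo-group keeps roughly proportional representation of the two
    original groups, the SAM convention).
    """
    n1, n2 = len(idx1), len(idx2)
    total = math.comb(n_samples, n1)
    if total <= n_perm:
        logger.warning(
            "only %d distinct permutations exist (<= %d requested); enumerating all",
            total, n_perm,
        )
        memb = np.zeros((n_samples, total), dtype=bool)
        for b, combo in enumerate(itertools.combinations(range(n_samples), n1)):
            memb[list(combo), b] = True
        return memb, total
    k1 = int(round(n1 * n1 / n_samples))
    k1 = min(max(k1, max(0, n1 - n2)), n1)
    memb = np.zeros((n_samples, n_perm), dtype=bool)
    for b in range(n_perm):
        take1 = rng.choice(idx1, size=k1, replace=False)
        take2 = rng.choice(idx2, size=n1 - k1, replace=False)
        memb[take1, b] = True
        memb[take2, b] = True
    return memb, n_perm


def _permuted_d(X: np.ndarray, memb: np.ndarray, n1: int, s0: float) -> np.ndarray:
    """d-statistics for every permutation column, vectorised via matmuls."""
    n = X.shape[1]
    n2 = n - n1
    memb_f = memb.astype(float)
    S1 = X @ memb_f
    Q1 = (X ** 2) @ memb_f
    T = X.sum(axis=1, keepdims=True)
    Q = (X ** 2).sum(axis=1, keepdims=True)
    m1 = S1 / n1
    m2 = (T - S1) / n2
    ss1 = np.maximum(Q1 - n1 * m1 ** 2, 0.0)
    ss2 = np.maximum((Q - Q1) - n2 * m2 ** 2, 0.0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n - 2))
    return _safe_ratio(m1 - m2, s + s0)


def sam_fdr(matrix: pd.DataFrame, groups, params: SamParams | None = None) -> SamResult:
    """Full SAM run: statistic, permutation null, q-values and selection."""
    params = params or SamParams()
    matrix = impute_missing(matrix)
    labels = _aligned_labels(matrix, groups)
    idx1, idx2 = _group_indices(labels)
    X = matrix.to_numpy(dtype=float)
    G = X.shape[0]
    r, s = _pooled_stats(X, idx1, idx2)
    s0 = params.s0_value if params.s0_mode == "fixed" else _choose_s0(r, s)
    d = _safe_ratio(r, s + s0)
    fc = 2.0 ** r  # geometric-mean ratio on linear scale (log2 input assumed)

    rng = np.random.default_rng(params.seed)
    memb, n_used = _permutation_memberships(
        rng, idx1, idx2, X.shape[1], params.n_permutations
    )
    D = _permuted_d(X, memb, len(idx1), s0)
    D_sorted = np.sort(D, axis=0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = D_sorted.mean(axis=1)  # permutation-expected order statistics
    diff = d_sorted - dbar
    mid = int(np.argmin(np.abs(dbar)))

    # One-parameter joint two-tail threshold family: for a deviation
    # threshold Delta, the upper cut is the first sorted statistic (walking
    # up from the middle) whose deviation from its expected order statistic
    # reaches Delta, and symmetrically downward. Only running-maximum record
    # deviations yield distinct cuts.
    up_cut_vals, up_deltas = [], []
    run_max = -np.inf
    for i in range(mid, G):
        if diff[i] > run_max:
            run_max = diff[i]
            up_cut_vals.append(d_sorted[i])
            up_deltas.append(run_max)
    down_cut_vals, down_deltas = [], []
    run_max = -np.inf
    for i in range(mid, -1, -1):
        if -diff[i] > run_max:
            run_max = -diff[i]
            down_cut_vals.append(d_sorted[i])
            down_deltas.append(run_max)
    up_cut_vals = np.asarray(up_cut_vals)
    up_deltas = np.asarray(up_deltas)
    down_cut_vals = np.asarray(down_cut_vals)
    down_deltas = np.asarray(down_deltas)

    # Pooled permutation tail counts; the estimated false-call count carries a
    # plus-one correction ((1 + pooled)/(B + 1)), which keeps the estimate
    # strictly positive whenever anything is called (see docs/methods.md).
    D_flat = np.sort(D.ravel())
    n_pool = D_flat.size

    def _estimate(delta: float) -> tuple[float, float, float, int]:
        """(fdr, cut_up, cut_low, n_called) for one Delta."""
        j_up = int(np.searchsorted(up_deltas, delta, side="left"))
        j_dn = int(np.searchsorted(down_deltas, delta, side="left"))
        cut_up = up_cut_vals[j_up] if j_up < len(up_cut_vals) else np.inf
        cut_low = down_cut_vals[j_dn] if j_dn < len(down_cut_vals) else -np.inf
        called = int(G - np.searchsorted(d_sorted, cut_up, side="left"))
        called += int(np.searchsorted(d_sorted, cut_low, side="right"))
        if called == 0:
            return np.nan, cut_up, cut_low, 0
        pooled = 0
        if np.isfinite(cut_up):
            pooled += n_pool - int(np.searchsorted(D_flat, cut_up, side="left"))
        if np.isfinite(cut_low):
            pooled += int(np.searchsorted(D_flat, cut_low, side="right"))
        false = (1.0 + pooled) / (n_used + 1)
        return float(min(false / called, 1.0)), float(cut_up), float(cut_low), called

    # q-value: lowest estimated FDR over thresholds that call the gene.
    deltas = np.unique(np.concatenate([up_deltas, down_deltas, [0.0]]))
    q = np.full(G, 1.0)
    sorted_pos = np.empty(G, dtype=int)
    sorted_pos[order] = np.arange(G)
    q_sorted = np.full(G, 1.0)
    for delta in deltas:
        fdr, cut_up, cut_low, called = _estimate(float(delta))
        if called == 0:
            continue
        i_up = np.searchsorted(d_sorted, cut_up, side="left")
        i_dn = np.searchsorted(d_sorted, cut_low, side="right")
        if i_up < G:
            q_sorted[i_up:] = np.minimum(q_sorted[i_up:], fdr)
        if i_dn > 0:
            q_sorted[:i_dn] = np.minimum(q_sorted[:i_dn], fdr)
    q = q_sorted[sorted_pos]

    pooled_abs = np.sort(np.abs(D).ravel())
    p = 1.0 - np.searchsorted(pooled_abs, np.abs(d), side="left") / pooled_abs.size

    delta_used: float | None = None
    if params.target_fdr is not None:
        selected = q <= params.target_fdr
        achieved = float(q[selected].max()) if selected.any() else float("nan")
    else:
        delta_used = params.delta
        achieved, cut_up, cut_low, called = _estimate(params.delta)
        selected = (d >= cut_up) | (d <= cut_low)
        if called == 0:
            achieved = float("nan")
    if not selected.any():
        logger.info("SAM selected no genes; achieved FDR undefined")

    table = pd.DataFrame(
        {"d": d, "fold_change": fc, "q_value": q, "p_value": p, "selected": selected},
        index=matrix.index.copy(),
    )
    return SamResult(
        table=table,
        achieved_fdr=achieved,
        s0=float(s0),
        n_permutations_used=n_used,
        delta_used=delta_used,
    )


def extract_signature(result: SamResult, name: str) -> GeneSignature:
    """Turn the selected genes into a signature (direction from the sign of d).

    Genes are ordered by ascending q-value, ties broken by descending |d|.
    An empty selection yields an empty signature with a logged warning.
    """
    sel = result.table[result.table["selected"]]
    if sel.empty:
        logger.warning("no genes selected; returning empty signature %r", name)
        return GeneSignature(name, ())
    sel = sel.sort_values(["q_value", "d"], key=lambda c: c if c.name == "q_value" else -c.abs())
    entries = tuple(
        SignatureEntry(str(g), "up" if row.d > 0 else "down", float(row.fold_change))
        for g, row in sel.iterrows()
    )
    return GeneSignature(name, entries)


class SamSelector(BaseEstimator):
    """scikit-learn style wrapper around the SAM procedure.

    ``fit(X, y)`` expects samples x genes input (array or DataFrame) and
    parity labels ``y`` ('parous'/'nulliparous', booleans or 0/1 with 1 =
    parous). Fitted attributes mirror :class:`SamResult`; ``transform``
    restricts a matrix to the selected genes.
    """

    def __init__(
        self,
        s0_mode: str = "percentile_auto",
        s0_value: float = 0.0,
        n_permutations: int = 1000,
        delta: float | None = None,
        target_fdr: float | None = 0.01,
        random_state: int = 0,
    ):
        self.s0_mode = s0_mode
        self.s0_value = s0_value
        self.n_permutations = n_permutations
        self.delta = delta
        self.target_fdr = target_fdr
        self.random_state = random_state

    def _params(self) -> SamParams:
        return SamParams(
            s0_mode=self.s0_mode,
            s0_value=self.s0_value,
            n_permutations=self.n_permutations,
            delta=self.delta,
            target_fdr=self.target_fdr,
            seed=self.random_state,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            matrix = X.T
            self.feature_names_in_ = np.asarray(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            matrix = pd.DataFrame(
                X.T, index=[f"f{i}" for i in range(X.shape[1])]
            )
            self.feature_names_in_ = None
        result = sam_fdr(matrix, np.asarray(y), self._params())
        self.result_ = result
        self.d_ = result.table["d"].to_numpy()
        self.fold_change_ = result.table["fold_change"].to_numpy()
        self.q_values_ = result.table["q_value"].to_numpy()
        self.p_values_ = result.table["p_value"].to_numpy()
        self.selected_ = result.table["selected"].to_numpy()
        self.achieved_fdr_ = result.achieved_fdr
        self.s0_ = result.s0
        self.n_features_in_ = matrix.shape[0]
        return self

    def get_support(self) -> np.ndarray:
        return self.selected_.copy()

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_]
        return np.asarray(X)[:, self.selected_]

    def get_signature(self, name: str = "sam_signature") -> GeneSignature:
        return extract_signature(self.result_, name)
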