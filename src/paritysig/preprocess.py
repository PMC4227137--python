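"""Matrix preparation: probe collapse, missing-value imputation, centering."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLLAPSE_RULES = ("max_mean", "median")


def collapse_probes(matrix: pd.DataFrame, rule: str = "max_mean") -> pd.DataFrame:
    """Collapse duplicate gene rows (probes) to one row per symbol.

    ``max_mean`` keeps the probe with the largest mean expression (ties: first
    occurrence); ``median`` takes the element-wise median across probes.
    First-occurrence gene order is preserved. Idempotent.
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {rule!r}; expected one of {COLLAPSE_RULES}")
    if matrix.index.is_unique:
        return matrix.copy()
    order = matrix.index[~matrix.index.duplicated(keep="first")]
    if rule == "max_mean":
        means = matrix.mean(axis=1, skipna=True).to_numpy()
        keep_pos: dict[str, int] = {}
        for pos, gene in enumerate(matrix.index):
            best = keep_pos.get(gene)
            if best is None or means[pos] > means[best]:
                keep_pos[gene] = pos
        collapsed = matrix.iloc[[keep_pos[g] for g in order]]
    else:
        collapsed = matrix.groupby(level=0, sort=False).median().loc[order]
    n_dropped = len(matrix) - len(collapsed)
    logger.info("collapse_probes(%s): dropped %d duplicate probe rows", rule, n_dropped)
    return collapsed


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Impute missing values per gene with that gene's sample median.

    Downstream statistics assume complete data; this runs (with a logged
    count) at each analysis entry point. A gene missing in every sample
    cannot be imputed and raises.
    """
    values = matrix.to_numpy(dtype=float, copy=True)
    mask = np.isnan(values)
    n_missing = int(mask.sum())
    if n_missing == 0:
        return matrix
    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = list(matrix.index[all_missing][:10])
        raise ValueError(f"genes with no observed values cannot be imputed: {bad}")
    medians = np.nanmedian(values, axis=1)
    values[mask] = np.broadcast_to(medians[:, None], values.shape)[mask]
    logger.info("imputed %d missing expression values with per-gene medians", n_missing)
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def median_center_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each gene row on its median across samples."""
    return matrix.sub(matrix.median(axis=1), axis=0)
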