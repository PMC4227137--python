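"""Creighton correlation classification of samples against a signature.

A standard (template) vector over the signature genes assigns +1 to genes
whose training fold change exceeds the signature's median fold change and -1
to the rest. Each sample's expression over those genes, median-centered per
gene within the dataset being scored, is correlated (Pearson) with the
template; samples with r > 0 are called signature-positive, the rest
negative (r = 0 and undefined r resolve to negative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import impute_missing
from .signature import GeneSignature, align_signature

logger = logging.getLogger(__name__)

TEMPLATE_MODES = ("median_fold_change", "direction")


def template_vector(sig: GeneSignature, mode: str = "median_fold_change") -> pd.Series:
    """Build the +/-1 template over the signature genes.

    ``median_fold_change`` (the default): +1 iff the gene's fold change is
    greater than the median fold change of the signature, -1 if smaller;
    genes exactly at the median receive +1 (tie rule). Requires every entry
    to carry a fold change.

    ``direction``: +1 for up genes, -1 for down genes, ignoring fold changes
    (fallback for signatures without training fold changes).
    """
    if mode not in TEMPLATE_MODES:
        raise ValueError(f"unknown template mode {mode!r}")
    if len(sig) == 0:
        raise ValueError("cannot build a template from an empty signature")
    if mode == "direction":
        values = np.array([1.0 if e.direction == "up" else -1.0 for e in sig.entries])
    else:
        if not sig.has_fold_changes():
            raise ValueError(
                "signature has entries without fold changes; use mode='direction' "
                "(+1 for up, -1 for down) instead"
            )
        fcs = np.array([float(e.fold_change) for e in sig.entries])
        med = np.median(fcs)
        values = np.where(fcs >= med, 1.0, -1.0)
    if len(np.unique(values)) == 1:
        logger.warning(
            "degenerate template for %r: all entries %+g; correlations undefined",
            sig.name, values[0],
        )
    return pd.Series(values, index=sig.genes, name="template")


def score_samples(
    matrix: pd.DataFrame,
    sig: GeneSignature,
    template: pd.Series | None = None,
    mode: str = "median_fold_change",
    min_match_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-sample correlation with the template and the resulting call.

    Returns a DataFrame indexed by sample with columns ``r`` (Pearson
    correlation; NaN when undefined), ``call`` ('positive'/'negative') and
    ``flagged`` (True when r was undefined, e.g. a zero-variance sample).
    """
    matrix = impute_missing(matrix)
    aligned, _ = align_signature(sig, matrix, min_match_fraction)
    if len(aligned) < 3:
        raise ValueError(f"need >= 3 matched signature genes, got {len(aligned)}")
    if template is None:
        template = template_vector(aligned, mode)
    else:
        template = template.reindex(aligned.genes)
        if template.isna().any():
            raise ValueError("template does not cover the matched signature genes")
    sub = matrix.loc[aligned.genes]
    centered = sub.sub(sub.median(axis=1), axis=0).to_numpy()
    t = template.to_numpy(dtype=float)
    tc = t - t.mean()
    xc = centered - centered.mean(axis=0)
    t_norm = np.sqrt((tc ** 2).sum())
    x_norm = np.sqrt((xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc @ xc) / (t_norm * x_norm)
    flagged = ~np.isfinite(r)
    if flagged.any():
        logger.warning(
            "%d samples with undefined correlation (zero variance); called negative",
            int(flagged.sum()),
        )
    r = np.where(flagged, np.nan, r)
    calls = np.where(np.nan_to_num(r, nan=-1.0) > 0, "positive", "negative")
    return pd.DataFrame({"r": r, "call": calls, "flagged": flagged}, index=matrix.columns)


class CreightonClassifier(BaseEstimator, ClassifierMixin):
    """Correlation-template classifier in scikit-learn clothing.

    The classifier is fixed by the signature; ``fit`` only validates and
    stores the template. Median-centering is performed within the dataset
    passed to ``predict``/``decision_function`` (the scored cohort defines
    its own centering), so predictions are transductive per dataset.
    """

    classes_ = np.array(["negative", "positive"])

    def __init__(self, signature: GeneSignature | None = None, mode: str = "median_fold_change"):
        self.signature = signature
        self.mode = mode

    def fit(self, X=None, y=None):
        if self.signature is None or len(self.signature) == 0:
            raise ValueError("signature must be provided and nonempty")
        if self.mode not in TEMPLATE_MODES:
            raise ValueError(f"unknown template mode {self.mode!r}")
        self.template_ = template_vector(self.signature, self.mode)
        return self

    def _score(self, X) -> pd.DataFrame:
        if not hasattr(self, "template_"):
            self.fit()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("CreightonClassifier needs a DataFrame with gene columns")
        return score_samples(X.T, self.signature, mode=self.mode)

    def decision_function(self, X) -> np.ndarray:
        return self._score(X)["r"].to_numpy()

    def predict(self, X) -> np.ndarray:
        return self._score(X)["call"].to_numpy()
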