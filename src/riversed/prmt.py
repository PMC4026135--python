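"""Normalization of enzyme-gene abundance tables and PRMT scoring.

Predicted relative metabolic turnover (PRMT) projects per-sample deviations of
normalized, log2-scale enzyme-gene abundances from a reference (the average of
all samples) through the environmental transformation matrix (ETM):

    score(s, m) = sum_e ETM[m, e] * (x[s, e] - reference[e])

Positive scores indicate relative consumption potential for a metabolite,
negative scores relative accumulation.  Because the reference is the average
metagenome, scores describe relative flux only, never absolute production or
consumption.

The transform-shaped steps are scikit-learn estimators (``QuantileNormalizer``,
``PRMTScorer``) so they compose with sklearn pipelines; the module-level
functions are thin wrappers matching the procedural interface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import RiversedError, warn
from .reactions import ETM


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _map_to_target(row: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Assign rank-k target values to a row; ties get the mean of their
    tied-rank targets."""
    order = np.argsort(row, kind="mergesort")
    assigned = np.empty_like(target)
    assigned[order] = target
    # average assigned values over groups of equal input values
    s = pd.Series(assigned)
    return s.groupby(pd.Series(row)).transform("mean").to_numpy()


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization: every sample gets the same value distribution.

    ``fit`` learns the target distribution (the mean of the rank-k values
    across the fitted samples); ``transform`` maps each sample's ranks onto
    it.  ``fit_transform`` on a table reproduces classic quantile
    normalization of that table.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise RiversedError("quantile normalization needs >= 2 samples")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        self.target_distribution_ = np.sort(X.to_numpy(float), axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "target_distribution_")
        X = _as_frame(X)
        if X.shape[1] != self.n_features_in_:
            raise RiversedError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        arr = X.to_numpy(float)
        out = np.vstack([_map_to_target(r, self.target_distribution_) for r in arr])
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a samples x features table (rank means across samples)."""
    return QuantileNormalizer().fit_transform(table)


def log2_with_pseudocount(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """``x -> log2(x + pseudocount)``; requires nonnegative input."""
    if pseudocount <= 0:
        raise RiversedError(f"pseudocount must be > 0, got {pseudocount}")
    table = _as_frame(table)
    if (table.to_numpy(float) < 0).any():
        raise RiversedError("log2 transform requires nonnegative values")
    return np.log2(table + pseudocount)


def average_reference(norm: pd.DataFrame) -> pd.Series:
    """The 'average of all samples' reference: per-enzyme arithmetic mean."""
    norm = _as_frame(norm)
    if norm.shape[0] < 1:
        raise RiversedError("reference requires at least one sample")
    return norm.mean(axis=0)


def prmt_scores(etm: ETM, norm: pd.DataFrame, reference: pd.Series) -> pd.DataFrame:
    """PRMT scores (samples x metabolites) from normalized abundances.

    Enzymes present in the table but absent from the ETM are excluded with a
    warning; ETM enzymes missing from the table contribute nothing (their
    abundance delta is taken as zero).
    """
    norm = _as_frame(norm)
    enzymes = [e for e in norm.columns if e in set(etm.enzymes)]
    n_missing = norm.shape[1] - len(enzymes)
    if n_missing:
        warn(f"{n_missing} enzyme(s) in the table are absent from the ETM; excluded")
    if not enzymes:
        raise RiversedError("no enzyme in the table matches the ETM")
    delta = norm[enzymes].to_numpy(float) - np.asarray(reference[enzymes], dtype=float)
    mat = etm.matrix[enzymes].to_numpy(float)  # metabolites x enzymes
    scores = delta @ mat.T
    return pd.DataFrame(scores, index=norm.index, columns=etm.metabolites)


class PRMTScorer(BaseEstimator, TransformerMixin):
    """End-to-end PRMT transformer: counts -> metabolite turnover scores.

    Parameters
    ----------
    etm : ETM
        Environmental transformation matrix (metabolites x enzymes).
    quantile : bool
        Quantile-normalize raw abundances before the log transform.
    pseudocount : float
        Pseudocount for the log2 transform.
    log_first : bool
        Apply log2 before quantile normalization instead of after.

    ``fit`` learns the quantile target distribution and the reference (mean of
    the fitted, transformed samples); ``transform`` scores samples against
    that reference, so the fitted samples' scores sum to zero per metabolite.
    """

    def __init__(self, etm: ETM, quantile: bool = True, pseudocount: float = 1.0,
                 log_first: bool = False):
        self.etm = etm
        self.quantile = quantile
        self.pseudocount = pseudocount
        self.log_first = log_first

    def _pretransform(self, X: pd.DataFrame, fit: bool) -> pd.DataFrame:
        if self.log_first:
            X = log2_with_pseudocount(X, self.pseudocount)
        if self.quantile:
            X = self.normalizer_.fit_transform(X) if fit else self.normalizer_.transform(X)
        if not self.log_first:
            X = log2_with_pseudocount(X, self.pseudocount)
        return X

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.normalizer_ = QuantileNormalizer()
        norm = self._pretransform(X, fit=True)
        self.reference_ = average_reference(norm)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        X = _as_frame(X)
        norm = self._pretransform(X, fit=False)
        return prmt_scores(self.etm, norm, self.reference_)


def average_replicates(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average PRMT scores over replicates: one row per (site, season, year).

    Unit ids are ``site.Yyear.season``.  Every scored sample must appear in
    the metadata.
    """
    missing = [s for s in scores.index if s not in meta.index]
    if missing:
        raise RiversedError(f"samples missing from metadata: {missing[:5]}")
    keys = meta.loc[scores.index]
    unit = (
        keys["site"].astype(str)
        + ".Y" + keys["year"].astype(str)
        + "." + keys["season"].astype(str)
    )
    out = scores.groupby(unit).mean()
    out.index.name = "unit"
    return out
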