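"""Ancestry verification from a panel of ancestry-informative SNPs.

Self-declared population labels are checked by projecting the genotype
matrix (samples x SNPs, dosages 0/1/2) onto its first two principal
components and modelling each population as a full-covariance bivariate
Gaussian in that plane — a "non-naive" Bayes classifier, in that the
correlation between the two components is modelled rather than assumed
away. Samples whose maximum-posterior population disagrees with the
declared label are flagged for review.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _impute_center(X: np.ndarray, means: np.ndarray | None = None):
    """Missing dosages (NaN) to the SNP mean, then center."""
    X = np.asarray(X, dtype=float)
    if means is None:
        means = np.nanmean(X, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    X = np.where(np.isnan(X), means[None, :], X)
    return X - means[None, :], means


class AncestryClassifier(BaseEstimator, ClassifierMixin):
    """2-PC projection + per-class bivariate Gaussian Bayes classifier.

    Parameters
    ----------
    covariance : {"full", "diag", "shared"}
        Class-conditional covariance structure. "full" (default) is the
        non-naive model; "diag" drops the PC correlation (the naive
        variant, for sensitivity checks); "shared" pools one covariance
        across classes (linear boundaries).
    priors : array-like or None
        Class priors; uniform when None.
    ridge : float
        Diagonal loading added when a class covariance is singular.

    Attributes (after fit)
    ----------------------
    classes_, snp_means_, pca_, class_means_, class_covs_, priors_
    """

    def __init__(self, covariance: str = "full", priors=None, ridge: float = 1e-6):
        self.covariance = covariance
        self.priors = priors
        self.ridge = ridge

    # -- projection ----------------------------------------------------
    def _project(self, X: np.ndarray) -> np.ndarray:
        Xc, _ = _impute_center(X, self.snp_means_)
        return Xc @ self.pca_components_.T

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("genotype matrix needs at least 2 SNPs")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if self.covariance not in ("full", "diag", "shared"):
            raise ValueError(f"unknown covariance structure {self.covariance!r}")

        Xc, self.snp_means_ = _impute_center(X)
        pca = PCA(n_components=2, svd_solver="full")
        proj = pca.fit_transform(Xc)
        if pca.n_components_ < 2:
            raise ValueError("genotype matrix has rank < 2")
        comps = pca.components_
        # deterministic sign: largest-magnitude loading positive
        for i in range(2):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
                proj[:, i] = -proj[:, i]
        self.pca_components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_

        self.classes_ = np.unique(y)
        means, covs = [], []
        for cls in self.classes_:
            pts = proj[y == cls]
            if len(pts) < 3:
                raise ValueError(f"class {cls!r} has fewer than 3 samples")
            means.append(pts.mean(axis=0))
            covs.append(np.cov(pts, rowvar=False, ddof=1))
        covs = np.array(covs)
        if self.covariance == "diag":
            covs = np.array([np.diag(np.diag(c)) for c in covs])
        elif self.covariance == "shared":
            pooled = covs.mean(axis=0)
            covs = np.array([pooled] * len(self.classes_))
        for i, c in enumerate(covs):
            if np.linalg.eigvalsh(c)[0] < self.ridge:
                logger.warning("class %s covariance near-singular; ridge added",
                               self.classes_[i])
                covs[i] = c + self.ridge * np.eye(2)
        self.class_means_ = np.array(means)
        self.class_covs_ = covs

        if self.priors is None:
            self.priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if len(self.priors_) != len(self.classes_):
                raise ValueError("priors length must match number of classes")
            self.priors_ = self.priors_ / self.priors_.sum()
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_components_")
        return self._project(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "class_means_")
        proj = self.transform(X)
        return self.posteriors_from_projection(proj)

    def posteriors_from_projection(self, proj: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "class_means_")
        logp = np.column_stack([
            multivariate_normal.logpdf(proj, mean=m, cov=c) + np.log(pr)
            for m, c, pr in zip(self.class_means_, self.class_covs_, self.priors_)
        ])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def pca_fit_project(genotypes) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 PCA of a genotype matrix: (projections, loadings).

    Mean-imputes missing dosages, centers, and applies the deterministic
    sign convention (largest-magnitude loading positive per component).
    """
    X = np.asarray(genotypes, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xc, _ = _impute_center(X)
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(Xc)
    comps = pca.components_
    for i in range(2):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            proj[:, i] = -proj[:, i]
    return proj, comps


def fit_bayes(projections, labels, priors=None, covariance: str = "full") -> AncestryClassifier:
    """Fit the Gaussian-class Bayes model on precomputed 2-D projections."""
    proj = np.asarray(projections, dtype=float)
    model = AncestryClassifier(covariance=covariance, priors=priors)
    # fit directly in projection space: identity "PCA"
    model.snp_means_ = np.zeros(proj.shape[1])
    model.pca_components_ = np.eye(2)
    y = np.asarray(labels)
    model.classes_ = np.unique(y)
    means, covs = [], []
    for cls in model.classes_:
        pts = proj[y == cls]
        if len(pts) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        means.append(pts.mean(axis=0))
        covs.append(np.cov(pts, rowvar=False, ddof=1))
    covs = np.array(covs)
    if covariance == "diag":
        covs = np.array([np.diag(np.diag(c)) for c in covs])
    elif covariance == "shared":
        covs = np.array([covs.mean(axis=0)] * len(model.classes_))
    for i, c in enumerate(covs):
        if np.linalg.eigvalsh(c)[0] < model.ridge:
            covs[i] = c + model.ridge * np.eye(2)
    model.class_means_ = np.array(means)
    model.class_covs_ = covs
    if priors is None:
        model.priors_ = np.full(len(model.classes_), 1.0 / len(model.classes_))
    else:
        model.priors_ = np.asarray(priors, dtype=float)
        model.priors_ = model.priors_ / model.priors_.sum()
    return model


def classify(model: AncestryClassifier, genotypes, declared=None) -> pd.DataFrame:
    """Per-sample posteriors, hard label and mismatch flag vs declared."""
    proba = model.predict_proba(genotypes)
    out = pd.DataFrame(proba, columns=[str(c) for c in model.classes_])
    out["label"] = model.classes_[np.argmax(proba, axis=1)]
    if declared is not None:
        declared = np.asarray(declared)
        out["declared"] = declared
        out["mismatch"] = out["label"].to_numpy() != declared
    return out
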