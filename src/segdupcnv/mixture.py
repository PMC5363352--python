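"""Copy-number calling: oriented first principal component and a univariate
Gaussian mixture with an additive cohort offset.

The summary statistic for copy number is the first principal component of
the mean-centered sample x probe log2-ratio matrix, with every probe
weighted equally. Its sign is fixed so that PC1 correlates *negatively*
with the per-sample mean log2 ratio: deletions score high, duplications
low, which makes "remove samples with PC1 above a threshold" a homozygous-
deletion filter.

Copy-number classes are then called from a k-component mixture

    y_i ~ Normal(mu_{z_i} + beta_{cohort(i)}, sd_{z_i}^2),

with the offset of the reference cohort fixed at zero. The cohort term
absorbs between-cohort intensity bias so that component boundaries are
shared across cohorts. The model is fitted by EM with coordinate-wise
M-steps (an ECM scheme: means, then offsets, then variances), which keeps
the observed-data log-likelihood non-decreasing; k-means initialization
with multiple restarts guards against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

_LOG_2PI = float(np.log(2.0 * np.pi))


class OrientedPC1(TransformerMixin, BaseEstimator):
    """First principal component with a fixed sign convention.

    Columns are mean-centered but not rescaled (equal probe weighting).
    After fitting, ``loadings_`` is the unit-norm probe-weight vector and
    ``orientation_`` records whether the raw PC1 was flipped to satisfy the
    deletions-high convention.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=2)
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        if np.allclose(centered, 0.0):
            warnings.warn("constant matrix: PC1 undefined, scores set to 0")
            self.loadings_ = np.zeros(X.shape[1])
            self.orientation_ = 1
            return self
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        loadings = vt[0]
        scores = centered @ loadings
        # deletions (low mean log2 ratio) must land at high PC1
        corr = float(np.dot(scores - scores.mean(), centered.mean(axis=1)))
        self.orientation_ = -1 if corr > 0 else 1
        self.loadings_ = loadings * self.orientation_
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        return (X - self.mean_) @ self.loadings_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class PCResult:
    scores: np.ndarray
    loadings: np.ndarray
    orientation: int


def pc_scores(matrix, probe_subset: Sequence[str] | None = None) -> PCResult:
    """Oriented PC1 scores of an intensity matrix (optionally probe-subset)."""
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        frame = matrix
    elif isinstance(getattr(matrix, "values", None), pd.DataFrame):
        frame = matrix.values  # IntensityMatrix
    else:
        frame = None
    if probe_subset is not None:
        if frame is None:
            raise TypeError("probe_subset requires a labelled matrix")
        frame = frame[list(probe_subset)]
    arr = np.asarray(frame if frame is not None else matrix, dtype=float)
    pc = OrientedPC1().fit(arr)
    return PCResult(
        scores=pc.transform(arr), loadings=pc.loadings_, orientation=pc.orientation_
    )


class CohortGaussianMixture(BaseEstimator):
    """Univariate Gaussian mixture with an additive cohort mean offset.

    Parameters
    ----------
    n_components : number of mixture components.
    n_init : number of EM restarts; the best log-likelihood wins.
    max_iter, tol : EM stopping rule (absolute log-likelihood gain).
    sd_floor : lower bound on component standard deviations, preventing
        degenerate single-point components.
    equal_var : pool a single variance across components.
    random_state : seed for the k-means initializations.

    Fitted attributes: ``means_``, ``sds_``, ``weights_`` (length k),
    ``cohort_offsets_`` (dict, reference cohort fixed at 0.0),
    ``responsibilities_``, ``loglik_trace_``, ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_components: int = 3,
        n_init: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        sd_floor: float = 1e-4,
        equal_var: bool = False,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.sd_floor = sd_floor
        self.equal_var = equal_var
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _log_resp(self, y, cohort_idx, means, sds, weights, betas):
        shift = betas[cohort_idx]  # per-sample offset
        z = (y[:, None] - shift[:, None] - means[None, :]) / sds[None, :]
        log_dens = (
            -0.5 * z**2 - np.log(sds)[None, :] - 0.5 * _LOG_2PI + np.log(weights)[None, :]
        )
        norm = logsumexp(log_dens, axis=1)
        return log_dens - norm[:, None], float(norm.sum())

    def _m_step(self, y, cohort_idx, resp, means, sds, betas, n_cohorts):
        nk = resp.sum(axis=0)
        adj = y - betas[cohort_idx]
        means = (resp * adj[:, None]).sum(axis=0) / nk
        if n_cohorts > 1:
            # precision-weighted offset update per non-reference cohort
            prec = resp / (sds**2)[None, :]
            resid = y[:, None] - means[None, :]
            num = (prec * resid).sum(axis=1)
            den = prec.sum(axis=1)
            for c in range(1, n_cohorts):
                sel = cohort_idx == c
                betas[c] = num[sel].sum() / den[sel].sum()
        centered = y[:, None] - betas[cohort_idx][:, None] - means[None, :]
        if self.equal_var:
            var = float((resp * centered**2).sum() / resp.sum())
            sds = np.full(self.n_components, np.sqrt(var))
        else:
            sds = np.sqrt((resp * centered**2).sum(axis=0) / nk)
        sds = np.maximum(sds, self.sd_floor)
        return means, sds, nk / len(y), betas

    def _run_em(self, y, cohort_idx, n_cohorts, init_seed):
        k = self.n_components
        if k == 1:
            init_means = np.array([y.mean()])
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=init_seed).fit(
                y.reshape(-1, 1)
            )
            init_means = np.sort(km.cluster_centers_.ravel())
        means = init_means.copy()
        spread = max(y.std(), self.sd_floor)
        sds = np.full(k, spread if k == 1 else max(spread / k, self.sd_floor))
        weights = np.full(k, 1.0 / k)
        betas = np.zeros(n_cohorts)

        trace: list[float] = []
        converged = False
        for _ in range(self.max_iter):
            log_resp, loglik = self._log_resp(y, cohort_idx, means, sds, weights, betas)
            trace.append(loglik)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break
            resp = np.exp(log_resp)
            means, sds, weights, betas = self._m_step(
                y, cohort_idx, resp, means, sds, betas, n_cohorts
            )
            if np.any(weights * len(y) < 1e-10):
                return None  # component collapse: signal a restart
        log_resp, loglik = self._log_resp(y, cohort_idx, means, sds, weights, betas)
        if trace and loglik >= trace[-1]:
            trace.append(loglik)
        return {
            "means": means,
            "sds": sds,
            "weights": weights,
            "betas": betas,
            "resp": np.exp(log_resp),
            "trace": np.array(trace),
            "converged": converged,
        }

    # -- estimator API -----------------------------------------------------

    def fit(self, y, cohort: Sequence[str] | None = None):
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < self.n_components:
            raise ValueError("need at least as many samples as components")
        if cohort is None:
            cohort = ["all"] * len(y)
        cohort = np.asarray([str(c) for c in cohort])
        if len(cohort) != len(y):
            raise ValueError("cohort labels must match the sample count")
        # first-seen cohort is the reference (offset fixed at zero)
        levels = list(dict.fromkeys(cohort))
        level_index = {c: i for i, c in enumerate(levels)}
        cohort_idx = np.array([level_index[c] for c in cohort])

        rng = np.random.default_rng(self.random_state)
        best = None
        failures = []
        for _ in range(max(1, self.n_init)):
            seed = int(rng.integers(2**31))
            result = self._run_em(y, cohort_idx, len(levels), seed)
            if result is None:
                failures.append(seed)
                continue
            if best is None or result["trace"][-1] > best["trace"][-1]:
                best = result
        if best is None:
            raise RuntimeError(
                f"all {self.n_init} EM restarts degenerated "
                f"(n={len(y)}, k={self.n_components}, seeds={failures})"
            )

        order = np.argsort(best["means"])
        self.means_ = best["means"][order]
        self.sds_ = best["sds"][order]
        self.weights_ = best["weights"][order]
        self.cohort_offsets_ = {c: float(best["betas"][level_index[c]]) for c in levels}
        self.reference_cohort_ = levels[0]
        self.responsibilities_ = best["resp"][:, order]
        self.loglik_trace_ = best["trace"]
        self.converged_ = best["converged"]
        self.n_iter_ = len(best["trace"])
        self._levels = levels
        return self

    def n_parameters(self) -> int:
        check_is_fitted(self, "means_")
        k = self.n_components
        n_sds = 1 if self.equal_var else k
        return k + n_sds + (k - 1) + (len(self._levels) - 1)

    def bic(self) -> float:
        """Bayesian information criterion of the fit (lower is better)."""
        check_is_fitted(self, "means_")
        n = self.responsibilities_.shape[0]
        return -2.0 * float(self.loglik_trace_[-1]) + self.n_parameters() * np.log(n)

    def predict_proba(self, y, cohort: Sequence[str] | None = None) -> np.ndarray:
        check_is_fitted(self, "means_")
        y = np.asarray(y, dtype=float).ravel()
        if cohort is None:
            cohort = [self.reference_cohort_] * len(y)
        betas = np.array(
            [self.cohort_offsets_.get(str(c), 0.0) for c in cohort]
        )
        z = (y[:, None] - betas[:, None] - self.means_[None, :]) / self.sds_[None, :]
        log_dens = (
            -0.5 * z**2
            - np.log(self.sds_)[None, :]
            - 0.5 * _LOG_2PI
            + np.log(self.weights_)[None, :]
        )
        return np.exp(log_dens - logsumexp(log_dens, axis=1)[:, None])

    def predict(self, y, cohort: Sequence[str] | None = None) -> np.ndarray:
        return np.argmax(self.predict_proba(y, cohort), axis=1)


# Thin functional surface ----------------------------------------------------

def fit_gaussian_mixture(
    values: Sequence[float],
    k: int,
    cohort: Sequence[str] | None = None,
    seed: int | None = None,
    **kwargs,
) -> CohortGaussianMixture:
    """Fit the cohort-adjusted mixture and return the fitted estimator."""
    return CohortGaussianMixture(n_components=k, random_state=seed, **kwargs).fit(
        values, cohort
    )


CopyClass = Literal["loss", "normal", "gain"]


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    copy_class: CopyClass
    posterior: float
    uncertain: bool


def call_copy_number(
    fit: CohortGaussianMixture,
    sample_ids: Sequence[str],
    min_posterior: float = 0.5,
) -> list[CopyNumberCall]:
    """Loss/normal/gain calls from a fitted 3-component mixture.

    Components are ranked by mean on the oriented PC1 scale: the highest
    mean is the loss class (deletions score high by the sign convention),
    the lowest is gain. Calls with posterior below ``min_posterior`` are
    flagged uncertain.
    """
    check_is_fitted(fit, "means_")
    if fit.n_components != 3:
        raise ValueError("copy-number calling requires a 3-component fit")
    resp = fit.responsibilities_
    if len(sample_ids) != resp.shape[0]:
        raise ValueError("sample_ids must match the fitted data")
    # means_ is sorted ascending: index 0 = lowest mean = gain, 2 = loss
    class_of = {0: "gain", 1: "normal", 2: "loss"}
    calls = []
    for i, sid in enumerate(sample_ids):
        j = int(np.argmax(resp[i]))
        post = float(resp[i, j])
        calls.append(
            CopyNumberCall(
                sample_id=sid,
                copy_class=class_of[j],  # type: ignore[arg-type]
                posterior=post,
                uncertain=post < min_posterior,
            )
        )
    return calls
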