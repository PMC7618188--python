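"""Marginal predictive value of candidate regions via Bayesian regression.

Given per-patient binary damage matrices restricted to candidate regions
(e.g. the SBM-inferred critical region vs a meta-analytically defined ROI),
each region's matrix is reduced to a few principal components, a Bayesian
linear regression with a Zellner g-prior predicts the behavioural score
from those components, and candidates are ranked by the Widely Applicable
Information Criterion, ``WAIC = -2 (lppd - p_waic)`` (smaller is better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .imaging import ROI, Volume
from .synthetic_cohort import LesionCohort


@dataclass(frozen=True)
class RegionMatrix:
    """Patients x voxels binary damage matrix restricted to one region."""

    data: np.ndarray
    patient_ids: tuple[str, ...]
    voxels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("region matrix entries must be binary")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def _region_voxels(region, shape) -> np.ndarray:
    if isinstance(region, ROI):
        return np.ravel_multi_index(tuple(region.voxels.T), shape)
    if isinstance(region, Volume):
        region = region.data
    region = np.asarray(region)
    if region.shape != tuple(shape):
        raise ValueError("region grid does not match mask grid")
    return np.flatnonzero(region != 0)


def extract_region_matrix(
    cohort: LesionCohort | list[np.ndarray],
    region,
    patient_ids: list[str] | None = None,
    name: str = "",
) -> RegionMatrix:
    """Binary damage matrix: entry (k, v) = 1 iff patient k lesions voxel v."""
    if isinstance(cohort, LesionCohort):
        masks = cohort.masks()
        ids = [p.id for p in cohort.patients]
    else:
        masks = list(cohort)
        ids = patient_ids or [f"sub-{k:04d}" for k in range(len(masks))]
    if not masks:
        raise ValueError("no patients")
    shape = np.asarray(masks[0]).shape
    voxels = _region_voxels(region, shape)
    if len(voxels) == 0:
        raise ValueError("region is empty")
    rows = np.stack([np.asarray(m).astype(bool).ravel()[voxels] for m in masks])
    if not rows.any():
        raise ValueError("region is disjoint from every lesion: nothing to model")
    return RegionMatrix(
        data=rows.astype(np.uint8), patient_ids=tuple(ids), voxels=voxels, name=name
    )


def pca_reduce(matrix: RegionMatrix | np.ndarray, k: int = 5) -> tuple[np.ndarray, float]:
    """Column-centred PCA to ``k`` components.

    Returns the patient scores (n x k, zero-padded beyond the matrix rank)
    and the fraction of total variance the returned components capture.
    """
    X = matrix.data if isinstance(matrix, RegionMatrix) else np.asarray(matrix)
    X = X.astype(float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} patients for {k} components")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < 1:
        raise ValueError("region matrix has rank 0 (all columns constant)")
    n_comp = min(k, rank, n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xc)
    if n_comp < k:
        scores = np.hstack([scores, np.zeros((n, k - n_comp))])
    return scores, float(pca.explained_variance_ratio_.sum())


@dataclass
class GPriorFit:
    """Posterior samples from the g-prior Gaussian regression.

    ``loglik`` is the per-sample per-observation log-likelihood matrix
    (samples x patients) consumed by :func:`waic`.
    """

    loglik: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    g: float
    seed: int

    @property
    def coef_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def effective_sample_size(self) -> float:
        # crude lag-1 autocorrelation ESS on sigma2 (single-chain sanity check)
        x = self.sigma2 - self.sigma2.mean()
        if len(x) < 3 or x.std() == 0:
            return float(len(x))
        rho = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        rho = min(max(rho, -0.999), 0.999)
        return float(len(x) * (1 - rho) / (1 + rho))


def fit_gprior_regression(
    X: np.ndarray,
    y: np.ndarray,
    g: float | None = None,
    n_samples: int = 10_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> GPriorFit:
    """Gaussian linear regression with a Zellner g-prior, by single-chain MCMC.

    Model: ``y = alpha + X beta + eps``, ``eps ~ N(0, sigma^2)``; prior
    ``beta | sigma^2 ~ N(0, g sigma^2 (X'X)^{-1})`` with a flat prior on the
    intercept (excluded from shrinkage) and Jeffreys prior on ``sigma^2``.
    ``g`` defaults to ``n`` (unit-information prior).  A Gibbs sampler runs
    ``burn_in + n_samples`` iterations; the returned per-observation
    log-likelihoods feed WAIC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant columns are not identifiable under the g-prior")
    g = float(n) if g is None else float(g)

    Xc = X - X.mean(axis=0)
    xtx = Xc.T @ Xc
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular design after centring") from err
    shrink = g / (g + 1.0)
    chol = np.linalg.cholesky(xtx_inv * shrink)

    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    alpha = float(y.mean())
    sigma2 = float(y.var()) or 1.0

    alphas = np.empty(n_samples)
    betas = np.empty((n_samples, p))
    sigma2s = np.empty(n_samples)
    beta_hat = shrink * (xtx_inv @ (Xc.T @ (y - y.mean())))

    total = burn_in + n_samples
    for it in range(total):
        # alpha | beta, sigma2  (Xc centred, so the conditional mean is ybar)
        alpha = rng.normal(y.mean(), np.sqrt(sigma2 / n))
        # beta | alpha, sigma2
        mean_b = shrink * (xtx_inv @ (Xc.T @ (y - alpha)))
        beta = mean_b + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
        # sigma2 | alpha, beta
        resid = y - alpha - Xc @ beta
        a_post = 0.5 * (n + p)
        b_post = 0.5 * (resid @ resid + (beta @ xtx @ beta) / g)
        sigma2 = b_post / rng.gamma(a_post)
        if it >= burn_in:
            j = it - burn_in
            alphas[j] = alpha
            betas[j] = beta
            sigma2s[j] = sigma2

    mu = alphas[:, None] + betas @ Xc.T
    loglik = (
        -0.5 * np.log(2 * np.pi * sigma2s)[:, None]
        - 0.5 * (y[None, :] - mu) ** 2 / sigma2s[:, None]
    )
    del beta_hat
    return GPriorFit(
        loglik=loglik, alpha=alphas, beta=betas, sigma2=sigma2s, g=g, seed=seed
    )


def waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC decomposition from a samples x observations log-likelihood matrix.

    ``lppd = sum_i log mean_s exp(ll_si)``; ``p_waic = sum_i var_s(ll_si)``;
    ``waic = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a 2D log-likelihood matrix with >= 2 samples")
    if not np.isfinite(ll).all():
        raise ValueError("non-finite log-likelihoods")
    s = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - np.log(s)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), lppd, p_waic


@dataclass
class ModelComparison:
    """Ranked WAIC comparison of candidate region models."""

    table: pd.DataFrame
    best: str
    tie: bool = False

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank")["name"])


def rank_waics(waics: dict[str, float]) -> ModelComparison:
    """Rank precomputed WAIC values ascending (smaller is better)."""
    names = list(waics)
    values = np.array([waics[n] for n in names])
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(names), dtype=int)
    ranks[order] = np.arange(1, len(names) + 1)
    table = pd.DataFrame({"name": names, "waic": values, "rank": ranks})
    best = names[int(order[0])]
    tie = len(values) > 1 and np.isclose(np.sort(values)[0], np.sort(values)[1])
    return ModelComparison(table=table, best=best, tie=tie)


def compare_models(
    candidates: list[tuple[str, np.ndarray]],
    y: np.ndarray,
    g: float | None = None,
    n_samples: int = 10_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> ModelComparison:
    """Fit every candidate design on the same scores and rank by WAIC.

    Each candidate is fitted with the same seed and the same prior policy
    (``g = n`` unless given).  Ties are broken by declared order and
    flagged.  The table records WAIC, lppd and p_waic per candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    rows = []
    for name, X in candidates:
        try:
            fit = fit_gprior_regression(
                X, y, g=g, n_samples=n_samples, burn_in=burn_in, seed=seed
            )
        except Exception as err:
            raise RuntimeError(f"candidate {name!r} failed to fit: {err}") from err
        w, lppd, p_w = waic(fit.loglik)
        rows.append(
            {"name": name, "waic": w, "lppd": lppd, "p_waic": p_w,
             "n_samples": fit.loglik.shape[0], "n_obs": fit.loglik.shape[1]}
        )
    table = pd.DataFrame(rows)
    order = np.argsort(table["waic"].values, kind="stable")
    ranks = np.empty(len(rows), dtype=int)
    ranks[order] = np.arange(1, len(rows) + 1)
    table["rank"] = ranks
    waic_sorted = np.sort(table["waic"].values)
    tie = bool(np.isclose(waic_sorted[0], waic_sorted[1]))
    return ModelComparison(table=table, best=table.loc[int(order[0]), "name"], tie=tie)
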