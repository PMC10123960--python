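"""Univariate BayesC: spike-and-slab whole-genome regression by Gibbs sampling.

Model for plot-level phenotypes

    y_kli = mu + r_k + b_l(k) + sum_j w_ij alpha_j + eps_kli

with flat priors on the fixed effects (intercept, replication, block nested
in replication), marker effects alpha_j that are exactly zero with
probability pi and N(0, sigma^2_alpha) otherwise (pi is fixed, never
estimated), and scaled inverse-chi^2 priors on both variances with nu
degrees of freedom and scales chosen so each prior variance mean equals
``variance_partition`` times the phenotypic variance.  Marker covariates
are the raw 0/1/2 dosages.

Per retained draw the genomic variance sigma^2_g is the empirical variance
of W alpha across plots; genomic heritability is
sigma^2_g / (sigma^2_g + sigma^2_eps / nr) with nr the replication count.
The posterior inclusion probability (PIP) of a marker is the fraction of
retained draws in which its effect is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._kernels import sweep_univariate
from .design import DesignSpec, resolve_design
from .diagnostics import diagnostics


def genomic_heritability(sigma2_g: float, sigma2_e: float, nr: int) -> float:
    """h2 = sigma2_g / (sigma2_g + sigma2_e / nr).

    The residual variance is divided by the replication count because the
    genetic signal acts on line means over nr replicated plots.
    """
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variances must be nonnegative")
    if nr < 1:
        raise ValueError("nr must be >= 1")
    denom = sigma2_g + sigma2_e / nr
    if denom == 0.0:
        raise ValueError("heritability undefined: both variances are zero")
    return sigma2_g / denom


@dataclass
class BayesCConfig:
    """Prior and chain settings for the univariate sampler."""

    pi: float = 0.99
    prior_df: float = 4.0
    variance_partition: float = 0.5
    n_iter: int = 60_000
    burn_in: int = 6_000
    thin: int = 60
    seed: int = 0
    n_rep_for_h2: int = 2

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.prior_df <= 2.0:
            raise ValueError("prior_df must exceed 2 (prior mean must exist)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means, PIPs, retained draws and diagnostics of one fit."""

    post_mean_alpha: np.ndarray
    pip: np.ndarray
    post_mean_sigma2_alpha: float
    post_mean_sigma2_g: float
    post_mean_sigma2_eps: float
    h2: float
    h2_ci: tuple[float, float]
    h2_from_mean_variances: float
    fixed_effects: dict
    retained_samples: dict = field(default_factory=dict)
    marker_ids: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained_samples["sigma2_eps"])

    def diagnostics(self, outdir=None) -> pd.DataFrame:
        scalar = {k: v for k, v in self.retained_samples.items()
                  if np.ndim(v) == 1}
        return diagnostics(scalar, outdir=outdir)

    def effects_frame(self, chrom=None, pos_bp=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "marker_id": self.marker_ids if self.marker_ids is not None
            else np.arange(self.pip.size),
            "post_mean_alpha": self.post_mean_alpha,
            "pip": self.pip,
        })
        if chrom is not None:
            df.insert(1, "chrom", chrom)
        if pos_bp is not None:
            df.insert(2, "pos_bp", pos_bp)
        return df

    def variances_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "sigma2_alpha": self.post_mean_sigma2_alpha,
                "sigma2_g": self.post_mean_sigma2_g,
                "sigma2_eps": self.post_mean_sigma2_eps,
                "h2": self.h2,
                "h2_ci": list(self.h2_ci),
                "h2_from_mean_variances": self.h2_from_mean_variances,
                "fixed_effects": self.fixed_effects,
            }, fh, indent=2)


class BayesCRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for univariate BayesC.

    Parameters mirror :class:`BayesCConfig`; ``fix_sigma2_alpha`` /
    ``fix_sigma2_eps`` disable variance sampling (used by the conjugate and
    ridge-limit checks).  ``design`` is passed to :meth:`fit`: a
    :class:`DesignSpec`, a ready design matrix, ``None`` (intercept only) or
    ``False`` (no fixed effects, known zero mean).

    Attributes (after fit)
    ----------------------
    coef_ : posterior mean marker effects
    pip_ : posterior inclusion probabilities
    sigma2_alpha_, sigma2_g_, sigma2_eps_ : posterior mean variances
    h2_ : posterior mean of the per-draw heritability ratio (headline);
        ``h2_from_mean_variances_`` applies the ratio to posterior means
    samples_ : dict of retained thinned post-burn-in draws
    """

    def __init__(self, pi=0.99, prior_df=4.0, variance_partition=0.5,
                 n_iter=60_000, burn_in=6_000, thin=60, n_rep_for_h2=2,
                 fix_sigma2_alpha=None, fix_sigma2_eps=None,
                 store_effect_samples=False, random_state=0):
        self.pi = pi
        self.prior_df = prior_df
        self.variance_partition = variance_partition
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_rep_for_h2 = n_rep_for_h2
        self.fix_sigma2_alpha = fix_sigma2_alpha
        self.fix_sigma2_eps = fix_sigma2_eps
        self.store_effect_samples = store_effect_samples
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, design=None):
        cfg = BayesCConfig(pi=self.pi, prior_df=self.prior_df,
                           variance_partition=self.variance_partition,
                           n_iter=self.n_iter, burn_in=self.burn_in,
                           thin=self.thin, seed=0,
                           n_rep_for_h2=self.n_rep_for_h2)
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be n_plots × n_markers matching y")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype values")
        if np.isnan(X).any():
            raise ValueError("missing dosages; impute before fitting")
        n, m = X.shape
        rng = np.random.default_rng(self.random_state)

        Xd, names = resolve_design(design, n)
        if Xd is not None:
            XtX = Xd.T @ Xd
            Lchol = np.linalg.cholesky(XtX)
        WT = np.ascontiguousarray(X.T)
        c = np.einsum("ij,ij->j", X, X)

        vary = y.var()
        if vary == 0.0:
            raise ValueError("phenotype has zero variance")
        nu = self.prior_df
        S_eps = self.variance_partition * vary * (nu - 2.0) / nu
        p_freq = X.mean(axis=0) / 2.0
        sumvar = float(np.sum(2.0 * p_freq * (1.0 - p_freq)))
        incl = max(1.0 - self.pi, 1e-4)
        E_sa = self.variance_partition * vary / (incl * max(sumvar, 1e-8))
        S_a = E_sa * (nu - 2.0) / nu

        with np.errstate(divide="ignore"):
            log_prior_ratio = float(np.log(max(1.0 - self.pi, 0.0))
                                    - np.log(max(self.pi, 0.0))) \
                if 0.0 < self.pi < 1.0 else (np.inf if self.pi == 0.0 else -np.inf)

        s2e = (self.fix_sigma2_eps if self.fix_sigma2_eps is not None
               else self.variance_partition * vary)
        s2a = (self.fix_sigma2_alpha if self.fix_sigma2_alpha is not None
               else E_sa)
        alpha = np.zeros(m)
        delta = np.zeros(m, dtype=np.int8)
        b = np.zeros(Xd.shape[1]) if Xd is not None else None
        e = y.copy()

        n_ret = (self.n_iter - self.burn_in) // self.thin
        keep = {
            "sigma2_alpha": np.empty(n_ret), "sigma2_eps": np.empty(n_ret),
            "sigma2_g": np.empty(n_ret), "h2": np.empty(n_ret),
            "n_included": np.empty(n_ret),
        }
        if Xd is not None:
            keep["fixed"] = np.empty((n_ret, Xd.shape[1]))
        if self.store_effect_samples:
            keep["alpha"] = np.empty((n_ret, m))
            keep["delta"] = np.empty((n_ret, m), dtype=np.int8)
        pip_acc = np.zeros(m)
        alpha_acc = np.zeros(m)
        r = 0

        for it in range(1, self.n_iter + 1):
            if Xd is not None:
                e += Xd @ b
                bhat = np.linalg.solve(XtX, Xd.T @ e)
                b = bhat + np.sqrt(s2e) * np.linalg.solve(Lchol.T,
                                                          rng.standard_normal(len(b)))
                e -= Xd @ b
            if m:
                k, ssq = sweep_univariate(
                    WT, e, alpha, delta, c, s2a, s2e, log_prior_ratio,
                    rng.random(m), rng.standard_normal(m))
            else:
                k, ssq = 0, 0.0
            if self.fix_sigma2_alpha is None:
                s2a = (nu * S_a + ssq) / rng.chisquare(nu + k)
            if self.fix_sigma2_eps is None:
                s2e = (nu * S_eps + e @ e) / rng.chisquare(nu + n)

            if it > self.burn_in and (it - self.burn_in) % self.thin == 0:
                g = X @ alpha if m else np.zeros(n)
                s2g = float(g.var())
                keep["sigma2_alpha"][r] = s2a
                keep["sigma2_eps"][r] = s2e
                keep["sigma2_g"][r] = s2g
                keep["h2"][r] = genomic_heritability(s2g, s2e, self.n_rep_for_h2) \
                    if (s2g + s2e) > 0 else 0.0
                keep["n_included"][r] = k
                if Xd is not None:
                    keep["fixed"][r] = b
                if self.store_effect_samples:
                    keep["alpha"][r] = alpha
                    keep["delta"][r] = delta
                pip_acc += delta
                alpha_acc += alpha
                r += 1

        assert r == n_ret
        self.coef_ = alpha_acc / n_ret
        self.pip_ = pip_acc / n_ret
        self.sigma2_alpha_ = float(keep["sigma2_alpha"].mean())
        self.sigma2_eps_ = float(keep["sigma2_eps"].mean())
        self.sigma2_g_ = float(keep["sigma2_g"].mean())
        self.h2_ = float(keep["h2"].mean())
        self.h2_ci_ = tuple(np.quantile(keep["h2"], [0.025, 0.975]))
        self.h2_from_mean_variances_ = genomic_heritability(
            self.sigma2_g_, self.sigma2_eps_, self.n_rep_for_h2)
        self.fixed_effect_names_ = names
        self.fixed_effects_ = (
            dict(zip(names, keep["fixed"].mean(axis=0))) if Xd is not None else {})
        self.samples_ = keep
        self.n_features_in_ = m
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        mu = self.fixed_effects_.get("mu", 0.0)
        return mu + X @ self.coef_

    def summary_(self, marker_ids=None) -> PosteriorSummary:
        return PosteriorSummary(
            post_mean_alpha=self.coef_, pip=self.pip_,
            post_mean_sigma2_alpha=self.sigma2_alpha_,
            post_mean_sigma2_g=self.sigma2_g_,
            post_mean_sigma2_eps=self.sigma2_eps_,
            h2=self.h2_, h2_ci=self.h2_ci_,
            h2_from_mean_variances=self.h2_from_mean_variances_,
            fixed_effects=self.fixed_effects_,
            retained_samples=self.samples_,
            marker_ids=marker_ids)


def fit_bayesc(y, design, G, config: BayesCConfig | None = None,
               line_ids=None, **kwargs) -> PosteriorSummary:
    """Functional wrapper: fit univariate BayesC on a phenotype vector.

    ``G`` is a :class:`~specgwas.genotypes.GenotypeMatrix` (with ``line_ids``
    mapping plots to lines) or a ready plot × marker array.  ``design`` as in
    :class:`BayesCRegressor.fit`.
    """
    if config is None:
        config = BayesCConfig(**kwargs)
    X, marker_ids = _expand_genotypes(G, line_ids, len(np.ravel(y)))
    est = BayesCRegressor(
        pi=config.pi, prior_df=config.prior_df,
        variance_partition=config.variance_partition, n_iter=config.n_iter,
        burn_in=config.burn_in, thin=config.thin,
        n_rep_for_h2=config.n_rep_for_h2, random_state=config.seed)
    est.fit(X, y, design=design)
    return est.summary_(marker_ids=marker_ids)


def _expand_genotypes(G, line_ids, n_plots):
    from ..genotypes import GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        if line_ids is None:
            if G.n_lines != n_plots:
                raise ValueError("provide line_ids to map plots onto lines")
            return G.dosages, G.marker_ids
        index = {lid: i for i, lid in enumerate(G.line_ids)}
        rows = [index[lid] for lid in line_ids]
        return G.dosages[rows], G.marker_ids
    return np.asarray(G, dtype=float), None
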