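"""Bivariate BayesC: two-trait spike-and-slab regression with correlated
marker effects and residuals.

The marker effect for locus j is reparameterized as alpha_j = D_j beta_j,
where D_j is diagonal with per-trait inclusion indicators
delta_j = (delta_j1, delta_j2) and beta_j ~ N_2(0, Sigma_alpha).  All four
indicator categories (0,0), (0,1), (1,0), (1,1) carry prior mass (by default
the product of independent per-trait inclusion probabilities).  Residual
rows are i.i.d. N_2(0, Sigma_eps).  Both covariance matrices take inverse-
Wishart priors whose means equal ``variance_partition`` times the diagonal
phenotypic (co)variance.

The genomic correlation between the traits is summarized per retained draw
as the Pearson correlation of the two genetic-value vectors W alpha_t
(draws in which either vector is constant are skipped and counted); the
corresponding Sigma_alpha-based correlation is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from ._kernels import sweep_bivariate
from .design import resolve_design
from .univariate import genomic_heritability

log = logging.getLogger(__name__)

#: spec order of the indicator categories in ``delta_prior``
DELTA_CATEGORIES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class BivariateConfig:
    """Priors and chain settings for the two-trait sampler."""

    pi_t: tuple[float, float] = (0.99, 0.99)
    delta_prior: tuple[float, float, float, float] | None = None
    wishart_df: float = 4.0
    variance_partition: float = 0.5
    n_iter: int = 60_000
    burn_in: int = 6_000
    thin: int = 60
    seed: int = 0
    n_rep_for_h2: int = 2

    def __post_init__(self):
        if self.delta_prior is None:
            p1, p2 = (1.0 - self.pi_t[0]), (1.0 - self.pi_t[1])
            self.delta_prior = ((1 - p1) * (1 - p2), (1 - p1) * p2,
                                p1 * (1 - p2), p1 * p2)
        dp = np.asarray(self.delta_prior, dtype=float)
        if dp.shape != (4,) or not np.isclose(dp.sum(), 1.0):
            raise ValueError("delta_prior must be 4 probabilities summing to 1")
        if self.wishart_df <= 3.0:
            raise ValueError("wishart_df must exceed dimension + 1 = 3")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")


@dataclass
class BivariatePosterior:
    post_mean_Sigma_alpha: np.ndarray
    post_mean_Sigma_eps: np.ndarray
    genomic_correlation: float
    genomic_correlation_ci: tuple[float, float]
    genomic_correlation_from_Sigma: float
    h2: tuple[float, float]
    pip: np.ndarray                    # m × 2
    category_freqs: np.ndarray         # m × 4, spec category order
    post_mean_alpha: np.ndarray        # m × 2
    retained_samples: dict = field(default_factory=dict)
    n_rg_skipped: int = 0
    n_jitter_retries: int = 0
    marker_ids: np.ndarray | None = None


def genomic_correlation_from_draws(genetic_values_draws: np.ndarray) -> dict:
    """Mean and central 95% interval of per-draw Pearson correlations.

    ``genetic_values_draws`` has shape (draws, lines, 2).  Draws in which
    either trait's genetic values are constant are skipped and counted.
    """
    gv = np.asarray(genetic_values_draws, dtype=float)
    if gv.ndim != 3 or gv.shape[0] < 10:
        raise ValueError("need >= 10 draws of line × 2 genetic values")
    rs, skipped = [], 0
    for d in range(gv.shape[0]):
        s1, s2 = gv[d, :, 0].std(), gv[d, :, 1].std()
        if s1 == 0.0 or s2 == 0.0:
            skipped += 1
            continue
        rs.append(np.corrcoef(gv[d, :, 0], gv[d, :, 1])[0, 1])
    if skipped:
        log.warning("genomic correlation: skipped %d degenerate draws", skipped)
    if not rs:
        return {"mean": float("nan"), "ci": (float("nan"), float("nan")),
                "n_skipped": skipped}
    rs = np.asarray(rs)
    lo, hi = np.quantile(rs, [0.025, 0.975])
    return {"mean": float(rs.mean()), "ci": (float(lo), float(hi)),
            "n_skipped": skipped}


class BivariateBayesC(BaseEstimator):
    """Scikit-learn style estimator for the two-trait sampler.

    ``fit(X, Y, design=...)`` with X the plot × marker dosage matrix and Y a
    plot × 2 phenotype matrix (both complete).  Fitted attributes include
    ``Sigma_alpha_``, ``Sigma_eps_``, ``genomic_correlation_``, ``pip_``
    (m × 2), ``category_freqs_`` (m × 4, category order (0,0), (0,1), (1,0),
    (1,1)) and ``h2_`` per trait.
    """

    def __init__(self, pi_t=(0.99, 0.99), delta_prior=None, wishart_df=4.0,
                 variance_partition=0.5, n_iter=60_000, burn_in=6_000,
                 thin=60, n_rep_for_h2=2, random_state=0):
        self.pi_t = pi_t
        self.delta_prior = delta_prior
        self.wishart_df = wishart_df
        self.variance_partition = variance_partition
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_rep_for_h2 = n_rep_for_h2
        self.random_state = random_state

    def fit(self, X, Y, design=None):
        cfg = BivariateConfig(
            pi_t=tuple(self.pi_t), delta_prior=self.delta_prior,
            wishart_df=self.wishart_df,
            variance_partition=self.variance_partition, n_iter=self.n_iter,
            burn_in=self.burn_in, thin=self.thin,
            n_rep_for_h2=self.n_rep_for_h2)
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be plot × 2")
        if not np.all(np.isfinite(Y)):
            raise ValueError("both phenotype columns must be complete")
        n, m = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        rng = np.random.default_rng(self.random_state)
        nu = self.wishart_df
        vp = self.variance_partition

        Xd, names = resolve_design(design, n)
        if Xd is not None:
            XtX = Xd.T @ Xd
            XtX_inv_chol = np.linalg.cholesky(np.linalg.inv(XtX))
        WT = np.ascontiguousarray(X.T)
        c = np.einsum("ij,ij->j", X, X)

        vary = Y.var(axis=0)
        p_freq = X.mean(axis=0) / 2.0
        sumvar = max(float(np.sum(2.0 * p_freq * (1.0 - p_freq))), 1e-8)
        incl = np.maximum(1.0 - np.asarray(cfg.pi_t), 1e-4)
        # IW(S, nu) has mean S / (nu - dim - 1); dim = 2
        Sa_prior = np.diag(vp * vary / (incl * sumvar)) * (nu - 3.0)
        Se_prior = np.diag(vp * vary) * (nu - 3.0)

        dp = np.maximum(np.asarray(cfg.delta_prior, dtype=float), 1e-300)
        # spec order (00, 01, 10, 11) -> kernel order (00, 10, 01, 11)
        lp = np.log(dp[[0, 2, 1, 3]])

        Sig_a = np.diag(vp * vary / (incl * sumvar))
        Sig_e = np.diag(vp * vary)
        alpha = np.zeros((m, 2))
        cat = np.zeros(m, dtype=np.int8)
        B = np.zeros((Xd.shape[1], 2)) if Xd is not None else None
        E = Y.copy(order="F")
        E0 = np.ascontiguousarray(E[:, 0])
        E1 = np.ascontiguousarray(E[:, 1])

        n_ret = (self.n_iter - self.burn_in) // self.thin
        keep = {
            "Sigma_alpha_11": np.empty(n_ret), "Sigma_alpha_12": np.empty(n_ret),
            "Sigma_alpha_22": np.empty(n_ret),
            "Sigma_eps_11": np.empty(n_ret), "Sigma_eps_12": np.empty(n_ret),
            "Sigma_eps_22": np.empty(n_ret),
            "rg_genetic_values": np.empty(n_ret),
            "rg_from_Sigma": np.empty(n_ret),
            "h2_trait1": np.empty(n_ret), "h2_trait2": np.empty(n_ret),
        }
        cat_counts = np.zeros((m, 4))
        alpha_acc = np.zeros((m, 2))
        r_idx = 0
        n_skipped = 0
        jitters = 0

        for it in range(1, self.n_iter + 1):
            if Xd is not None:
                E += Xd @ B
                Bhat = np.linalg.solve(XtX, Xd.T @ E)
                Z = rng.standard_normal(B.shape)
                B = Bhat + XtX_inv_chol @ Z @ np.linalg.cholesky(Sig_e).T
                E -= Xd @ B
            E0[:] = E[:, 0]
            E1[:] = E[:, 1]
            Ri = np.linalg.inv(Sig_e)
            scatter = np.zeros((2, 2))
            k = sweep_bivariate(
                WT, E0, E1, alpha, cat, c,
                Ri[0, 0], Ri[0, 1], Ri[1, 1],
                Sig_a[0, 0], Sig_a[0, 1], Sig_a[1, 1],
                lp[0], lp[1], lp[2], lp[3],
                rng.random(m), rng.standard_normal((m, 2)), scatter)
            E[:, 0] = E0
            E[:, 1] = E1

            Sig_a, j1 = _draw_iw(rng, nu + k, Sa_prior + scatter)
            Sig_e, j2 = _draw_iw(rng, nu + n, Se_prior + E.T @ E)
            jitters += j1 + j2

            if it > self.burn_in and (it - self.burn_in) % self.thin == 0:
                g1 = X @ alpha[:, 0]
                g2 = X @ alpha[:, 1]
                v1, v2 = g1.var(), g2.var()
                if v1 > 0 and v2 > 0:
                    keep["rg_genetic_values"][r_idx] = np.corrcoef(g1, g2)[0, 1]
                else:
                    keep["rg_genetic_values"][r_idx] = np.nan
                    n_skipped += 1
                keep["rg_from_Sigma"][r_idx] = Sig_a[0, 1] / np.sqrt(
                    Sig_a[0, 0] * Sig_a[1, 1])
                keep["Sigma_alpha_11"][r_idx] = Sig_a[0, 0]
                keep["Sigma_alpha_12"][r_idx] = Sig_a[0, 1]
                keep["Sigma_alpha_22"][r_idx] = Sig_a[1, 1]
                keep["Sigma_eps_11"][r_idx] = Sig_e[0, 0]
                keep["Sigma_eps_12"][r_idx] = Sig_e[0, 1]
                keep["Sigma_eps_22"][r_idx] = Sig_e[1, 1]
                keep["h2_trait1"][r_idx] = genomic_heritability(
                    v1, Sig_e[0, 0], self.n_rep_for_h2)
                keep["h2_trait2"][r_idx] = genomic_heritability(
                    v2, Sig_e[1, 1], self.n_rep_for_h2)
                # kernel order -> spec order for reporting
                cat_counts[np.arange(m), _KERNEL_TO_SPEC[cat]] += 1
                alpha_acc += alpha
                r_idx += 1

        rg = keep["rg_genetic_values"]
        rg_ok = rg[np.isfinite(rg)]
        self.Sigma_alpha_ = np.array(
            [[keep["Sigma_alpha_11"].mean(), keep["Sigma_alpha_12"].mean()],
             [keep["Sigma_alpha_12"].mean(), keep["Sigma_alpha_22"].mean()]])
        self.Sigma_eps_ = np.array(
            [[keep["Sigma_eps_11"].mean(), keep["Sigma_eps_12"].mean()],
             [keep["Sigma_eps_12"].mean(), keep["Sigma_eps_22"].mean()]])
        self.genomic_correlation_ = float(rg_ok.mean()) if rg_ok.size else float("nan")
        self.genomic_correlation_ci_ = (
            tuple(np.quantile(rg_ok, [0.025, 0.975])) if rg_ok.size
            else (float("nan"),) * 2)
        self.genomic_correlation_from_Sigma_ = float(
            keep["rg_from_Sigma"].mean())
        self.h2_ = (float(keep["h2_trait1"].mean()),
                    float(keep["h2_trait2"].mean()))
        self.category_freqs_ = cat_counts / n_ret
        self.pip_ = np.column_stack([
            self.category_freqs_[:, 2] + self.category_freqs_[:, 3],
            self.category_freqs_[:, 1] + self.category_freqs_[:, 3]])
        self.coef_ = alpha_acc / n_ret
        self.samples_ = keep
        self.n_rg_skipped_ = n_skipped
        self.n_jitter_retries_ = jitters
        self.n_features_in_ = m
        return self

    def summary_(self, marker_ids=None) -> BivariatePosterior:
        return BivariatePosterior(
            post_mean_Sigma_alpha=self.Sigma_alpha_,
            post_mean_Sigma_eps=self.Sigma_eps_,
            genomic_correlation=self.genomic_correlation_,
            genomic_correlation_ci=self.genomic_correlation_ci_,
            genomic_correlation_from_Sigma=self.genomic_correlation_from_Sigma_,
            h2=self.h2_, pip=self.pip_, category_freqs=self.category_freqs_,
            post_mean_alpha=self.coef_, retained_samples=self.samples_,
            n_rg_skipped=self.n_rg_skipped_,
            n_jitter_retries=self.n_jitter_retries_, marker_ids=marker_ids)


# kernel category (00, 10, 01, 11) -> spec order index (00, 01, 10, 11)
_KERNEL_TO_SPEC = np.array([0, 2, 1, 3])


def _draw_iw(rng, df: float, scale: np.ndarray, max_tries: int = 6):
    """Inverse-Wishart draw with jitter-and-retry on a non-PD scale."""
    scale = (scale + scale.T) / 2.0
    eps = 1e-8 * max(np.trace(scale) / scale.shape[0], 1e-12)
    for t in range(max_tries):
        try:
            np.linalg.cholesky(scale)
            draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
            return np.atleast_2d(draw), t
        except np.linalg.LinAlgError:
            scale = scale + eps * np.eye(scale.shape[0])
            eps *= 10.0
    raise np.linalg.LinAlgError(
        "inverse-Wishart scale not positive definite after jitter retries")


def fit_bayesc_bivariate(Y, design, G, config: BivariateConfig | None = None,
                         line_ids=None, **kwargs) -> BivariatePosterior:
    """Functional wrapper around :class:`BivariateBayesC`."""
    from .univariate import _expand_genotypes

    if config is None:
        config = BivariateConfig(**kwargs)
    Y = np.asarray(Y, dtype=float)
    X, marker_ids = _expand_genotypes(G, line_ids, Y.shape[0])
    est = BivariateBayesC(
        pi_t=config.pi_t, delta_prior=config.delta_prior,
        wishart_df=config.wishart_df,
        variance_partition=config.variance_partition, n_iter=config.n_iter,
        burn_in=config.burn_in, thin=config.thin,
        n_rep_for_h2=config.n_rep_for_h2, random_state=config.seed)
    est.fit(X, Y, design=design)
    return est.summary_(marker_ids=marker_ids)


def fit_pairs(pairs: list[tuple[str, str]], phenotype_columns: dict,
              design, X, config: BivariateConfig,
              management: str = "") -> pd.DataFrame:
    """Fit one bivariate model per (trait, phenotype) pair.

    ``phenotype_columns`` maps names to plot-level vectors; returns the
    long-format table behind a correlation-spectrum plot: management, trait,
    phenotype, r_g mean and 95% interval, and both traits' heritabilities.
    """
    rows = []
    for trait, pheno in pairs:
        Y = np.column_stack([phenotype_columns[trait],
                             phenotype_columns[pheno]])
        post = fit_bayesc_bivariate(Y, design, X, config)
        rows.append({
            "management": management, "trait": trait, "phenotype": pheno,
            "r_g_mean": post.genomic_correlation,
            "r_g_low": post.genomic_correlation_ci[0],
            "r_g_high": post.genomic_correlation_ci[1],
            "r_g_from_Sigma": post.genomic_correlation_from_Sigma,
            "h2_trait1": post.h2[0], "h2_trait2": post.h2[1],
        })
    return pd.DataFrame(rows)
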