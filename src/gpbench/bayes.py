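"""BayesA: Bayesian whole-genome regression with per-marker variances.

Model: y_i = mu + sum_j m_ij alpha_j + e_i with alpha_j | sigma_j^2 ~
N(0, sigma_j^2) and sigma_j^2 ~ scaled-inv-chi^2(nu, S), which marginally
places a scaled-t prior on each marker effect.  Estimation is by Gibbs
sampling with the standard full conditionals:

* mu | rest        ~ Normal(mean of current residual offset, sigma_e^2 / n)
* alpha_j | rest   ~ Normal with precision (m_j'm_j + sigma_e^2/sigma_j^2)/sigma_e^2
* sigma_j^2 | a_j  ~ scaled-inv-chi^2(nu + 1, (nu S + alpha_j^2) / (nu + 1))
* sigma_e^2 | rest ~ scaled-inv-chi^2(nu_e + n, (e'e + nu_e S_e) / (nu_e + n))

Hyperparameters follow the BGLR-style rule: nu = 4 and S chosen so the prior
marker variance explains a proportion R2 = 0.5 of the phenotypic variance
given the panel's sum of 2 p_j (1 - p_j); the residual scale puts the prior
mode at (1 - R2) * var(y).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import GenotypePanel

__all__ = ["BayesA", "BayesAResults"]


@dataclass
class BayesAResults:
    """Posterior summaries of a BayesA Gibbs run."""

    model: "BayesA"
    posterior_mean_mu: float
    posterior_mean_effects: np.ndarray
    posterior_mean_sigma_e2: float
    posterior_mean_sigma_j2: np.ndarray
    n_iter: int
    burn_in: int
    hyper_nu: float
    hyper_S: float

    def predict(self, ids) -> np.ndarray:
        """mu + M alpha for the given panel rows (no phenotype is read)."""
        idx = np.asarray(ids, dtype=np.intp).reshape(-1)
        M = self.model.panel.dosages[idx].astype(np.float64)
        return self.posterior_mean_mu + M @ self.posterior_mean_effects

    def summary(self) -> str:
        top = np.argsort(-np.abs(self.posterior_mean_effects))[:5]
        lines = [
            "BayesA Gibbs fit",
            "=" * 40,
            f"{'posterior mean mu':<26}{self.posterior_mean_mu:>12.5f}",
            f"{'posterior mean sigma_e^2':<26}{self.posterior_mean_sigma_e2:>12.5f}",
            f"{'iterations (burn-in)':<26}{self.n_iter:>7d} ({self.burn_in})",
            f"{'prior nu / S':<26}{self.hyper_nu:>7.1f} / {self.hyper_S:.5g}",
            "largest |posterior mean effect| markers: "
            + ", ".join(f"{j}:{self.posterior_mean_effects[j]:+.4f}" for j in top),
        ]
        return "\n".join(lines)


class BayesA:
    """BayesA model bound to a panel and training phenotypes.

    ``fit(n_iter, burn_in, seed)`` runs the Gibbs sampler; identical seeds
    give identical chains.
    """

    def __init__(self, y_train, panel: GenotypePanel, train_ids=None,
                 nu: float = 4.0, r2: float = 0.5):
        self.panel = panel
        y = np.asarray(y_train, dtype=np.float64).reshape(-1)
        if not np.isfinite(y).all():
            raise ValueError("non-finite phenotypes")
        if train_ids is None:
            train_ids = np.arange(y.size)
        self.train_ids = np.asarray(train_ids, dtype=np.intp).reshape(-1)
        if self.train_ids.size != y.size:
            raise ValueError("y_train and train_ids lengths differ")
        self.y = y
        self.nu = float(nu)
        self.r2 = float(r2)

    def fit(self, n_iter: int = 5000, burn_in: int = 1000,
            seed: int = 0) -> BayesAResults:
        if not n_iter > burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        rng = np.random.default_rng(seed)
        # Fortran order so per-marker column access is contiguous.
        M = np.asfortranarray(self.panel.dosages[self.train_ids], dtype=np.float64)
        y = self.y
        n, p = M.shape
        mjm = np.einsum("ij,ij->j", M, M)
        vy = y.var()
        freqs = self.panel.allele_frequencies()
        msx = float(np.sum(2.0 * freqs * (1.0 - freqs)))
        nu = self.nu
        # Prior marker-variance scale: E[sigma_j^2] * msx ~ r2 * var(y).
        S = max(self.r2 * vy, 1e-12) / max(msx, 1e-12) * (nu + 2.0) / nu
        nu_e = 4.0
        S_e = max((1.0 - self.r2) * vy, 1e-12) * (nu_e + 2.0) / nu_e

        mu = float(y.mean())
        alpha = np.zeros(p)
        sigma_j2 = np.full(p, S)
        sigma_e2 = max(vy, 1e-12)
        e = y - mu  # current residual

        sum_mu = 0.0
        sum_alpha = np.zeros(p)
        sum_s2e = 0.0
        sum_sj2 = np.zeros(p)
        kept = 0
        for it in range(n_iter):
            # mu | rest
            offset = e + mu
            mu = float(rng.normal(offset.mean(), np.sqrt(sigma_e2 / n)))
            e = offset - mu
            # alpha_j | rest (sequential scan)
            z = rng.standard_normal(p)
            for j in range(p):
                mj = M[:, j]
                old = alpha[j]
                rhs = mj @ e + mjm[j] * old
                cj = mjm[j] + sigma_e2 / sigma_j2[j]
                mean = rhs / cj
                new = mean + z[j] * np.sqrt(sigma_e2 / cj)
                alpha[j] = new
                e += mj * (old - new)
            # sigma_j^2 | alpha_j  (vectorized scaled-inv-chi^2 draws)
            chi = rng.chisquare(nu + 1.0, size=p)
            sigma_j2 = (nu * S + alpha * alpha) / chi
            # sigma_e^2 | rest
            sigma_e2 = float((e @ e + nu_e * S_e) / rng.chisquare(nu_e + n))
            if not (np.isfinite(mu) and np.isfinite(sigma_e2)
                    and np.isfinite(alpha).all()):
                raise FloatingPointError(
                    f"BayesA sampler diverged at iteration {it}: "
                    f"mu={mu}, sigma_e2={sigma_e2}")
            if it >= burn_in:
                kept += 1
                sum_mu += mu
                sum_alpha += alpha
                sum_s2e += sigma_e2
                sum_sj2 += sigma_j2
        return BayesAResults(
            model=self,
            posterior_mean_mu=sum_mu / kept,
            posterior_mean_effects=sum_alpha / kept,
            posterior_mean_sigma_e2=sum_s2e / kept,
            posterior_mean_sigma_j2=sum_sj2 / kept,
            n_iter=n_iter, burn_in=burn_in, hyper_nu=nu, hyper_S=float(S))
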