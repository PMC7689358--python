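"""GBLUP and extended GBLUP mixed models.

Both models follow the statsmodels convention: construct with data, call
``fit()`` to obtain a results object carrying variance components, BLUPs
and a ``summary()``.

GBLUP fits y = 1*mu + g + e with g ~ N(0, sigma_g^2 * G) by REML: G_train is
eigendecomposed once and the restricted likelihood is maximized over the
variance ratio delta = sigma_e^2 / sigma_g^2 by bounded 1-D search on
log10(delta), the spectral approach used by rrBLUP's mixed.solve.  EGBLUP
adds a second genetic component with covariance H = G o G (the Hadamard
square), capturing pairwise marker interactions; its two variance ratios are
found on a coarse grid refined by Nelder-Mead.

Prediction for unphenotyped individuals uses the genomic cross-covariance
block: g_hat = G[all, train] K^{-1} (y - mu_hat), so no test phenotype ever
enters the fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize, minimize_scalar

from .kinship import GRM

__all__ = ["GBLUP", "EGBLUP", "MixedModelResults"]

_LOG10_DELTA_BOUNDS = (-10.0, 10.0)


def _as_index(ids, n) -> np.ndarray:
    idx = np.asarray(ids, dtype=np.intp).reshape(-1)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError("index outside the panel")
    return idx


@dataclass
class MixedModelResults:
    """Fitted mixed-model state shared by GBLUP and EGBLUP.

    ``blup`` holds genetic-value predictions for all n individuals in the
    GRM (trained and untrained); ``predict(ids)`` returns mu + blup[ids].
    For EGBLUP ``variance_components`` has three entries
    (sigma_1^2, sigma_2^2, sigma_e^2) and ``lambda_`` is sigma_e^2/sigma_1^2.
    """

    model: object
    mu: float
    variance_components: tuple[float, ...]
    lambda_: float
    blup: np.ndarray
    llf: float
    extra: dict = field(default_factory=dict)

    @property
    def sigma_g2(self) -> float:
        return sum(self.variance_components[:-1])

    @property
    def sigma_e2(self) -> float:
        return self.variance_components[-1]

    @property
    def h2(self) -> float:
        """REML heritability estimate sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan

    def predict(self, ids) -> np.ndarray:
        """Phenotype-scale predictions mu + g_hat for the given individuals."""
        idx = _as_index(ids, self.blup.size)
        return self.mu + self.blup[idx]

    def fittedvalues(self) -> np.ndarray:
        return self.mu + self.blup

    def summary(self) -> str:
        name = type(self.model).__name__
        lines = [
            f"{name} mixed-model fit (REML)",
            "=" * 40,
            f"{'grand mean mu':<28}{self.mu:>12.5f}",
        ]
        comp_names = (["sigma_g^2"] if len(self.variance_components) == 2
                      else ["sigma_1^2 (additive)", "sigma_2^2 (epistatic)"])
        for cname, v in zip(comp_names, self.variance_components[:-1]):
            lines.append(f"{cname:<28}{v:>12.5f}")
        lines.append(f"{'sigma_e^2':<28}{self.sigma_e2:>12.5f}")
        lines.append(f"{'lambda (sigma_e^2/sigma_g^2)':<28}{self.lambda_:>12.5g}")
        lines.append(f"{'h2 (REML)':<28}{self.h2:>12.4f}")
        lines.append(f"{'restricted log-likelihood':<28}{self.llf:>12.4f}")
        lines.append(f"{'n trained / total':<28}"
                     f"{len(self.model.train_ids):>6d} /{self.blup.size:>5d}")
        return "\n".join(lines)


class GBLUP:
    """Genomic BLUP with a VanRaden GRM.

    Parameters
    ----------
    y_train : array
        Phenotypes of the training individuals, aligned with ``train_ids``.
    grm : GRM
        Relationship matrix over all individuals (train + test).
    train_ids : array of int, optional
        Row indices of the training individuals in the GRM; defaults to
        0..len(y_train)-1.
    """

    def __init__(self, y_train, grm: GRM, train_ids=None):
        self.grm = grm
        y = np.asarray(y_train, dtype=np.float64).reshape(-1)
        if not np.isfinite(y).all():
            raise ValueError("non-finite phenotypes")
        if train_ids is None:
            train_ids = np.arange(y.size)
        self.train_ids = _as_index(train_ids, grm.n)
        if self.train_ids.size != y.size:
            raise ValueError("y_train and train_ids lengths differ")
        if y.size < 3:
            raise ValueError("need at least 3 training individuals")
        self.y = y

    def fit(self, delta: float | None = None) -> MixedModelResults:
        """REML fit; pass ``delta`` to fix the variance ratio
        sigma_e^2 / sigma_g^2 instead of estimating it."""
        tr = self.train_ids
        G_tr = self.grm.matrix[np.ix_(tr, tr)]
        d, U = eigh(G_tr)
        d = np.clip(d, 0.0, None)  # G is PSD up to round-off
        yt = U.T @ self.y
        ot = U.T @ np.ones(tr.size)
        m = tr.size

        def neg_restricted_ll(log10_delta: float) -> float:
            w = d + 10.0 ** log10_delta
            denom = np.sum(ot * ot / w)
            mu = np.sum(ot * yt / w) / denom
            r = yt - mu * ot
            s2 = np.sum(r * r / w) / (m - 1)
            return 0.5 * ((m - 1) * np.log(s2) + np.sum(np.log(w)) + np.log(denom))

        if delta is None:
            opt = minimize_scalar(neg_restricted_ll, bounds=_LOG10_DELTA_BOUNDS,
                                  method="bounded", options={"xatol": 1e-8})
            delta = 10.0 ** opt.x
            log10_delta, nll = float(opt.x), float(opt.fun)
        else:
            if delta <= 0:
                raise ValueError("delta must be positive")
            log10_delta = float(np.log10(delta))
            nll = neg_restricted_ll(log10_delta)
        w = d + delta
        denom = np.sum(ot * ot / w)
        mu = float(np.sum(ot * yt / w) / denom)
        r = yt - mu * ot
        sigma_g2 = float(np.sum(r * r / w) / (m - 1))
        sigma_e2 = float(delta * sigma_g2)
        # H^{-1} (y - mu) in the original coordinates; H = G_tr + delta I.
        hinv_r = U @ (r / w)
        blup = self.grm.matrix[:, tr] @ hinv_r
        return MixedModelResults(
            model=self, mu=mu,
            variance_components=(sigma_g2, sigma_e2),
            lambda_=float(delta), blup=blup, llf=-nll,
            extra={"log10_delta": log10_delta})


class EGBLUP:
    """Extended GBLUP: y = 1*mu + g1 + g2 + e with Cov(g1) = sigma_1^2 G and
    Cov(g2) = sigma_2^2 (G o G).  REML over the two ratios
    lambda_i = sigma_i^2 / sigma_e^2."""

    def __init__(self, y_train, grm: GRM, train_ids=None):
        base = GBLUP(y_train, grm, train_ids)
        self.grm = grm
        self.y = base.y
        self.train_ids = base.train_ids
        self.H = grm.hadamard_square()

    def _profile(self, lam1: float, lam2: float):
        tr = self.train_ids
        m = tr.size
        K = (lam1 * self.grm.matrix[np.ix_(tr, tr)]
             + lam2 * self.H[np.ix_(tr, tr)]
             + np.eye(m))
        c, low = cho_factor(K, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        one = np.ones(m)
        Kinv_y = cho_solve((c, low), self.y)
        Kinv_1 = cho_solve((c, low), one)
        denom = one @ Kinv_1
        mu = (one @ Kinv_y) / denom
        r = self.y - mu
        Kinv_r = Kinv_y - mu * Kinv_1
        s2e = (r @ Kinv_r) / (m - 1)
        nll = 0.5 * ((m - 1) * np.log(s2e) + logdet + np.log(denom))
        return nll, float(mu), float(s2e), Kinv_r

    def fit(self, fix_lambda2: float | None = None,
            grid: np.ndarray | None = None) -> MixedModelResults:
        """REML fit.  ``fix_lambda2`` pins the epistatic ratio (0 recovers
        plain GBLUP); otherwise a log-spaced grid is scanned and refined by
        Nelder-Mead."""
        if grid is None:
            grid = np.arange(-4.0, 3.0)  # log10 lambda grid

        def objective(x):
            l1 = 10.0 ** x[0]
            l2 = 10.0 ** x[1] if fix_lambda2 is None else fix_lambda2
            return self._profile(l1, l2)[0]

        if fix_lambda2 is None:
            best, best_val = None, np.inf
            for a in grid:
                for b in grid:
                    v = objective((a, b))
                    if v < best_val:
                        best, best_val = (a, b), v
            opt = minimize(objective, best, method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400})
            lam1, lam2 = 10.0 ** opt.x[0], 10.0 ** opt.x[1]
            nll = opt.fun
        else:
            opt = minimize_scalar(lambda a: objective((a,)),
                                  bounds=_LOG10_DELTA_BOUNDS, method="bounded",
                                  options={"xatol": 1e-8})
            lam1, lam2 = 10.0 ** opt.x, float(fix_lambda2)
            nll = opt.fun
        _, mu, s2e, Kinv_r = self._profile(lam1, lam2)
        tr = self.train_ids
        g1 = lam1 * (self.grm.matrix[:, tr] @ Kinv_r)
        g2 = lam2 * (self.H[:, tr] @ Kinv_r)
        s1, s2_, se = lam1 * s2e, lam2 * s2e, s2e
        return MixedModelResults(
            model=self, mu=mu,
            variance_components=(float(s1), float(s2_), float(se)),
            lambda_=float(1.0 / lam1) if lam1 > 0 else np.inf,
            blup=g1 + g2, llf=float(-nll),
            extra={"blup_additive": g1, "blup_epistatic": g2,
                   "lambda1": float(lam1), "lambda2": float(lam2)})
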