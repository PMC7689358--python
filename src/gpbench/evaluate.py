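"""Cross-validation protocol, predictive ability and the benchmark harness.

Protocol: 80% of a panel forms the fitting set, further divided into a
training set and a validation set used only for epoch selection by the
ANNs; the remaining 20% is the test set.  On a 10,000-individual panel with
a 1,000-strong validation set this yields the 7,000 / 1,000 / 2,000 split.
Predictive ability is the Pearson correlation between predictions and the
phenotypes of test individuals; the standardized variant divides by
sqrt(h2), the theoretical ceiling for a trait of heritability h2.

Linear models (GBLUP, EGBLUP, BayesA) need no epoch selection and are
fitted on the full fitting set (train + validation); ANNs train on the
training set and select their epoch on the validation set.  No code path
sees a test phenotype before scoring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesA
from .kinship import GRM, vanraden_grm
from .linear import EGBLUP, GBLUP
from .markers import GenotypePanel
from .nets import (NetworkModel, NetworkSpec, TrainConfig, cnn_baseline,
                   lcnn_baseline, mlp_baseline)
from .traits import PhenotypePanel

__all__ = [
    "SplitPlan", "make_split", "training_size_grid", "FIT_SIZES", "VAL_SIZES",
    "predictive_ability", "standardized_predictive_ability",
    "max_predictive_ability", "ModelSpec", "baseline_model_specs",
    "run_benchmark", "BenchmarkResult",
]

#: Paired (fitting size, validation size) grid of the training-size sweep.
FIT_SIZES = (100, 250, 500, 1000, 2000, 3000, 4000, 6000, 8000)
VAL_SIZES = (20, 50, 100, 200, 300, 400, 500, 750, 1000)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train / validation / test index sets for one repeat."""

    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray
    repeat_id: int = 0
    seed: int = 0

    def __post_init__(self):
        tr = np.asarray(self.train_ids, dtype=np.intp)
        va = np.asarray(self.validation_ids, dtype=np.intp)
        te = np.asarray(self.test_ids, dtype=np.intp)
        allidx = np.concatenate([tr, va, te])
        if np.unique(allidx).size != allidx.size:
            raise ValueError("split sets must be disjoint")
        object.__setattr__(self, "train_ids", tr)
        object.__setattr__(self, "validation_ids", va)
        object.__setattr__(self, "test_ids", te)

    @property
    def fitting_ids(self) -> np.ndarray:
        """Train and validation together: the model-fitting set."""
        return np.concatenate([self.train_ids, self.validation_ids])


def _split_sizes(n: int, fit_size: int, validation_size: int, seed: int,
                 repeat_id: int = 0) -> SplitPlan:
    if not (0 <= validation_size < fit_size <= n):
        raise ValueError(f"infeasible split: n={n}, fit={fit_size}, "
                         f"validation={validation_size}")
    perm = np.random.default_rng(seed).permutation(n)
    fit = perm[:fit_size]
    return SplitPlan(train_ids=np.sort(fit[validation_size:]),
                     validation_ids=np.sort(fit[:validation_size]),
                     test_ids=np.sort(perm[fit_size:]),
                     repeat_id=repeat_id, seed=seed)


def make_split(n: int, train_fraction: float = 0.8, validation_size: int = 0,
               seed: int = 0, repeat_id: int = 0) -> SplitPlan:
    """Uniformly random split: ``train_fraction`` of the panel is the fitting
    set (train + validation), the remainder the test set."""
    fit_size = int(round(train_fraction * n))
    return _split_sizes(n, fit_size, validation_size, seed, repeat_id)


def training_size_grid(n: int, seed: int = 0) -> list[SplitPlan]:
    """One split per (fitting size, validation size) pair of the sweep grid.

    Pairs exceeding the panel (leaving no test individual) are dropped with
    a warning so desk-scale panels can run a truncated sweep.
    """
    plans = []
    for i, (fs, vs) in enumerate(zip(FIT_SIZES, VAL_SIZES)):
        if fs >= n:
            warnings.warn(f"panel of {n} too small for fitting size {fs}; "
                          "grid truncated", stacklevel=2)
            break
        plans.append(_split_sizes(n, fs, vs, seed + i, repeat_id=i))
    if not plans:
        raise ValueError(f"panel of {n} too small for the smallest grid size")
    return plans


def predictive_ability(predictions, phenotypes) -> float:
    """Pearson correlation between predictions and held-out phenotypes.

    Returns NaN (with a warning) when either vector is constant, where the
    correlation is undefined — never a silent 0.
    """
    a = np.asarray(predictions, dtype=np.float64).reshape(-1)
    b = np.asarray(phenotypes, dtype=np.float64).reshape(-1)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        warnings.warn("zero-variance input; predictive ability undefined",
                      stacklevel=2)
        return float("nan")
    return float((a @ b) / denom)


def standardized_predictive_ability(r: float, h2: float) -> float:
    """r / sqrt(h2): predictive ability relative to its theoretical ceiling."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    return r / np.sqrt(h2)


def max_predictive_ability(h2: float) -> float:
    """Theoretical ceiling sqrt(h2) of the predictive ability for a trait of
    heritability h2 (0.707 at h2 = 0.5)."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    return float(np.sqrt(h2))


@dataclass(frozen=True)
class ModelSpec:
    """One predictor in a benchmark: a linear-model kind or an ANN spec."""

    name: str
    kind: str  # gblup | egblup | bayesa | ann
    network: NetworkSpec | None = None
    train: TrainConfig | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("gblup", "egblup", "bayesa", "ann"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "ann" and self.network is None:
            raise ValueError("ann ModelSpec needs a NetworkSpec")


def baseline_model_specs(include=("gblup", "mlp", "cnn", "lcnn")) -> list[ModelSpec]:
    """The four baseline predictors (plus optional 'egblup'/'bayesa')."""
    out = []
    for name in include:
        if name in ("gblup", "egblup", "bayesa"):
            out.append(ModelSpec(name=name.upper(), kind=name))
        elif name == "mlp":
            out.append(ModelSpec("MLP", "ann", network=mlp_baseline()))
        elif name == "cnn":
            out.append(ModelSpec("CNN", "ann", network=cnn_baseline()))
        elif name == "lcnn":
            out.append(ModelSpec("LCNN", "ann", network=lcnn_baseline()))
        else:
            raise ValueError(f"unknown baseline {name!r}")
    return out


@dataclass
class BenchmarkResult:
    """Tidy per-(trait, model, repeat) results with an aggregating summary."""

    frame: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean predictive ability per (trait, model) with a 95% normal-theory
        confidence interval for the mean across repeats."""
        def agg(g: pd.Series):
            m = g.mean()
            se = g.std(ddof=1) / np.sqrt(g.count()) if g.count() > 1 else 0.0
            return pd.Series({"mean_pa": m, "ci_low": m - 1.96 * se,
                              "ci_high": m + 1.96 * se, "n_repeats": g.count()})
        return (self.frame.groupby(["trait", "model"])["predictive_ability"]
                .apply(agg).unstack())

    def mean_pa(self, model: str, trait: str | None = None) -> float:
        f = self.frame[self.frame["model"] == model]
        if trait is not None:
            f = f[f["trait"] == trait]
        return float(f["predictive_ability"].mean())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _fit_and_predict(spec: ModelSpec, panel: GenotypePanel, y: np.ndarray,
                     split: SplitPlan, grm: GRM | None, model_seed: int):
    """Fit one predictor on one split; returns (test predictions, epoch)."""
    if spec.kind in ("gblup", "egblup"):
        ids = split.fitting_ids
        cls = GBLUP if spec.kind == "gblup" else EGBLUP
        res = cls(y[ids], grm, train_ids=ids).fit()
        return res.predict(split.test_ids), None
    if spec.kind == "bayesa":
        ids = split.fitting_ids
        opts = {"n_iter": 1500, "burn_in": 300, **spec.options}
        res = BayesA(y[ids], panel, train_ids=ids).fit(seed=model_seed, **opts)
        return res.predict(split.test_ids), None
    # ANN
    X = panel.dosages.astype(np.float64)
    cfg = spec.train or TrainConfig()
    cfg = TrainConfig(mode=cfg.mode, max_epochs=cfg.max_epochs,
                      batch_size=cfg.batch_size,
                      learning_rate=cfg.learning_rate, seed=model_seed)
    ymat = y if y.ndim == 2 else y[:, None]
    if cfg.mode == "early_stop":
        mdl = NetworkModel(ymat[split.train_ids], X[split.train_ids],
                           spec.network, y_val=ymat[split.validation_ids],
                           X_val=X[split.validation_ids])
    else:
        mdl = NetworkModel(ymat[split.fitting_ids], X[split.fitting_ids],
                           spec.network)
    res = mdl.fit(cfg)
    pred = res.predict(X[split.test_ids])
    return pred, res.selected_epoch


def run_benchmark(panel: GenotypePanel, phenotypes: PhenotypePanel,
                  model_specs: list[ModelSpec], n_repeats: int = 25,
                  seed: int = 0, fit_size: int | None = None,
                  validation_size: int | None = None,
                  traits=None, grm: GRM | None = None) -> BenchmarkResult:
    """Repeated random-split benchmark.

    Every repeat draws a fresh split (seed = master + repeat); all models see
    the identical split and are scored on the identical test set.  Model m
    (1-based) uses seed master + 10000*m + repeat for its own randomness, so
    models stay comparable within a repeat.  A failing model is recorded as a
    NaN cell and does not abort the sweep.
    """
    if not model_specs:
        raise ValueError("need at least one model spec")
    n = panel.n_individuals
    if fit_size is None:
        fit_size = int(round(0.8 * n))
    if validation_size is None:
        validation_size = max(1, fit_size // 8)
    trait_idx = range(phenotypes.n_traits) if traits is None else [
        phenotypes.trait_names.index(t) if isinstance(t, str) else t
        for t in traits]
    needs_grm = any(s.kind in ("gblup", "egblup") for s in model_specs)
    if needs_grm and grm is None:
        grm = vanraden_grm(panel)

    rows = []
    for r in range(n_repeats):
        split = _split_sizes(n, fit_size, validation_size, seed + r, repeat_id=r)
        for m, spec in enumerate(model_specs, start=1):
            model_seed = seed + 10_000 * m + r
            for t in trait_idx:
                y = phenotypes.phenotypes[:, t]
                row = {"trait": phenotypes.trait_names[t], "model": spec.name,
                       "repeat": r, "n_fit": fit_size,
                       "h2": (phenotypes.target_h2[t]
                              if phenotypes.target_h2 else np.nan)}
                try:
                    pred, epoch = _fit_and_predict(spec, panel, y, split,
                                                   grm, model_seed)
                    pa = predictive_ability(pred, y[split.test_ids])
                except Exception as exc:  # recorded, not fatal to the sweep
                    warnings.warn(f"{spec.name} failed on repeat {r}: {exc}",
                                  stacklevel=2)
                    pa, epoch = np.nan, None
                row["predictive_ability"] = pa
                row["standardized_pa"] = (
                    pa / np.sqrt(row["h2"]) if np.isfinite(row["h2"]) else np.nan)
                row["selected_epoch"] = epoch if epoch is not None else np.nan
                rows.append(row)
    return BenchmarkResult(pd.DataFrame(rows))


def plot_benchmark(result: BenchmarkResult, ax=None):
    """Bar plot of mean predictive ability with 95% CI per (trait, model).

    Requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    summ = result.summary().reset_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(summ) + 2, 4))
    x = np.arange(len(summ))
    err = np.vstack([summ["mean_pa"] - summ["ci_low"],
                     summ["ci_high"] - summ["mean_pa"]])
    ax.bar(x, summ["mean_pa"], yerr=err, capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels([f"{t}\n{m}" for t, m in zip(summ["trait"], summ["model"])],
                       fontsize=8)
    ax.set_ylabel("predictive ability")
    return ax
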