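"""Quantitative-trait simulation on a genotype panel.

Two QTL types define a genetic-value function: additive single-marker QTL
(a linear effect per allele copy) and epistatic QTL pairs carrying a full
3 x 3 effect table over the nine dosage combinations (00, 01, ..., 22).
"Linked" epistatic pairs sit at most ``max_link_distance`` marker indices
apart on the same chromosome, emulating local interactions within a gene.

Heritability is imposed by adding i.i.d. Gaussian residuals with variance
sigma_e^2 = Var(g) * (1 - h2) / h2, where Var(g) is the realized (population,
ddof=0) variance of the genetic values in the panel, so the realized h2 is
tight around the target.  Correlated multi-trait sets share one QTL position
set and mix i.i.d. Gaussian effect vectors through the Cholesky factor of an
equicorrelation matrix.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .markers import GenotypePanel, MarkerMap

__all__ = [
    "AdditiveQTL",
    "EpistaticQTL",
    "TraitArchitecture",
    "PhenotypePanel",
    "sample_architecture",
    "genetic_value",
    "apply_heritability",
    "correlated_traits",
]


@dataclass(frozen=True)
class AdditiveQTL:
    """A single-marker QTL: ``effect`` phenotype units per allele copy."""

    marker_index: int
    effect: float


@dataclass(frozen=True)
class EpistaticQTL:
    """A marker-pair QTL with nine separate effects, one per dosage combo."""

    marker_index_a: int
    marker_index_b: int
    effect_table: np.ndarray  # 3 x 3, indexed [dosage_a, dosage_b]

    def __post_init__(self):
        if self.marker_index_a == self.marker_index_b:
            raise ValueError("epistatic QTL needs two distinct markers")
        tab = np.asarray(self.effect_table, dtype=np.float64)
        if tab.shape != (3, 3):
            raise ValueError("effect_table must be 3x3")
        if not np.isfinite(tab).all():
            raise ValueError("effect_table entries must be finite")
        object.__setattr__(self, "effect_table", tab)


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL positions and effects defining one trait's genetic-value map."""

    additive: tuple[AdditiveQTL, ...] = ()
    epistatic: tuple[EpistaticQTL, ...] = ()
    linked: bool = False
    max_link_distance: int = 5
    effect_distribution: str = "gaussian"
    h2: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "additive", tuple(self.additive))
        object.__setattr__(self, "epistatic", tuple(self.epistatic))
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.linked:
            for q in self.epistatic:
                if abs(q.marker_index_a - q.marker_index_b) > self.max_link_distance:
                    raise ValueError("linked architecture violates max_link_distance")

    @property
    def n_qtl(self) -> int:
        return len(self.additive) + len(self.epistatic)

    def max_pair_distance(self) -> int | None:
        """Largest |index_a - index_b| over epistatic pairs (None if purely additive)."""
        if not self.epistatic:
            return None
        return max(abs(q.marker_index_a - q.marker_index_b) for q in self.epistatic)

    def to_json(self) -> str:
        payload = {
            "linked": self.linked,
            "max_link_distance": self.max_link_distance,
            "effect_distribution": self.effect_distribution,
            "h2": self.h2,
            "additive": [{"marker_index": q.marker_index, "effect": q.effect}
                         for q in self.additive],
            "epistatic": [{"marker_index_a": q.marker_index_a,
                           "marker_index_b": q.marker_index_b,
                           "effect_table": q.effect_table.tolist()}
                          for q in self.epistatic],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TraitArchitecture":
        d = json.loads(text)
        return cls(
            additive=tuple(AdditiveQTL(q["marker_index"], q["effect"])
                           for q in d["additive"]),
            epistatic=tuple(EpistaticQTL(q["marker_index_a"], q["marker_index_b"],
                                         np.array(q["effect_table"]))
                            for q in d["epistatic"]),
            linked=d["linked"], max_link_distance=d["max_link_distance"],
            effect_distribution=d["effect_distribution"], h2=d["h2"])


@dataclass(frozen=True)
class PhenotypePanel:
    """Genetic values, residuals and phenotypes for T traits on n individuals.

    All arrays are ``n x T``; ``phenotypes = genetic_values + residuals`` holds
    elementwise and ``realized_h2[t] = Var(g_t) / Var(y_t)`` (population
    variances on the realized sample).
    """

    genetic_values: np.ndarray
    residuals: np.ndarray
    trait_names: tuple[str, ...] = ()
    target_h2: tuple[float, ...] = ()

    def __post_init__(self):
        g = np.asarray(self.genetic_values, dtype=np.float64)
        e = np.asarray(self.residuals, dtype=np.float64)
        if g.ndim == 1:
            g = g[:, None]
        if e.ndim == 1:
            e = e[:, None]
        if g.shape != e.shape:
            raise ValueError("genetic_values and residuals must have equal shape")
        object.__setattr__(self, "genetic_values", g)
        object.__setattr__(self, "residuals", e)
        names = tuple(self.trait_names) or tuple(
            f"trait_{t + 1}" for t in range(g.shape[1]))
        if len(names) != g.shape[1]:
            raise ValueError("trait_names length mismatch")
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "target_h2", tuple(self.target_h2))

    @property
    def phenotypes(self) -> np.ndarray:
        return self.genetic_values + self.residuals

    @property
    def n_traits(self) -> int:
        return int(self.genetic_values.shape[1])

    @property
    def realized_h2(self) -> np.ndarray:
        vg = self.genetic_values.var(axis=0)
        vy = self.phenotypes.var(axis=0)
        return vg / vy

    def trait(self, t: int | str) -> np.ndarray:
        """Phenotype vector of one trait, by index or name."""
        if isinstance(t, str):
            t = self.trait_names.index(t)
        return self.phenotypes[:, t]


def _draw_effects(rng: np.random.Generator, size, distribution: str) -> np.ndarray:
    if distribution == "equal":
        return np.ones(size)
    if distribution == "gaussian":
        return rng.standard_normal(size)
    if distribution == "gamma":
        # Heavy-tailed alternative: shape 0.4, scale 1, random sign.
        mag = rng.gamma(0.4, 1.0, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign
    raise ValueError(f"unknown effect_distribution {distribution!r}")


def sample_architecture(panel_or_map: GenotypePanel | MarkerMap, n_qtl: int,
                        kind: str = "additive",
                        effect_distribution: str = "gaussian",
                        max_link_distance: int = 5,
                        h2: float = 0.5,
                        seed: int = 0) -> TraitArchitecture:
    """Draw a random trait architecture on a marker map.

    ``kind`` is one of ``additive`` (n_qtl distinct markers, one linear effect
    each), ``epistatic`` (n_qtl disjoint marker pairs, 3x3 tables) or
    ``linked_epistatic`` (pairs at most ``max_link_distance`` indices apart on
    the same chromosome).
    """
    mmap = panel_or_map.map if isinstance(panel_or_map, GenotypePanel) else panel_or_map
    p = mmap.n_markers
    rng = np.random.default_rng(seed)
    if n_qtl < 1:
        raise ValueError("n_qtl must be positive")
    if kind == "additive":
        if n_qtl > p:
            raise ValueError("more additive QTL requested than markers available")
        idx = rng.choice(p, size=n_qtl, replace=False)
        eff = _draw_effects(rng, n_qtl, effect_distribution)
        qtl = tuple(AdditiveQTL(int(j), float(a)) for j, a in zip(idx, eff))
        return TraitArchitecture(additive=qtl, effect_distribution=effect_distribution,
                                 h2=h2, max_link_distance=max_link_distance)
    if kind not in ("epistatic", "linked_epistatic"):
        raise ValueError(f"unknown architecture kind {kind!r}")
    linked = kind == "linked_epistatic"
    if linked and max_link_distance < 1:
        raise ValueError("linked architecture requires max_link_distance >= 1")
    if 2 * n_qtl > p:
        raise ValueError("not enough markers for disjoint epistatic pairs")

    available = np.ones(p, dtype=bool)
    chrom = mmap.chromosome
    pairs: list[tuple[int, int]] = []
    attempts = 0
    while len(pairs) < n_qtl:
        attempts += 1
        if attempts > 200 * n_qtl:
            raise ValueError("could not place disjoint QTL pairs; map too constrained")
        free = np.flatnonzero(available)
        a = int(rng.choice(free))
        if linked:
            lo, hi = max(0, a - max_link_distance), min(p, a + max_link_distance + 1)
            cand = np.arange(lo, hi)
            cand = cand[(cand != a) & available[lo:hi][cand - lo]
                        & (chrom[cand] == chrom[a])]
        else:
            cand = free[free != a]
        if cand.size == 0:
            continue
        b = int(rng.choice(cand))
        available[a] = available[b] = False
        pairs.append((a, b))
    tables = _draw_effects(rng, (n_qtl, 3, 3), effect_distribution)
    qtl = tuple(EpistaticQTL(a, b, tab) for (a, b), tab in zip(pairs, tables))
    return TraitArchitecture(epistatic=qtl, linked=linked,
                             max_link_distance=max_link_distance,
                             effect_distribution=effect_distribution, h2=h2)


def genetic_value(panel: GenotypePanel, arch: TraitArchitecture) -> np.ndarray:
    """Deterministic genetic value g_i = sum of additive effects times dosage
    plus epistatic 3x3 table lookups."""
    M = panel.dosages
    p = panel.n_markers
    g = np.zeros(panel.n_individuals)
    if arch.additive:
        idx = np.array([q.marker_index for q in arch.additive])
        if idx.min() < 0 or idx.max() >= p:
            raise IndexError("additive QTL index outside the panel")
        eff = np.array([q.effect for q in arch.additive])
        g += M[:, idx].astype(np.float64) @ eff
    for q in arch.epistatic:
        if not (0 <= q.marker_index_a < p and 0 <= q.marker_index_b < p):
            raise IndexError("epistatic QTL index outside the panel")
        da = M[:, q.marker_index_a].astype(np.intp)
        db = M[:, q.marker_index_b].astype(np.intp)
        g += q.effect_table[da, db]
    return g


def apply_heritability(genetic: np.ndarray, h2: float, seed: int = 0,
                       trait_name: str = "trait_1") -> PhenotypePanel:
    """Add Gaussian residuals scaled so the trait has heritability ``h2``.

    sigma_e^2 = Var(g) * (1 - h2) / h2 with Var the realized population
    variance; ``h2 = 1`` yields zero residuals exactly.
    """
    g = np.asarray(genetic, dtype=np.float64).reshape(-1)
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    vg = g.var()
    if vg == 0.0:
        raise ValueError("genetic values are constant; heritability is undefined")
    if h2 == 1.0:
        resid = np.zeros_like(g)
    else:
        sigma_e = np.sqrt(vg * (1.0 - h2) / h2)
        resid = np.random.default_rng(seed).normal(0.0, sigma_e, size=g.size)
    return PhenotypePanel(g[:, None], resid[:, None], (trait_name,), (h2,))


def correlated_traits(panel: GenotypePanel, n_traits: int = 5, n_qtl: int = 1000,
                      rho: float = 0.8, h2: float = 0.5,
                      seed: int = 0) -> PhenotypePanel:
    """Correlated additive traits sharing one QTL position set.

    Per-trait effect vectors are linear mixtures of i.i.d. standard-normal
    effect vectors.  The mixture matrix is the Cholesky factor of the
    equicorrelation target (1 on the diagonal, ``rho`` off it) composed with
    an empirical whitening step: the raw genetic values are decorrelated on
    the realized panel before the target correlation is imposed, so the
    sample genetic correlations equal ``rho`` exactly rather than only in
    expectation (LD and kinship would otherwise inflate their spread far
    beyond the i.i.d. sampling error).  Residuals are independent across
    traits and scaled per trait to the common ``h2``.
    """
    if n_traits < 2:
        raise ValueError("need at least 2 traits")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = panel.n_markers
    if n_qtl > p:
        raise ValueError("more QTL than markers")
    idx = rng.choice(p, size=n_qtl, replace=False)
    raw = rng.standard_normal((n_qtl, n_traits))
    corr = np.full((n_traits, n_traits), rho)
    np.fill_diagonal(corr, 1.0)
    L = np.linalg.cholesky(corr)  # raises on non-PD targets
    M_qtl = panel.dosages[:, idx].astype(np.float64)
    G0 = M_qtl @ raw
    Gc = G0 - G0.mean(axis=0)
    C = (Gc.T @ Gc) / Gc.shape[0]
    A = np.linalg.cholesky(C)
    mix = np.linalg.solve(A, np.eye(n_traits)).T @ L.T  # whiten, then target
    effects = raw @ mix
    G = M_qtl @ effects  # n x T genetic values, sample correlation == rho
    resid = np.empty_like(G)
    for t in range(n_traits):
        vg = G[:, t].var()
        if h2 == 1.0:
            resid[:, t] = 0.0
        else:
            resid[:, t] = rng.normal(0.0, np.sqrt(vg * (1.0 - h2) / h2), size=G.shape[0])
    names = tuple(f"trait_{t + 1}" for t in range(n_traits))
    return PhenotypePanel(G, resid, names, (h2,) * n_traits)


def simulate_trait(panel: GenotypePanel, arch: TraitArchitecture,
                   seed: int = 0, trait_name: str = "trait_1") -> PhenotypePanel:
    """Convenience: genetic values for ``arch`` plus residuals at ``arch.h2``."""
    g = genetic_value(panel, arch)
    return apply_heritability(g, arch.h2, seed=seed, trait_name=trait_name)
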