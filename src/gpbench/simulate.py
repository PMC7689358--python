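"""Synthetic breeding-population genotypes.

Panels are produced in two stages mirroring how a maize breeding panel arises
from a landrace: (1) founder haplotypes with tunable local LD, (2) one round
of random mating between founder lines, with recombination following a
Poisson crossover process on the genetic map.

The founder generator is a Gaussian-copula first-order Markov chain along
each chromosome: a latent AR(1) process z_j = a*z_{j-1} + sqrt(1-a^2)*eps_j
with persistence a = ``ld_strength`` is thresholded at the per-marker target
allele frequency, so marginal frequencies are exact and adjacent-marker
correlation rises monotonically with ``ld_strength``.  Chromosomes are
independent.  This stands in for a real founder panel; it reproduces local
LD, which is what window-based (local convolutional) predictors exploit, but
not long-range structure or a realistic site-frequency spectrum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.signal import lfilter

from .markers import GenotypePanel, HaplotypeSet, MarkerMap

__all__ = [
    "generate_founder_haplotypes",
    "random_mating",
    "PanelConfig",
    "simulate_panel",
    "desk_config",
    "maize_config",
]


def generate_founder_haplotypes(n_haplotypes: int, marker_map: MarkerMap,
                                allele_freq_range: tuple[float, float] = (0.05, 0.95),
                                ld_strength: float = 0.8,
                                seed: int = 0) -> HaplotypeSet:
    """Simulate founder haplotypes with local LD.

    Parameters
    ----------
    n_haplotypes : int
        Number of haplotypes (>= 2; use an even number if the set will be
        paired into diploid founders).
    marker_map : MarkerMap
        Ordered marker map; chromosomes are simulated independently.
    allele_freq_range : (float, float)
        Per-marker target allele frequencies are drawn uniformly from this
        interval, which must lie strictly inside (0, 1) — a request touching
        0 or 1 would produce monomorphic markers and is rejected.
    ld_strength : float in [0, 1)
        Persistence of the latent AR(1) chain.  0 gives independent markers;
        values near 1 give strong adjacent-marker correlation.
    seed : int
        Seed for the random generator; same seed, same haplotypes.
    """
    lo, hi = float(allele_freq_range[0]), float(allele_freq_range[1])
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(
            f"allele_freq_range must satisfy 0 < lo <= hi < 1, got ({lo}, {hi}); "
            "frequencies of 0 or 1 would make markers monomorphic")
    if not (0.0 <= ld_strength < 1.0):
        raise ValueError("ld_strength must lie in [0, 1)")
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    p = marker_map.n_markers
    if p < 2:
        raise ValueError("need at least 2 markers")

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    thresholds = ndtri(freqs)  # allele = 1  <=>  z < Phi^{-1}(f)
    hap = np.empty((n_haplotypes, p), dtype=np.uint8)
    a = ld_strength
    for _, sl in marker_map.chrom_slices().items():
        m = sl.stop - sl.start
        eps = rng.standard_normal((n_haplotypes, m))
        if a == 0.0:
            z = eps
        else:
            # AR(1): z_j = a z_{j-1} + sqrt(1-a^2) eps_j, stationary start.
            innov = eps * np.sqrt(1.0 - a * a)
            innov[:, 0] = eps[:, 0]
            z = lfilter([1.0], [1.0, -a], innov, axis=1)
        hap[:, sl] = (z < thresholds[np.newaxis, sl]).astype(np.uint8)
    return HaplotypeSet(hap, marker_map)


def _gamete(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray,
            pos: np.ndarray, length: float) -> np.ndarray:
    """One recombinant gamete from a parent's two chromosome haplotypes.

    Crossover count is Poisson(length); crossover positions are uniform on
    the chromosome's genetic span.  The starting haplotype is random.
    """
    start = rng.integers(2)
    n_x = rng.poisson(length) if length > 0 else 0
    if n_x == 0:
        return hap_a if start == 0 else hap_b
    xpos = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
    parity = (np.searchsorted(xpos, pos, side="right") + start) % 2
    return np.where(parity == 0, hap_a, hap_b)


def random_mating(founders: HaplotypeSet, n_offspring: int,
                  recombination_rate: float | None = None,
                  seed: int = 0) -> GenotypePanel:
    """One generation of random mating between founder individuals.

    Founder haplotypes are paired into diploid founders in a seed-determined
    shuffled order.  Each offspring draws two parents uniformly with
    replacement and receives one recombinant gamete from each.

    Parameters
    ----------
    recombination_rate : float or None
        Expected crossovers per chromosome (Morgans).  ``None`` uses each
        chromosome's map length; ``0`` transmits intact parental haplotypes.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    h = founders.n_haplotypes
    if h % 2 != 0:
        raise ValueError("founder haplotypes must pair into individuals (even count)")
    n_founders = h // 2
    rng = np.random.default_rng(seed)
    order = rng.permutation(h)
    haps = founders.haplotypes[order]
    mmap = founders.map
    slices = list(mmap.chrom_slices().values())
    lengths = []
    for sl in slices:
        span = float(mmap.genetic_position[sl.stop - 1] - mmap.genetic_position[sl.start])
        lengths.append(span if recombination_rate is None else float(recombination_rate))

    dosages = np.zeros((n_offspring, mmap.n_markers), dtype=np.int8)
    parents = rng.integers(n_founders, size=(n_offspring, 2))
    for i in range(n_offspring):
        for parent in parents[i]:
            ha, hb = haps[2 * parent], haps[2 * parent + 1]
            for sl, L in zip(slices, lengths):
                dosages[i, sl] += _gamete(rng, ha[sl], hb[sl],
                                          mmap.genetic_position[sl], L)
    ids = np.array([f"ind{i + 1}" for i in range(n_offspring)], dtype=object)
    return GenotypePanel(dosages, mmap, ids)


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one simulated panel."""

    n_individuals: int = 2000
    n_markers: int = 3000
    n_chromosomes: int = 10
    n_founder_haplotypes: int = 470
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    ld_strength: float = 0.8
    chrom_length: float = 1.0  # Morgans


def desk_config(n_individuals: int = 2000, n_markers: int = 3000) -> PanelConfig:
    """Desk-scale default: 2,000 individuals x 3,000 markers on 10 chromosomes."""
    return PanelConfig(n_individuals=n_individuals, n_markers=n_markers)


def maize_config() -> PanelConfig:
    """Full-scale maize-like panel: 10,000 individuals x 34,595 markers,
    bred from 235 founder lines (470 founder haplotypes)."""
    return PanelConfig(n_individuals=10_000, n_markers=34_595)


def simulate_panel(config: PanelConfig = PanelConfig(), seed: int = 0) -> GenotypePanel:
    """Founder haplotypes plus one round of random mating, per ``config``."""
    mmap = MarkerMap.equidistant(config.n_markers, config.n_chromosomes,
                                 config.chrom_length)
    founders = generate_founder_haplotypes(
        config.n_founder_haplotypes, mmap,
        allele_freq_range=config.allele_freq_range,
        ld_strength=config.ld_strength, seed=seed)
    return random_mating(founders, config.n_individuals, seed=seed + 1)
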