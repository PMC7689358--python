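"""VanRaden genomic relationship matrix."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import GenotypePanel

__all__ = ["GRM", "vanraden_grm"]


@dataclass(frozen=True)
class GRM:
    """n x n genomic relationship matrix G = ZZ' / (2 * sum p_j (1 - p_j)),
    with Z the dosage matrix centered at twice the allele frequency."""

    matrix: np.ndarray
    scaling_constant: float
    allele_freqs: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    def hadamard_square(self) -> np.ndarray:
        """Elementwise square G o G — the pairwise-epistasis kernel."""
        return self.matrix * self.matrix


def vanraden_grm(panel: GenotypePanel) -> GRM:
    """Compute the VanRaden GRM from a dosage panel.

    Allele frequencies are taken from the provided panel (train and test
    together when a full panel is passed — the single-G convention).
    Monomorphic markers have a zero centered column and a zero p(1-p) term,
    so they drop out of both numerator and denominator; a panel that is
    monomorphic everywhere has no genomic variance and is rejected.
    """
    freqs = panel.allele_frequencies()
    c = 2.0 * np.sum(freqs * (1.0 - freqs))
    if c <= 0.0:
        raise ValueError("all markers are monomorphic; the GRM scaling constant is zero")
    Z = panel.dosages.astype(np.float64) - 2.0 * freqs
    G = (Z @ Z.T) / c
    return GRM(G, float(c), freqs)
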