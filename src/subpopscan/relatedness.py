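"""Genomic relationship matrix, GRM-based inbreeding, and PCA of the GRM.

The GRM follows VanRaden's first method with the base allele frequency fixed
at 0.5: G = ZZ' / (2 m p0 (1 - p0)) with Z = dosage - 2 p0. With p0 = 0.5 the
centred dosages lie in {-1, 0, 1}, the scale factor is m/2, every diagonal
element lies in [0, 2], and the inbreeding coefficient F = G_ii - 1 reduces
algebraically to 1 - 2 * (observed heterozygosity of sample i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypePanel


@dataclass
class Grm:
    matrix: np.ndarray
    base_freq: float
    m: int
    samples: np.ndarray


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending
    variance_proportions: np.ndarray
    coordinates: np.ndarray          # samples x components
    samples: np.ndarray


def compute_grm(panel: GenotypePanel, base_freq: float = 0.5) -> Grm:
    if panel.n_snps == 0:
        raise ValueError("cannot compute a GRM from zero SNPs")
    if np.any(panel.dosage == MISSING):
        raise ValueError("GRM requires complete dosages (impute or QC first)")
    z = panel.dosage.astype(float) - 2.0 * base_freq
    denom = 2.0 * panel.n_snps * base_freq * (1.0 - base_freq)
    g = (z @ z.T) / denom
    return Grm(matrix=g, base_freq=base_freq, m=panel.n_snps, samples=panel.samples)


def f_grm(grm: Grm) -> np.ndarray:
    """Per-sample genomic inbreeding: diagonal minus one."""
    return np.diag(grm.matrix) - 1.0


def pca_grm(grm: Grm, n_components: int = 10) -> PcaResult:
    g = grm.matrix
    if not np.all(np.isfinite(g)):
        raise ValueError("GRM contains non-finite entries")
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    nonneg = np.clip(eigval, 0.0, None)
    total = nonneg.sum()
    proportions = nonneg / total if total > 0 else nonneg
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(nonneg[:k])[None, :]
    return PcaResult(eigenvalues=eigval, variance_proportions=proportions,
                     coordinates=coords, samples=grm.samples)
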