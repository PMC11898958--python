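"""Synthetic descriptor matrices, responses and endpoint tables.

The generators emulate the statistical structure the GA-MLR analysis
assumes: a wide compound x descriptor matrix with correlated blocks and
near-duplicate columns (as descriptor software produces), a response
that is linear in a small planted subset of descriptors plus Gaussian
noise, and an endpoint table with realistically correlated
chromatographic indices.  Everything is reproducible bit-for-bit from
a seed, so downstream stages are testable without external descriptor
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chrom_indices import percent_hsa_from_logk
from .datatypes import CompoundRecord, DescriptorMatrix, RetentionTable

__all__ = [
    "SyntheticDataset",
    "generate_descriptors",
    "generate_response",
    "generate_endpoint_table",
]


@dataclass
class SyntheticDataset:
    """A descriptor matrix with a planted linear response and its truth."""

    X: DescriptorMatrix
    y: np.ndarray
    true_support: list[str]
    true_coefficients: dict[str, float]
    intercept: float
    noise_sd: float
    seed: int
    signal: np.ndarray = field(repr=False, default=None)


def generate_descriptors(
    n_compounds: int,
    n_descriptors: int,
    block_correlation: float = 0.0,
    n_redundant: int = 0,
    seed: int = 0,
    block_size: int = 5,
) -> DescriptorMatrix:
    """Generate a compound x descriptor matrix.

    Base columns are standard normal.  With ``block_correlation`` = rho
    > 0, consecutive blocks of ``block_size`` columns share a latent
    factor: X = sqrt(rho)*F + sqrt(1-rho)*E, giving within-block
    pairwise correlation rho in expectation.  ``n_redundant`` extra
    columns are near-duplicates (r > 0.99) of the first base columns,
    named ``<base>_dup``, for pruning tests.
    """
    if n_compounds < 4:
        raise ValueError("need at least 4 compounds")
    if not (0.0 <= block_correlation < 1.0):
        raise ValueError("block_correlation must be in [0, 1)")
    n_base = n_descriptors - n_redundant
    if n_base <= 0:
        raise ValueError("n_redundant must be smaller than n_descriptors")
    if n_redundant > n_base:
        raise ValueError("cannot have more duplicates than base columns")
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n_compounds, n_base))
    if block_correlation > 0.0:
        n_blocks = int(np.ceil(n_base / block_size))
        F = rng.standard_normal((n_compounds, n_blocks))
        factors = np.repeat(F, block_size, axis=1)[:, :n_base]
        X = np.sqrt(block_correlation) * factors + np.sqrt(1.0 - block_correlation) * E
    else:
        X = E
    names = [f"D{i+1}" for i in range(n_base)]
    provenance = {n: "synthetic:base" for n in names}
    if n_redundant:
        dups = X[:, :n_redundant] + 0.01 * rng.standard_normal((n_compounds, n_redundant))
        X = np.hstack([X, dups])
        dup_names = [f"D{i+1}_dup" for i in range(n_redundant)]
        provenance.update({n: "synthetic:near-duplicate" for n in dup_names})
        names += dup_names
    compounds = [f"C{i+1:03d}" for i in range(n_compounds)]
    return DescriptorMatrix(X, compound_names=compounds, descriptor_names=names,
                            provenance=provenance)


def generate_response(
    X: DescriptorMatrix,
    support_size: int = 2,
    effect_scale: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    intercept: float = 0.0,
) -> SyntheticDataset:
    """Plant a linear response on a random descriptor subset.

    The support is drawn from the non-duplicate columns; coefficients
    have magnitude near ``effect_scale`` (uniform in [0.8, 1.2] times
    it) with random signs.  ``noise_sd`` is the absolute Gaussian noise
    standard deviation; pass ``noise_sd = 0.1 * signal sd`` for a
    10%-noise regime.
    """
    candidates = [n for n in X.descriptor_names
                  if X.provenance.get(n) != "synthetic:near-duplicate"]
    if support_size > len(candidates):
        raise ValueError(
            f"support_size {support_size} exceeds the {len(candidates)} non-duplicate descriptors"
        )
    rng = np.random.default_rng(seed)
    support = sorted(rng.choice(len(candidates), size=support_size, replace=False))
    support_names = [candidates[i] for i in support]
    signs = rng.choice([-1.0, 1.0], size=support_size)
    mags = effect_scale * rng.uniform(0.8, 1.2, size=support_size)
    coefs = {n: float(s * m) for n, s, m in zip(support_names, signs, mags)}
    signal = intercept + X.frame[support_names].to_numpy() @ np.array(list(coefs.values()))
    y = signal + rng.normal(0.0, noise_sd, size=signal.size) if noise_sd > 0 else signal.copy()
    return SyntheticDataset(
        X=X,
        y=y,
        true_support=support_names,
        true_coefficients=coefs,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
        signal=signal,
    )


def generate_endpoint_table(
    n_compounds: int,
    seed: int = 0,
    chi_correlation: float = 0.8,
    logk_correlation: float = 0.6,
) -> RetentionTable:
    """Generate a synthetic chromatographic-index table.

    CHI_C18 spans [20, 110] and CHI_IAM [15, 45] with correlation
    ``chi_correlation``; LogK_HSA is correlated with CHI_IAM at
    ``logk_correlation`` and spans roughly [-0.5, 1.3]; %HSA is
    computed exactly from LogK_HSA by the logistic transform, as in the
    measured table.
    """
    if n_compounds < 4:
        raise ValueError("need at least 4 compounds")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [1.0, chi_correlation, 0.0],
            [chi_correlation, 1.0, logk_correlation],
            [0.0, logk_correlation, 1.0],
        ]
    )
    # nearest-PD nudge for extreme correlation choices
    w, V = np.linalg.eigh(cov)
    cov = (V * np.clip(w, 1e-6, None)) @ V.T
    z = rng.multivariate_normal(np.zeros(3), cov, size=n_compounds)
    u = 0.5 * (1.0 + np.tanh(z / 2.0))  # squash to (0, 1), keeps rank correlation
    chi_c18 = 20.0 + 90.0 * u[:, 0]
    chi_iam = 15.0 + 30.0 * u[:, 1]
    logk = -0.5 + 1.8 * u[:, 2]
    pct = percent_hsa_from_logk(logk)
    records = [
        CompoundRecord(
            id=i + 1,
            name=f"Synthetic-{i+1:03d}",
            chi_c18=float(chi_c18[i]),
            chi_iam=float(chi_iam[i]),
            logk_hsa=float(logk[i]),
            pct_hsa=float(pct[i]),
        )
        for i in range(n_compounds)
    ]
    return RetentionTable(records)
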