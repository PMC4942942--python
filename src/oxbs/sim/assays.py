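"""Simulators for the orthogonal assays: qPCR dilution series, chip-based
digital PCR, and mC/hmC ELISA plates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..rng import substream

__all__ = ["simulate_qpcr_dilution", "simulate_dpcr", "simulate_elisa"]


def simulate_qpcr_dilution(per_cycle_amplification: float = 1.75,
                           ct_at_1000ng: float = 22.0,
                           quantities=(1000.0, 750.0, 500.0, 250.0, 125.0),
                           noise_sd: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Ct values for an input-dilution series.

    Noiseless model: Ct(Q) = Ct(1000) - log_b(Q / 1000) where b is the
    per-cycle amplification factor (2 = perfect doubling, 1.75 = the
    DNMT3a2-assay default).
    """
    if not 1.0 < per_cycle_amplification <= 2.0:
        raise ValueError("per-cycle amplification must lie in (1, 2]")
    q = np.asarray(quantities, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    ct = ct_at_1000ng - np.log(q / 1000.0) / np.log(per_cycle_amplification)
    if noise_sd > 0:
        ct = ct + substream(seed, "assays", "qpcr").normal(0.0, noise_sd, size=len(q))
    return pd.DataFrame({"quantity": q, "ct": ct})


def simulate_dpcr(lambda_per_partition: float, n_partitions: int = 20_000,
                  seed: int = 0) -> tuple:
    """(positives, negatives) well counts on a digital-PCR chip.

    Template molecules land in partitions Poisson(lambda); a partition is
    positive iff it received >= 1 copy, so
    positives ~ Binomial(n, 1 - exp(-lambda)).
    """
    if lambda_per_partition < 0:
        raise ValueError("lambda must be non-negative")
    p_pos = 1.0 - np.exp(-lambda_per_partition)
    rng = substream(seed, "assays", "dpcr")
    positives = int(rng.binomial(n_partitions, p_pos))
    return positives, n_partitions - positives


def simulate_elisa(true_mc_fraction: float,
                   sample_density: float = 0.01,
                   standard_density: float = 0.05,
                   curve=(0.05, 10.0),
                   standard_percents=(0.0, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0),
                   noise_sd: float = 0.0,
                   n_sample_reps: int = 3,
                   seed: int = 0) -> dict:
    """Absorbances for a standard curve plus sample technical replicates.

    Absorbance is affine in the per-base modified-cytosine density:
    A = a0 + a1 * (modified fraction) * (CG-cytosine density of the
    material).  Standards are mixtures of 0 % and 100 % modified material
    built at ``standard_density``; when that density exceeds the sample
    genome's, interpolation understates the sample's true fraction by the
    density ratio.
    """
    a0, a1 = curve
    rng = substream(seed, "assays", "elisa")
    pct = np.asarray(standard_percents, dtype=float)
    std_abs = a0 + a1 * (pct / 100.0) * standard_density
    smp_abs = np.full(n_sample_reps, a0 + a1 * true_mc_fraction * sample_density)
    if noise_sd > 0:
        std_abs = std_abs + rng.normal(0.0, noise_sd, size=len(std_abs))
        smp_abs = smp_abs + rng.normal(0.0, noise_sd, size=len(smp_abs))
    return {
        "standards": pd.DataFrame({"percent": pct, "absorbance": std_abs}),
        "sample_absorbances": smp_abs,
        "density_ratio": standard_density / sample_density,
    }
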