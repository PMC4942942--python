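"""Paired BS/oxBS per-cytosine count tables from a ground-truth methylome.

Depth at each site is Poisson around the target coverage (independently in
the two libraries); C/T calls are Binomial with the chemistry model's
per-read unconverted probability.  Zero-depth sites are emitted with zero
counts; downstream estimation excludes them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..chemistry import ChemistryParams, p_unconverted_bs, p_unconverted_oxbs

__all__ = ["simulate_counts", "write_cytosine_report", "read_cytosine_report"]

REPORT_COLUMNS = [
    "chrom", "pos", "strand", "count_modified", "count_unmodified",
    "context", "trinucleotide",
]


def _library_counts(sites: pd.DataFrame, p_c: np.ndarray, coverage: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    depth = rng.poisson(coverage, size=len(sites))
    c_calls = rng.binomial(depth, p_c)
    df = sites[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    df["count_modified"] = c_calls
    df["count_unmodified"] = depth - c_calls
    return df


def simulate_counts(truth, chemistry: ChemistryParams, coverage: float,
                    rng: np.random.Generator):
    """Simulate one sample's (BS, oxBS) cytosine count tables.

    ``truth`` is a MethylomeTruth; returns two DataFrames with columns
    chrom, pos (0-based), strand, context, trinucleotide, count_modified,
    count_unmodified.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    m, h = truth.m, truth.h
    if np.any(m + h > 1.0 + 1e-12):
        raise ValueError("truth violates m + h <= 1")
    p_bs = np.clip(p_unconverted_bs(m, h, chemistry), 0.0, 1.0)
    p_ox = np.clip(p_unconverted_oxbs(m, h, chemistry), 0.0, 1.0)
    bs = _library_counts(truth.sites, p_bs, coverage, rng)
    oxbs = _library_counts(truth.sites, p_ox, coverage, rng)
    return bs, oxbs


def write_cytosine_report(counts: pd.DataFrame, path) -> None:
    """Bismark-cytosine-report-style TSV (1-based positions, no header)."""
    out = counts[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS)
    df["pos"] = df["pos"] - 1
    return df
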