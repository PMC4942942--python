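"""Conversion QC from spike-in controls.

The bisulfite rate beta is the converted (T) fraction at unmodified-C
spike-in sites, estimated separately in each library.  The oxidation
efficiency omega is the converted fraction at 5hmC sites in the oxBS
library divided by that library's own bisulfite rate, which isolates
oxidation from conversion.  5mC spike-in sites are reported descriptively
(protection failure) and no correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionEstimate",
    "estimate_bisulfite_rate",
    "estimate_oxidation_rate",
    "summarize_sample",
    "gate_samples",
]


class UndefinedEstimateError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionEstimate:
    value: float
    se: float
    n_reads: int
    clipped: bool = False


def _binomial_rate(successes: int, total: int) -> ConversionEstimate:
    if total <= 0:
        raise UndefinedEstimateError("zero total coverage at spike-in sites")
    p = successes / total
    se = float(np.sqrt(p * (1.0 - p) / total))
    return ConversionEstimate(value=p, se=se, n_reads=total)


def estimate_bisulfite_rate(spikeins, library: str) -> ConversionEstimate:
    """beta: T fraction at unmodified-C sites in the named library."""
    c, t = spikeins.class_totals("unmodified", library)
    return _binomial_rate(t, c + t)


def estimate_protection_failure(spikeins, library: str) -> ConversionEstimate:
    """Descriptive eps_m: T fraction at 5mC sites."""
    c, t = spikeins.class_totals("mC", library)
    return _binomial_rate(t, c + t)


def estimate_oxidation_rate(spikeins) -> ConversionEstimate:
    """omega = (T fraction at hmC sites in oxBS) / beta_oxBS.

    Standard error by the delta method for the ratio; values above 1 are
    clipped with a flag.
    """
    beta_ox = estimate_bisulfite_rate(spikeins, "oxBS")
    if beta_ox.value == 0:
        raise UndefinedEstimateError("oxBS bisulfite rate is zero; omega undefined")
    c, t = spikeins.class_totals("hmC", "oxBS")
    t_frac = _binomial_rate(t, c + t)
    omega = t_frac.value / beta_ox.value
    rel_var = 0.0
    if t_frac.value > 0:
        rel_var += (t_frac.se / t_frac.value) ** 2
    rel_var += (beta_ox.se / beta_ox.value) ** 2
    se = float(omega * np.sqrt(rel_var))
    clipped = omega > 1.0
    return ConversionEstimate(
        value=min(omega, 1.0), se=se, n_reads=t_frac.n_reads, clipped=clipped
    )


def summarize_sample(spikeins, sample_id: str = "sample") -> pd.DataFrame:
    """Tidy per-sample conversion QC table."""
    beta_bs = estimate_bisulfite_rate(spikeins, "BS")
    beta_ox = estimate_bisulfite_rate(spikeins, "oxBS")
    omega = estimate_oxidation_rate(spikeins)
    eps_m = estimate_protection_failure(spikeins, "BS")
    return pd.DataFrame(
        [
            {"sample_id": sample_id, "metric": "beta_bs", "value": beta_bs.value,
             "se": beta_bs.se, "clipped": False},
            {"sample_id": sample_id, "metric": "beta_oxbs", "value": beta_ox.value,
             "se": beta_ox.se, "clipped": False},
            {"sample_id": sample_id, "metric": "omega", "value": omega.value,
             "se": omega.se, "clipped": omega.clipped},
            {"sample_id": sample_id, "metric": "eps_m", "value": eps_m.value,
             "se": eps_m.se, "clipped": False},
        ]
    )


def gate_samples(estimates: pd.DataFrame, beta_min: float = 0.99,
                 omega_min: float = 0.97, strict: bool = False) -> pd.DataFrame:
    """Flag samples whose conversion estimates fall below threshold.

    ``estimates`` is the long table from :func:`summarize_sample` (possibly
    concatenated over samples).  Thresholds are per-sample minima.  In
    strict mode a failing sample raises; otherwise failures are flagged.
    """
    if len(estimates) == 0:
        return pd.DataFrame(columns=["sample_id", "beta_bs", "beta_oxbs", "omega", "passed"])
    wide = estimates.pivot_table(index="sample_id", columns="metric", values="value")
    rows = []
    for sample_id, row in wide.iterrows():
        beta_ok = row.get("beta_bs", np.nan) >= beta_min and row.get("beta_oxbs", np.nan) >= beta_min
        omega_ok = row.get("omega", np.nan) >= omega_min
        rows.append(
            {
                "sample_id": sample_id,
                "beta_bs": row.get("beta_bs", np.nan),
                "beta_oxbs": row.get("beta_oxbs", np.nan),
                "omega": row.get("omega", np.nan),
                "passed_bisulfite": bool(beta_ok),
                "passed_oxidation": bool(omega_ok),
                "passed": bool(beta_ok and omega_ok),
            }
        )
    out = pd.DataFrame(rows)
    if strict and not out["passed"].all():
        bad = out.loc[~out["passed"], "sample_id"].tolist()
        raise ValueError(f"conversion QC failed for samples: {bad}")
    return out
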