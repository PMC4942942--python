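"""Quantitation math for the orthogonal assays.

qPCR: amplification efficiency from the slope of Ct vs log10(input), and
efficiency-corrected ddCt fold changes, fold = (1 + E)^(-ddCt).  With
E = 1 this is the familiar 2^(-ddCt); with the 75 %-efficient assays it
becomes the 1.75-base rule.  Assuming perfect efficiency when the true
per-cycle factor is below 2 systematically overstates fold changes above 1.

dPCR: Poisson partition counting, lambda = -ln(negative fraction), scaled
to copies/uL and copies per ug of input by the dilution bookkeeping.

ELISA: linear standard-curve interpolation, with a CG-density correction
for standards built from material denser in CG cytosines than the sample
genome (raw % x density ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "EfficiencyEstimate",
    "fit_efficiency",
    "ddct_fold_change",
    "DpcrQuant",
    "dpcr_copies",
    "elisa_quantify",
]

DEFAULT_PARTITION_VOLUME_UL = 8.09e-4  # QuantStudio-3D-class chip partition


@dataclass(frozen=True)
class EfficiencyEstimate:
    slope: float
    intercept: float
    efficiency: float  # fraction: 1.0 = perfect doubling
    r_squared: float

    @property
    def per_cycle_amplification(self) -> float:
        return 1.0 + self.efficiency


def fit_efficiency(series: pd.DataFrame) -> EfficiencyEstimate:
    """Efficiency from a dilution series (columns ``quantity``, ``ct``).

    Least-squares slope of Ct on log10(quantity); E = 10^(-1/slope) - 1.
    A slope of -3.3219 corresponds to E = 1 (perfect doubling).
    """
    q = np.asarray(series["quantity"], dtype=float)
    ct = np.asarray(series["ct"], dtype=float)
    if len(np.unique(q)) < 3:
        raise ValueError("dilution series needs >= 3 distinct quantities")
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    fit = linregress(np.log10(q), ct)
    if fit.slope >= 0:
        raise ValueError(f"non-negative slope {fit.slope:.3f}: no amplification signal")
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyEstimate(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
    )


def ddct_fold_change(ct_table: pd.DataFrame, calibrator_group: str,
                     efficiency: float = 1.0) -> pd.DataFrame:
    """Efficiency-corrected ddCt fold changes relative to a calibrator group.

    ``ct_table`` columns: sample_id, group, ct_target, ct_reference.
    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean dCt of the
    calibrator group; fold = (1 + E)^(-ddCt).
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table lacks columns: {sorted(missing)}")
    if ct_table[["ct_target", "ct_reference"]].isna().any().any():
        bad = ct_table.loc[
            ct_table[["ct_target", "ct_reference"]].isna().any(axis=1), "sample_id"
        ].tolist()
        raise ValueError(f"missing Ct values for samples: {bad}")
    if not -1.0 < efficiency:
        raise ValueError("efficiency must exceed -1")
    out = ct_table.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    cal = out.loc[out["group"] == calibrator_group, "dct"]
    if len(cal) == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    out["ddct"] = out["dct"] - cal.mean()
    out["fold_change"] = (1.0 + efficiency) ** (-out["ddct"])
    return out


@dataclass(frozen=True)
class DpcrQuant:
    positives: int
    total: int
    lam: float              # mean copies per partition
    copies_per_ul: float
    copies_per_ug: float


def dpcr_copies(positives: int, total: int,
                partition_volume: float = DEFAULT_PARTITION_VOLUME_UL,
                dilution_factor: float = 1.0,
                template_volume: float = 3.33,
                rxn_template_mass_ug: float = 0.1665) -> DpcrQuant:
    """Absolute quantification from digital-PCR well counts.

    lambda = -ln(1 - positives/total); copies/uL = lambda / partition
    volume (uL); copies per ug of input = copies/uL x template volume (uL)
    x dilution factor / template mass (ug), assuming 1:1 RNA->cDNA
    carryover.  Defaults reflect 3.33 uL of a 50 ng/uL template load.
    """
    if total <= 0:
        raise ValueError("total partitions must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    if positives == total:
        raise ValueError("chip saturated (all partitions positive): lambda undefined")
    lam = float(-np.log(1.0 - positives / total))
    copies_per_ul = lam / partition_volume
    copies_per_ug = copies_per_ul * template_volume * dilution_factor / rxn_template_mass_ug
    return DpcrQuant(positives=int(positives), total=int(total), lam=lam,
                     copies_per_ul=copies_per_ul, copies_per_ug=copies_per_ug)


def elisa_quantify(standards: pd.DataFrame, sample_absorbances,
                   density_ratio: float = 1.0) -> dict:
    """Interpolate sample modification levels on a linear standard curve.

    ``standards`` columns: percent (modified), absorbance.  Raw % comes
    from inverting the least-squares line; corrected % = raw % x
    density_ratio (the standard's CG-cytosine density over the sample
    genome's).  Samples outside the standard absorbance range are flagged
    as extrapolated.
    """
    if len(standards) < 2:
        raise ValueError("need >= 2 standard points")
    if density_ratio <= 0:
        raise ValueError("density_ratio must be positive")
    fit = linregress(standards["percent"], standards["absorbance"])
    if fit.slope == 0:
        raise ValueError("flat standard curve")
    a = np.asarray(sample_absorbances, dtype=float)
    raw = (a - fit.intercept) / fit.slope
    lo, hi = standards["absorbance"].min(), standards["absorbance"].max()
    extrapolated = bool(np.any((a < lo) | (a > hi)))
    return {
        "raw_percent": float(np.mean(raw)),
        "raw_sd": float(np.std(raw, ddof=1)) if len(a) > 1 else 0.0,
        "corrected_percent": float(np.mean(raw) * density_ratio),
        "replicates": raw,
        "extrapolated": extrapolated,
        "r_squared": float(fit.rvalue**2),
    }
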