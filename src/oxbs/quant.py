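"""Core mC/hmC estimation by BS-minus-oxBS differencing.

The oxBS library reads out 5mC alone; the BS library reads out 5mC + 5hmC.
Levels are modified-call fractions (count_modified / total).  hmC is the
difference of the two readouts.  Differencing happens on pooled levels:
per-site hmC is exposed for diagnostics with clamping at zero (negative
site differences are sampling noise), but BS and oxBS readouts are always
pooled separately before subtraction so no clamping bias enters aggregates.

Pooling is count-weighted: pooled level = sum(modified) / sum(total) over
the group's sites, identical to the coverage-weighted mean of site levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "site_levels",
    "corrected_levels",
    "pool_levels",
    "pooled_pair",
    "chromosome_summary",
]

SITE_KEY = ["chrom", "pos", "strand"]


class SiteKeyMismatch(ValueError):
    pass


class FemaleChrYError(ValueError):
    """A sample labelled female carries chrY records: design/label mismatch."""


def site_levels(bs: pd.DataFrame, oxbs: pd.DataFrame, min_depth: int = 1) -> pd.DataFrame:
    """Per-site level estimates from paired count tables.

    Sites below ``min_depth`` in either library are excluded.  Columns
    level_bs, level_oxbs, mc (= level_oxbs), hmc_raw (= difference) and
    hmc (clamped at 0) are added.
    """
    merged = bs.merge(
        oxbs, on=SITE_KEY + ["context", "trinucleotide"],
        suffixes=("_bs", "_oxbs"), how="outer", indicator=True,
    )
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", SITE_KEY].head()
        raise SiteKeyMismatch(f"BS/oxBS tables disagree on site keys, e.g.\n{bad}")
    merged = merged.drop(columns="_merge")
    merged["depth_bs"] = merged["count_modified_bs"] + merged["count_unmodified_bs"]
    merged["depth_oxbs"] = merged["count_modified_oxbs"] + merged["count_unmodified_oxbs"]
    merged = merged[(merged["depth_bs"] >= min_depth) & (merged["depth_oxbs"] >= min_depth)]
    merged = merged.copy()
    merged["level_bs"] = merged["count_modified_bs"] / merged["depth_bs"]
    merged["level_oxbs"] = merged["count_modified_oxbs"] / merged["depth_oxbs"]
    merged["mc"] = merged["level_oxbs"]
    merged["hmc_raw"] = merged["level_bs"] - merged["level_oxbs"]
    merged["hmc"] = merged["hmc_raw"].clip(lower=0.0)
    return merged


def corrected_levels(level_bs, level_oxbs, beta: float, omega: float):
    """Invert the conversion chemistry to recover (m, h) from the readouts.

    With conversion rate beta and oxidation efficiency omega (and no
    protection failure) the expected readouts are

        L_BS = (1 - beta) + beta (m + h)
        L_ox = (1 - beta) + beta (m + h (1 - omega))

    giving h = (L_BS - L_ox) / (omega beta) and
    m = (L_BS - (1 - beta)) / beta - h.  Estimates are clipped to the
    simplex {m >= 0, h >= 0, m + h <= 1}; returns (m, h, clipped_flag).
    """
    if beta <= 0 or omega <= 0:
        raise ValueError("corrected_levels undefined for omega * beta == 0")
    L_bs = np.asarray(level_bs, dtype=float)
    L_ox = np.asarray(level_oxbs, dtype=float)
    h = (L_bs - L_ox) / (omega * beta)
    m = (L_bs - (1.0 - beta)) / beta - h
    clipped = (m < 0) | (h < 0) | (m + h > 1)
    m_c = np.clip(m, 0.0, 1.0)
    h_c = np.clip(h, 0.0, 1.0)
    over = m_c + h_c > 1.0
    h_c = np.where(over, 1.0 - m_c, h_c)
    if np.isscalar(level_bs) and np.isscalar(level_oxbs):
        return float(m_c), float(h_c), bool(np.any(clipped))
    return m_c, h_c, clipped


def pool_levels(records: pd.DataFrame, grouping) -> pd.DataFrame:
    """Count-weighted pooled level per group of a single library's records.

    ``grouping`` is a column name, list of names, or precomputed key
    array.  Empty groups cannot occur (groupby on present keys); zero-read
    groups are dropped.
    """
    g = records.groupby(grouping, observed=True)
    out = g.agg(
        modified=("count_modified", "sum"),
        unmodified=("count_unmodified", "sum"),
        n_sites=("count_modified", "size"),
    )
    out["reads"] = out["modified"] + out["unmodified"]
    out = out[out["reads"] > 0].copy()
    out["level"] = out["modified"] / out["reads"]
    return out


def pooled_pair(bs: pd.DataFrame, oxbs: pd.DataFrame, mask=None) -> dict:
    """Pooled BS and oxBS levels (and mc/hmc) over an optional site mask."""
    if mask is not None:
        bs = bs[mask]
        oxbs = oxbs[mask]
    tot_bs = int(bs["count_modified"].sum() + bs["count_unmodified"].sum())
    tot_ox = int(oxbs["count_modified"].sum() + oxbs["count_unmodified"].sum())
    level_bs = bs["count_modified"].sum() / tot_bs if tot_bs else np.nan
    level_ox = oxbs["count_modified"].sum() / tot_ox if tot_ox else np.nan
    return {
        "level_bs": level_bs,
        "level_oxbs": level_ox,
        "mc": level_ox,
        "hmc": max(level_bs - level_ox, 0.0) if tot_bs and tot_ox else np.nan,
        "n_sites": int(len(bs)),
        "reads_bs": tot_bs,
        "reads_oxbs": tot_ox,
    }


def chromosome_summary(bs: pd.DataFrame, oxbs: pd.DataFrame, sample_id: str,
                       sex: str, autosomes=None) -> pd.DataFrame:
    """Per-sample pooled levels by chromosome class and context.

    Autosomes are pooled together; chrX and chrY are reported separately;
    contexts CG and CH (CHG+CHH rollup) are summarised separately.  A
    female sample containing chrY records raises, signalling a design
    mismatch.
    """
    chroms = bs["chrom"].unique()
    if autosomes is None:
        autosomes = [c for c in chroms if c not in ("chrX", "chrY")]
    has_y = bool((bs["chrom"] == "chrY").any() or (oxbs["chrom"] == "chrY").any())
    if sex == "female" and has_y:
        raise FemaleChrYError(
            f"sample {sample_id} is labelled female but carries chrY records"
        )
    classes = [("autosomes", bs["chrom"].isin(autosomes).to_numpy())]
    if (bs["chrom"] == "chrX").any():
        classes.append(("chrX", (bs["chrom"] == "chrX").to_numpy()))
    if has_y:
        classes.append(("chrY", (bs["chrom"] == "chrY").to_numpy()))
    is_cg = (bs["context"] == "CG").to_numpy()
    rows = []
    for cls, cls_mask in classes:
        for context, ctx_mask in (("CG", is_cg), ("CH", ~is_cg)):
            pooled = pooled_pair(bs, oxbs, cls_mask & ctx_mask)
            pooled.update(
                sample_id=sample_id, sex=sex, chrom_class=cls, context=context
            )
            rows.append(pooled)
    cols = ["sample_id", "sex", "chrom_class", "context", "level_bs", "level_oxbs",
            "mc", "hmc", "n_sites", "reads_bs", "reads_oxbs"]
    return pd.DataFrame(rows)[cols]
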