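"""CGI shores/shelves, promoter bins, meta-profiles and region aggregates.

Conventions: shores occupy 0-2 kb and shelves 2-4 kb from the island edge
on each side; flanks of neighbouring islands are truncated at the midpoint
between the islands; promoter bins tile TSS +/- flank in the gene's 5'->3'
orientation.  Meta-profiles pool read counts within each element's bin and
then average elements unweighted (each CGI/promoter counts once); bins
with no covered site in an element simply drop that element from the bin's
mean -- missing is not zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "derive_flanks",
    "promoter_bins",
    "promoter_superbins",
    "cgi_flank_bins",
    "CountIndex",
    "profile_elements",
    "region_aggregates",
    "repeat_surrogate",
]

FLANK_CLASSES = ["island", "shore_up", "shore_down", "shelf_up", "shelf_down"]


def derive_flanks(cgis: pd.DataFrame, shore_width: int = 2000, shelf_width: int = 2000,
                  chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Shore and shelf intervals for each island.

    "up" means lower genomic coordinates (islands are unstranded).  Flanks
    are truncated at chromosome bounds and at the midpoint between
    neighbouring islands; truncation is flagged.
    """
    if shore_width < 0 or shelf_width < 0:
        raise ValueError("shore/shelf widths must be non-negative")
    rows = []
    for chrom, sub in cgis.groupby("chrom", observed=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy() if "name" in sub else np.arange(len(sub)).astype(str)
        chrom_len = chrom_lengths.get(chrom) if chrom_lengths else None
        for i in range(len(sub)):
            left_limit = 0 if i == 0 else int((ends[i - 1] + starts[i]) // 2)
            right_limit = (
                (chrom_len if chrom_len is not None else np.iinfo(np.int64).max)
                if i == len(sub) - 1
                else int((ends[i] + starts[i + 1]) // 2)
            )
            spec = [
                ("island", starts[i], ends[i]),
                ("shore_up", starts[i] - shore_width, starts[i]),
                ("shelf_up", starts[i] - shore_width - shelf_width, starts[i] - shore_width),
                ("shore_down", ends[i], ends[i] + shore_width),
                ("shelf_down", ends[i] + shore_width, ends[i] + shore_width + shelf_width),
            ]
            for rtype, s, e in spec:
                cs = max(s, left_limit if rtype != "island" else s)
                ce = min(e, right_limit if rtype != "island" else e)
                if chrom_len is not None:
                    cs, ce = max(cs, 0), min(ce, chrom_len)
                else:
                    cs = max(cs, 0)
                if ce <= cs:
                    continue
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(cs),
                        "end": int(ce),
                        "region_type": rtype,
                        "element_id": names[i],
                        "truncated": bool((cs, ce) != (s, e)),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_type",
                                       "element_id", "truncated"])


def promoter_bins(promoters: pd.DataFrame, flank: int = 2000,
                  bin_width: int = 100, chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Oriented promoter bins: indices -k..-1 upstream and +1..+k downstream
    of the TSS in the gene's 5'->3' direction (k = flank / bin_width)."""
    if flank % bin_width:
        raise ValueError("flank must be a multiple of bin_width")
    k = flank // bin_width
    rows = []
    for p in promoters.itertuples():
        chrom_len = chrom_lengths.get(p.chrom) if chrom_lengths else None
        for j in range(1, k + 1):
            for sign in (-1, +1):
                idx = sign * j
                if p.strand == "+":
                    if idx > 0:
                        s, e = p.tss + (j - 1) * bin_width, p.tss + j * bin_width
                    else:
                        s, e = p.tss - j * bin_width, p.tss - (j - 1) * bin_width
                else:  # minus-strand gene: genomic coordinates mirrored
                    if idx > 0:
                        s, e = p.tss - j * bin_width, p.tss - (j - 1) * bin_width
                    else:
                        s, e = p.tss + (j - 1) * bin_width, p.tss + j * bin_width
                cs = max(s, 0)
                ce = min(e, chrom_len) if chrom_len is not None else e
                if ce <= cs:
                    continue
                rows.append(
                    {
                        "chrom": p.chrom,
                        "start": int(cs),
                        "end": int(ce),
                        "region_type": f"bin_{idx:+d}",
                        "bin_index": idx,
                        "element_id": p.name,
                        "truncated": bool((cs, ce) != (s, e)),
                    }
                )
    return pd.DataFrame(rows)


def promoter_superbins(promoters: pd.DataFrame,
                       chrom_lengths: dict | None = None) -> pd.DataFrame:
    """1-kb promoter super-bins (-2..-1, -1..0, 0..+1, +1..+2 kb of TSS)."""
    bins = promoter_bins(promoters, flank=2000, bin_width=1000,
                         chrom_lengths=chrom_lengths)
    label = {-2: "prom_-2kb", -1: "prom_-1kb", 1: "prom_+1kb", 2: "prom_+2kb"}
    bins["region_type"] = bins["bin_index"].map(label)
    return bins


def cgi_flank_bins(cgis: pd.DataFrame, n_bins: int = 20, bin_width: int = 200,
                   chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Edge-anchored bins across CGI flanks plus one whole-island bin.

    Bin indices -n_bins..-1 run up to the island start, +1..+n_bins from the
    island end; index 0 is the variable-length island body.
    """
    rows = []
    for c in cgis.itertuples():
        chrom_len = chrom_lengths.get(c.chrom) if chrom_lengths else None
        entries = [(0, c.start, c.end)]
        for j in range(1, n_bins + 1):
            entries.append((-j, c.start - j * bin_width, c.start - (j - 1) * bin_width))
            entries.append((+j, c.end + (j - 1) * bin_width, c.end + j * bin_width))
        for idx, s, e in entries:
            cs = max(s, 0)
            ce = min(e, chrom_len) if chrom_len is not None else e
            if ce <= cs:
                continue
            rows.append(
                {
                    "chrom": c.chrom,
                    "start": int(cs),
                    "end": int(ce),
                    "region_type": "island" if idx == 0 else f"flank_{idx:+d}",
                    "bin_index": idx,
                    "element_id": c.name,
                    "truncated": bool((cs, ce) != (s, e)),
                }
            )
    return pd.DataFrame(rows)


class CountIndex:
    """Per-chromosome cumulative count sums for O(log n) interval pooling."""

    def __init__(self, counts: pd.DataFrame, context: str | None = "CG"):
        df = counts
        if context is not None:
            if context == "CH":
                df = df[df["context"].isin(["CHG", "CHH"])]
            else:
                df = df[df["context"] == context]
        self._by_chrom = {}
        for chrom, sub in df.groupby("chrom", observed=True):
            sub = sub.sort_values("pos", kind="stable")
            pos = sub["pos"].to_numpy(dtype=np.int64)
            mod = np.concatenate([[0], np.cumsum(sub["count_modified"].to_numpy(dtype=np.int64))])
            unmod = np.concatenate([[0], np.cumsum(sub["count_unmodified"].to_numpy(dtype=np.int64))])
            self._by_chrom[chrom] = (pos, mod, unmod)

    def interval_sums(self, chrom: str, starts, ends):
        """(modified, unmodified) read-count sums per interval."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        if chrom not in self._by_chrom:
            z = np.zeros(len(starts), dtype=np.int64)
            return z, z.copy()
        pos, mod, unmod = self._by_chrom[chrom]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        return mod[hi] - mod[lo], unmod[hi] - unmod[lo]


def _interval_counts(regions: pd.DataFrame, index: CountIndex) -> pd.DataFrame:
    out = regions.copy()
    mod = np.zeros(len(regions), dtype=np.int64)
    unmod = np.zeros(len(regions), dtype=np.int64)
    for chrom, sub in regions.groupby("chrom", observed=True):
        m, u = index.interval_sums(chrom, sub["start"].to_numpy(), sub["end"].to_numpy())
        mod[sub.index] = m
        unmod[sub.index] = u
    out["mod"] = mod
    out["unmod"] = unmod
    return out


def profile_elements(bs_counts: pd.DataFrame, oxbs_counts: pd.DataFrame,
                     bin_regions: pd.DataFrame, context: str = "CG") -> pd.DataFrame:
    """Meta-profile over binned elements.

    Per element-bin, counts are pooled; the profile value is the unweighted
    mean over elements with coverage in that bin.  hmC per bin is the
    pooled BS minus pooled oxBS level of each element-bin, averaged.
    """
    if len(bin_regions) == 0:
        raise ValueError("empty region set")
    regions = bin_regions.reset_index(drop=True)
    bs = _interval_counts(regions, CountIndex(bs_counts, context))
    ox = _interval_counts(regions, CountIndex(oxbs_counts, context))
    tot_bs = bs["mod"] + bs["unmod"]
    tot_ox = ox["mod"] + ox["unmod"]
    covered = (tot_bs > 0) & (tot_ox > 0)
    level_bs = np.where(covered, bs["mod"] / np.where(tot_bs > 0, tot_bs, 1), np.nan)
    level_ox = np.where(covered, ox["mod"] / np.where(tot_ox > 0, tot_ox, 1), np.nan)
    per_bin = pd.DataFrame(
        {
            "bin_index": regions["bin_index"],
            "region_type": regions["region_type"],
            "mc": level_ox,
            "hmc": np.clip(level_bs - level_ox, 0.0, None),
            "covered": covered,
        }
    )
    grouped = per_bin[per_bin["covered"]].groupby("bin_index", sort=True)
    out = grouped.agg(mc=("mc", "mean"), hmc=("hmc", "mean"), n_elements=("mc", "size"))
    out = out.reset_index()
    type_map = per_bin.drop_duplicates("bin_index").set_index("bin_index")["region_type"]
    out["region_type"] = out["bin_index"].map(type_map)
    return out


def region_aggregates(bs_counts: pd.DataFrame, oxbs_counts: pd.DataFrame,
                      regions: pd.DataFrame, context: str = "CG") -> pd.DataFrame:
    """Pooled mc/hmc per region class (column ``region_type``).

    All member intervals of a class are pooled count-wise, matching the
    core pooling identity: level = sum(modified) / sum(total).
    """
    regions = regions.reset_index(drop=True)
    bs = _interval_counts(regions, CountIndex(bs_counts, context))
    ox = _interval_counts(regions, CountIndex(oxbs_counts, context))
    rows = []
    for rtype, sub in bs.groupby("region_type", sort=False):
        oxsub = ox.loc[sub.index]
        tot_bs = int(sub["mod"].sum() + sub["unmod"].sum())
        tot_ox = int(oxsub["mod"].sum() + oxsub["unmod"].sum())
        if tot_bs == 0 or tot_ox == 0:
            continue
        level_bs = sub["mod"].sum() / tot_bs
        level_ox = oxsub["mod"].sum() / tot_ox
        rows.append(
            {
                "region_type": rtype,
                "level_bs": level_bs,
                "level_oxbs": level_ox,
                "mc": level_ox,
                "hmc": max(level_bs - level_ox, 0.0),
                "reads_bs": tot_bs,
                "reads_oxbs": tot_ox,
            }
        )
    return pd.DataFrame(rows)


def repeat_surrogate(bs_counts: pd.DataFrame, repeats: pd.DataFrame,
                     context: str = "CG") -> dict:
    """Pooled BS-library level over repeats (the pyrosequencing surrogate:
    mC+hmC combined, no oxBS subtraction) next to the genome-wide BS level."""
    if len(repeats) == 0:
        warnings.warn("no repeat annotation; repeat surrogate is empty")
        return {"repeat_bs_level": np.nan, "genome_bs_level": np.nan, "n_reads": 0}
    index = CountIndex(bs_counts, context)
    regions = repeats.reset_index(drop=True).copy()
    regions["region_type"] = "repeat"
    counted = _interval_counts(regions, index)
    mod, unmod = counted["mod"].sum(), counted["unmod"].sum()
    if context == "CH":
        sel = bs_counts["context"].isin(["CHG", "CHH"])
    else:
        sel = bs_counts["context"] == context
    g = bs_counts[sel]
    g_tot = g["count_modified"].sum() + g["count_unmodified"].sum()
    return {
        "repeat_bs_level": mod / (mod + unmod) if mod + unmod else np.nan,
        "genome_bs_level": g["count_modified"].sum() / g_tot if g_tot else np.nan,
        "n_reads": int(mod + unmod),
    }
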