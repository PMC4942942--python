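"""Small interval utilities on 0-based half-open coordinates."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_intervals", "positions_in_intervals"]


def merge_intervals(starts, ends):
    """Merge possibly overlapping intervals; returns sorted disjoint arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def positions_in_intervals(positions, starts, ends) -> np.ndarray:
    """Boolean mask: which positions fall inside any interval."""
    positions = np.asarray(positions, dtype=np.int64)
    starts, ends = merge_intervals(starts, ends)
    if len(starts) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(starts, positions, side="right") - 1
    mask = idx >= 0
    mask[mask] = positions[mask] < ends[idx[mask]]
    return mask


def membership_mask(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Mask over a site table for membership in an interval DataFrame
    (columns chrom/start/end), handling per-chromosome grouping."""
    mask = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy()
    for chrom, sub in intervals.groupby("chrom", observed=True):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        mask[sel] = positions_in_intervals(
            pos[sel], sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    return mask
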