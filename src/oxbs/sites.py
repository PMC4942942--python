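"""Strand-specific enumeration of cytosine sites with sequence context.

A site is any reference position carrying a C on the plus strand or a G on
the plus strand (i.e. a C on the minus strand). Context is read 5'->3' on
the site's own strand: CG if the next base is G, otherwise CH (subclassed
CHG/CHH from the next two bases). CG sites on the two strands are kept
separate throughout; collapsing to symmetric CpG units would discard the
strand asymmetry of CH methylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cytosine_site_table", "assign_context"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _context_from_duplet(next1: np.ndarray, next2: np.ndarray) -> np.ndarray:
    """Context labels from the two downstream bases (on the site strand)."""
    ctx = np.where(next1 == b"G", "CG", np.where(next2 == b"G", "CHG", "CHH"))
    return ctx


def cytosine_site_table(genome) -> pd.DataFrame:
    """Enumerate every cytosine site in the genome.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context
    (CG/CHG/CHH), trinucleotide, edge (bool: subclass determined from fewer
    than two downstream bases). Sites whose immediate downstream base is
    off-chromosome (a terminal C) are excluded: their CG/CH status is
    undefined.
    """
    frames = []
    for chrom, s in genome.sequences.items():
        arr = np.frombuffer(s.encode("ascii"), dtype="S1")
        n = len(arr)
        padded = np.concatenate([np.full(2, b"N"), arr, np.full(2, b"N")])

        # plus strand: C at p, context from p+1, p+2
        pos_p = np.flatnonzero(arr == b"C")
        pos_p = pos_p[pos_p < n - 1]  # terminal C: context undefined
        nx1 = arr[pos_p + 1]
        nx2 = padded[pos_p + 4]  # == arr[pos_p+2] or N pad
        ctx_p = _context_from_duplet(nx1, nx2)
        edge_p = pos_p + 2 >= n
        tri_p = np.char.add(
            np.char.add(arr[pos_p].astype("U1"), nx1.astype("U1")), nx2.astype("U1")
        )

        # minus strand: G at p on plus == C on minus; downstream on minus is
        # p-1, p-2 complemented
        pos_m = np.flatnonzero(arr == b"G")
        pos_m = pos_m[pos_m > 0]
        prev1 = arr[pos_m - 1]
        prev2 = padded[pos_m]  # == arr[pos_m-2] or N pad
        # vectorised complement via translation table
        table = np.full(256, b"N", dtype="S1")
        for a, b in ((b"A", b"T"), (b"C", b"G"), (b"G", b"C"), (b"T", b"A")):
            table[a[0]] = b
        nx1m = table[prev1.view(np.uint8)]
        nx2m = table[prev2.view(np.uint8)]
        ctx_m = _context_from_duplet(nx1m, nx2m)
        edge_m = pos_m - 2 < 0
        tri_m = np.char.add(
            np.char.add(np.full(len(pos_m), "C"), nx1m.astype("U1")), nx2m.astype("U1")
        )

        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate([pos_p, pos_m]),
                "strand": np.repeat(["+", "-"], [len(pos_p), len(pos_m)]),
                "context": np.concatenate([ctx_p, ctx_m]),
                "trinucleotide": np.concatenate([tri_p, tri_m]),
                "edge": np.concatenate([edge_p, edge_m]),
            }
        )
        df.sort_values(["pos", "strand"], inplace=True, kind="stable")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["context"] = pd.Categorical(out["context"], categories=["CG", "CHG", "CHH"])
    out["strand"] = pd.Categorical(out["strand"], categories=["+", "-"])
    return out


def assign_context(genome, chrom: str, pos: int, strand: str):
    """Context and trinucleotide of a single site (0-based position).

    Mirrors :func:`cytosine_site_table` for one site; positions within 2 bp
    of the chromosome end fall back to an N-padded trinucleotide.
    """
    s = genome.sequences[chrom]
    if strand == "+":
        if s[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {s[pos]}, not C")
        tri = (s[pos : pos + 3] + "NN")[:3]
    else:
        if s[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {s[pos]}, not G (minus-strand C)")
        tri = ("NN" + s[max(0, pos - 2) : pos + 1])[-3:]
        tri = _revcomp(tri)
    if tri[1] == "G":
        return "CG", tri
    if tri[2] == "G":
        return "CHG", tri
    return "CHH", tri
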