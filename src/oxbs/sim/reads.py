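"""Coordinate-tagged paired-end bisulfite read simulator.

Fragments are drawn uniformly from both strands; conversion is applied
once per fragment (so overlapping mates agree, as they would when reading
one molecule) using the chemistry model and the per-site truth.  Read
names encode the exact mate placement, which replaces alignment.

No sequencing-error model is applied beyond base-quality annotation,
optional low-quality reads, and optional ambiguous (N) calls, which exist
to exercise the quality filters.
"""

from __future__ import annotations

import numpy as np

from ..chemistry import ChemistryParams, p_unconverted_bs, p_unconverted_oxbs
from ..readqc import ReadRecord, make_tag

__all__ = ["simulate_read_pairs"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class _TruthLookup:
    """Per-(chrom, strand) sorted site positions with P(C-call) arrays."""

    def __init__(self, truth, chemistry: ChemistryParams, library: str):
        if library == "BS":
            p = np.clip(p_unconverted_bs(truth.m, truth.h, chemistry), 0, 1)
        elif library == "oxBS":
            p = np.clip(p_unconverted_oxbs(truth.m, truth.h, chemistry), 0, 1)
        else:
            raise ValueError(f"unknown library {library!r}")
        self.by_key = {}
        sites = truth.sites
        chroms = sites["chrom"].to_numpy()
        strands = sites["strand"].to_numpy()
        pos = sites["pos"].to_numpy()
        for chrom in np.unique(chroms):
            for strand in ("+", "-"):
                sel = (chroms == chrom) & (strands == strand)
                self.by_key[(str(chrom), strand)] = (pos[sel], p[sel])

    def window(self, chrom, strand, start, end):
        pos, p = self.by_key.get((chrom, strand), (np.empty(0, int), np.empty(0)))
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], p[lo:hi]


def simulate_read_pairs(genome, truth, chemistry: ChemistryParams, library: str,
                        read_length: int = 100, coverage: float = 2.0,
                        insert_size: int = 250, per_base_n_rate: float = 0.0,
                        quality_mean: float = 35.0, quality_sd: float = 3.0,
                        low_quality_fraction: float = 0.0,
                        low_quality_mean: float = 15.0,
                        rng: np.random.Generator | None = None):
    """Simulate tagged read pairs for one sample and library.

    Returns a list of (R1, R2) ReadRecord tuples.
    """
    if read_length < 7:
        raise ValueError("read_length < 7: end trimming would exhaust the read")
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    rng = rng or np.random.default_rng(0)
    lookup = _TruthLookup(truth, chemistry, library)
    chrom_names = [c for c in genome.chrom_names
                   if c in {str(x) for x in truth.sites["chrom"].unique()}]
    lengths = genome.lengths
    total = sum(lengths[c] for c in chrom_names)
    n_frags = max(1, int(round(coverage * total / (2 * read_length))))
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    chrom_draw = rng.choice(len(chrom_names), size=n_frags, p=weights)

    pairs = []
    for serial in range(n_frags):
        chrom = chrom_names[int(chrom_draw[serial])]
        start = int(rng.integers(0, lengths[chrom] - insert_size + 1))
        end = start + insert_size
        frag_strand = "+" if rng.random() < 0.5 else "-"
        frag = list(genome.sequences[chrom][start:end])

        # conversion over the whole fragment on its own strand
        target = "C" if frag_strand == "+" else "G"
        converted_base = "T" if frag_strand == "+" else "A"
        pos, p = lookup.window(chrom, frag_strand, start, end)
        if len(pos):
            conv = rng.random(len(pos)) >= p  # True -> converted call
            for site_pos, c in zip(pos, conv):
                if c and frag[site_pos - start] == target:
                    frag[site_pos - start] = converted_base
        frag = "".join(frag)

        if frag_strand == "+":
            mates = [
                (start, start + read_length, "F", frag[:read_length]),
                (end - read_length, end, "R",
                 frag[-read_length:].translate(_COMPLEMENT)[::-1]),
            ]
        else:
            mates = [
                (end - read_length, end, "R",
                 frag[-read_length:].translate(_COMPLEMENT)[::-1]),
                (start, start + read_length, "F", frag[:read_length]),
            ]

        q_mean = (
            low_quality_mean
            if low_quality_fraction and rng.random() < low_quality_fraction
            else quality_mean
        )
        recs = []
        for mate_idx, (ms, me, orient, seq) in enumerate(mates, start=1):
            qual = np.clip(
                np.rint(rng.normal(q_mean, quality_sd, size=read_length)), 2, 40
            ).astype(int)
            if per_base_n_rate > 0:
                n_mask = rng.random(read_length) < per_base_n_rate
                if n_mask.any():
                    seq = "".join(
                        "N" if n_mask[i] else b for i, b in enumerate(seq)
                    )
                    qual[n_mask] = 2
            name = make_tag(chrom, ms, me, frag_strand, orient, library, serial)
            recs.append(ReadRecord(name=name, seq=seq, qual=qual, mate=mate_idx))
        pairs.append((recs[0], recs[1]))
    return pairs
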