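"""Mock reference genome with annotated CpG islands, promoters and repeats.

The generated genome is a small multi-chromosome stand-in (autosomes plus
chrX/chrY) for a real mammalian assembly: random near-uniform base
composition, CpG islands built with a strongly elevated CG-dinucleotide
rate, promoters whose TSS sits at an island midpoint (the common CGI
promoter arrangement, which yields the familiar U-shaped methylation
profile around the TSS), and unannotated-repeat intervals used to emulate
hypermethylated LINE/SINE elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..rng import substream

__all__ = [
    "GenomeConfig",
    "ReferenceGenome",
    "ElementAnnotationSet",
    "build_reference",
    "read_fasta",
    "read_bed",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_FLANK_WIDTH = 4000  # shore (2 kb) + shelf (2 kb)


class GenomeConfigError(ValueError):
    """Raised when a genome configuration cannot be honoured."""


@dataclass
class GenomeConfig:
    """Layout of the mock genome.

    Defaults give ~1.2 Mb over 5 chromosomes: enough CG sites (~1e5) for
    tight binomial recovery while staying desk-scale.
    """

    autosome_lengths: dict = field(
        default_factory=lambda: {"chr1": 300_000, "chr2": 300_000, "chr3": 300_000}
    )
    chrx_length: int = 200_000
    chry_length: int = 100_000
    n_cgis: int = 60
    cgi_length_range: tuple = (300, 600)
    n_promoters: int = 60
    repeat_fraction: float = 0.10
    repeat_length_range: tuple = (150, 400)
    cgi_cg_token_prob: float = 0.35

    @property
    def chrom_lengths(self) -> dict:
        out = dict(self.autosome_lengths)
        out["chrX"] = self.chrx_length
        out["chrY"] = self.chry_length
        return out

    @property
    def autosomes(self) -> list:
        return list(self.autosome_lengths)

    def validate(self) -> None:
        max_len = max(self.cgi_length_range)
        need = 2 * (_FLANK_WIDTH + max_len)
        for chrom in list(self.autosome_lengths) + ["chrX"]:
            length = self.chrom_lengths[chrom]
            if length < need:
                raise GenomeConfigError(
                    f"{chrom} length {length} < 2*(flank width + max element length) = {need}"
                )
        if self.n_promoters > self.n_cgis:
            raise GenomeConfigError("n_promoters may not exceed n_cgis (promoters are CGI-anchored)")
        if not 0.0 <= self.repeat_fraction < 0.5:
            raise GenomeConfigError("repeat_fraction must lie in [0, 0.5)")


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> A/C/G/T string."""

    sequences: dict

    @property
    def chrom_names(self) -> list:
        return list(self.sequences)

    @property
    def lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    def cg_site_counts(self, chrom: str) -> tuple:
        """(plus, minus) strand counts of CG-context cytosines.

        Each CG dinucleotide carries one C per strand, so the two counts are
        equal for any sequence (CpG palindromy).
        """
        n = self.sequences[chrom].count("CG")
        return n, n

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=c, description="") for c, s in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


@dataclass
class ElementAnnotationSet:
    """CGI / promoter / repeat annotations (0-based half-open intervals).

    Promoters carry the gene strand and a ``tss`` column.
    """

    cgis: pd.DataFrame
    promoters: pd.DataFrame
    repeats: pd.DataFrame

    def write_bed(self, outdir) -> dict:
        outdir = Path(outdir)
        paths = {}
        for name, df in (("cgi", self.cgis), ("promoters", self.promoters), ("repeats", self.repeats)):
            path = outdir / f"{name}.bed"
            bed = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df["name"],
                    "score": 0,
                    "strand": df["strand"] if "strand" in df else ".",
                }
            )
            bed.to_csv(path, sep="\t", header=False, index=False)
            paths[name] = path
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _island_sequence(rng: np.random.Generator, length: int, cg_token_prob: float) -> np.ndarray:
    """CG-dense sequence: emit 'CG' tokens with probability cg_token_prob,
    otherwise a single random base, until ``length`` is reached."""
    out = np.empty(length, dtype="S1")
    i = 0
    while i < length:
        if rng.random() < cg_token_prob and i + 1 < length:
            out[i] = b"C"
            out[i + 1] = b"G"
            i += 2
        else:
            out[i] = _BASES[rng.integers(0, 4)]
            i += 1
    return out


def _place_islands(rng, chrom_len, n_islands, length_range, margin):
    """Evenly slotted island placement with randomised position per slot.

    Slotting guarantees islands are well separated (flanks rarely collide)
    and keeps a margin from chromosome ends.
    """
    if n_islands == 0:
        return []
    lo, hi = length_range
    usable = chrom_len - 2 * margin
    slot = usable // n_islands
    if slot <= hi:
        raise GenomeConfigError(
            f"cannot place {n_islands} islands of up to {hi} bp on a {chrom_len} bp chromosome"
        )
    islands = []
    for k in range(n_islands):
        length = int(rng.integers(lo, hi + 1))
        slot_start = margin + k * slot
        start = int(slot_start + rng.integers(0, slot - length))
        islands.append((start, start + length))
    return islands


def _place_repeats(rng, chrom_len, fraction, length_range, exclude):
    """Non-overlapping repeat intervals covering ~``fraction`` of the
    chromosome, avoiding ``exclude`` intervals (the islands)."""
    target = fraction * chrom_len
    placed = []
    occupied = sorted(exclude)
    covered = 0.0
    attempts = 0
    lo, hi = length_range
    while covered < target and attempts < 50_000:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, chrom_len - length)))
        end = start + length
        clash = any(s < end and start < e for s, e in occupied)
        if clash:
            continue
        occupied.append((start, end))
        occupied.sort()
        placed.append((start, end))
        covered += length
    placed.sort()
    return placed


def build_reference(config: GenomeConfig | None = None, seed: int = 0):
    """Generate the mock genome and its annotations.

    Deterministic for fixed (config, seed). Returns
    (ReferenceGenome, ElementAnnotationSet).
    """
    config = config or GenomeConfig()
    config.validate()
    rng = substream(seed, "reference")

    lengths = config.chrom_lengths
    island_hosts = config.autosomes + ["chrX"]  # no islands on chrY
    host_len = sum(lengths[c] for c in island_hosts)

    # Apportion islands across host chromosomes proportionally to length.
    n_alloc, acc = {}, 0
    for i, chrom in enumerate(island_hosts):
        if i == len(island_hosts) - 1:
            n_alloc[chrom] = config.n_cgis - acc
        else:
            n_alloc[chrom] = int(round(config.n_cgis * lengths[chrom] / host_len))
            acc += n_alloc[chrom]

    sequences = {}
    cgi_rows, repeat_rows = [], []
    margin = _FLANK_WIDTH + 1000
    for chrom, length in lengths.items():
        seq = _random_sequence(rng, length)
        islands = []
        if chrom in island_hosts:
            islands = _place_islands(
                rng, length, n_alloc[chrom], config.cgi_length_range, margin
            )
            for start, end in islands:
                seq[start:end] = _island_sequence(rng, end - start, config.cgi_cg_token_prob)
        repeats = _place_repeats(
            rng, length, config.repeat_fraction, config.repeat_length_range, islands
        )
        for start, end in islands:
            cgi_rows.append((chrom, start, end))
        for start, end in repeats:
            repeat_rows.append((chrom, start, end))
        sequences[chrom] = seq.tobytes().decode("ascii")

    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    cgis["name"] = [f"CGI_{i:03d}" for i in range(len(cgis))]
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"])
    repeats["name"] = [f"RPT_{i:04d}" for i in range(len(repeats))]

    # Promoters: TSS anchored at the midpoint of a randomly chosen subset of
    # islands, random gene strand; interval is TSS +/- 2 kb.
    pick = rng.choice(len(cgis), size=config.n_promoters, replace=False)
    pick.sort()
    prom_rows = []
    for j, idx in enumerate(pick):
        row = cgis.iloc[int(idx)]
        tss = int((row["start"] + row["end"]) // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        prom_rows.append(
            (row["chrom"], max(0, tss - 2000), min(lengths[row["chrom"]], tss + 2000),
             f"PROM_{j:03d}", strand, tss)
        )
    promoters = pd.DataFrame(
        prom_rows, columns=["chrom", "start", "end", "name", "strand", "tss"]
    )

    genome = ReferenceGenome(sequences=sequences)
    annotations = ElementAnnotationSet(cgis=cgis, promoters=promoters, repeats=repeats)
    return genome, annotations


def read_fasta(path) -> ReferenceGenome:
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceGenome(sequences=sequences)


def read_bed(path, with_tss: bool = False) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    if with_tss:
        # gene-strand convention: TSS at interval start for +, end for -
        df["tss"] = np.where(df["strand"] == "+", (df["start"] + df["end"]) // 2,
                             (df["start"] + df["end"]) // 2)
    return df
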