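"""Read filtering, end trimming, and conversion of coordinate-tagged reads
into per-cytosine count tables.

Synthetic reads carry their true placement in the read name
(``oxbs|chrom|start|end|fragstrand|orient|library``, 0-based half-open
mate interval, orient F when the stored sequence is in reference
orientation and R when it is reverse-complemented), so no aligner is
needed: counting is exact bookkeeping.

Filtering keeps a pair iff both mates have mean base quality >= min_q and
each mate has at most ``max_ambiguous`` N calls; rejection is pair-level
because downstream libraries are paired.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sites import cytosine_site_table

__all__ = [
    "ReadRecord",
    "MalformedReadError",
    "filter_read_pairs",
    "trim_read_pairs",
    "reads_to_counts",
    "write_fastq_pair",
    "read_fastq_pair",
]

TAG_PREFIX = "oxbs"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MalformedReadError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRecord:
    """One mate with optional coordinate tag parsed from its name."""

    name: str
    seq: str
    qual: np.ndarray  # phred scores, same length as seq
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise MalformedReadError(
                f"read {self.name}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    @property
    def tag(self) -> dict | None:
        parts = self.name.split("|")
        if parts[0] != TAG_PREFIX or len(parts) < 7:
            return None
        return {
            "chrom": parts[1],
            "start": int(parts[2]),
            "end": int(parts[3]),
            "frag_strand": parts[4],
            "orient": parts[5],
            "library": parts[6],
        }

    def with_tag(self, **updates) -> "ReadRecord":
        tag = self.tag
        if tag is None:
            return self
        tag.update(updates)
        name = "|".join(
            [TAG_PREFIX, tag["chrom"], str(tag["start"]), str(tag["end"]),
             tag["frag_strand"], tag["orient"], tag["library"]]
            + self.name.split("|")[7:]
        )
        return replace(self, name=name)

    def mean_quality(self) -> float:
        return float(np.mean(self.qual)) if len(self.qual) else 0.0

    def n_ambiguous(self) -> int:
        return self.seq.count("N")


def make_tag(chrom, start, end, frag_strand, orient, library, serial=None) -> str:
    parts = [TAG_PREFIX, chrom, str(start), str(end), frag_strand, orient, library]
    if serial is not None:
        parts.append(str(serial))
    return "|".join(parts)


def filter_read_pairs(pairs, min_q: float = 25.0, max_ambiguous: int = 1,
                      per_base: bool = False):
    """(kept, dropped, report) after quality / ambiguity filtering.

    ``per_base=True`` switches the quality rule from mean base quality to a
    per-base minimum.
    """
    kept, dropped = [], []
    report = {"kept": 0, "quality": 0, "ambiguous": 0}
    for r1, r2 in pairs:
        if per_base:
            q_ok = all(np.min(r.qual) >= min_q for r in (r1, r2) if len(r.qual))
        else:
            q_ok = r1.mean_quality() >= min_q and r2.mean_quality() >= min_q
        n_ok = r1.n_ambiguous() <= max_ambiguous and r2.n_ambiguous() <= max_ambiguous
        if not n_ok:
            report["ambiguous"] += 1
            dropped.append((r1, r2))
        elif not q_ok:
            report["quality"] += 1
            dropped.append((r1, r2))
        else:
            report["kept"] += 1
            kept.append((r1, r2))
    return kept, dropped, report


def _trim_one(read: ReadRecord, end_trim: int) -> ReadRecord | None:
    if end_trim == 0:
        return read
    if len(read.seq) - 2 * end_trim < 1:
        return None
    seq = read.seq[end_trim:-end_trim]
    qual = read.qual[end_trim:-end_trim]
    out = ReadRecord(name=read.name, seq=seq, qual=qual, mate=read.mate)
    tag = read.tag
    if tag is not None:
        # both read ends lose end_trim bases; in reference coordinates the
        # interval shrinks symmetrically regardless of orientation
        out = out.with_tag(start=tag["start"] + end_trim, end=tag["end"] - end_trim)
    return out


def trim_read_pairs(pairs, end_trim: int = 3):
    """Trim ``end_trim`` bases from both ends of every mate (the residual
    end trim applied after adapter removal).  Pairs whose mates would be
    exhausted are dropped with reason "exhausted"."""
    if end_trim < 0:
        raise ValueError("end_trim must be non-negative")
    kept, report = [], {"kept": 0, "exhausted": 0}
    for r1, r2 in pairs:
        t1, t2 = _trim_one(r1, end_trim), _trim_one(r2, end_trim)
        if t1 is None or t2 is None:
            report["exhausted"] += 1
            continue
        kept.append((t1, t2))
        report["kept"] += 1
    return kept, report


def reads_to_counts(reads, genome, sites: pd.DataFrame | None = None) -> dict:
    """Accumulate C/T calls at reference cytosines, strand-specifically.

    ``reads`` is a flat iterable of tagged ReadRecords (any mix of mates
    and libraries).  Returns {library: count DataFrame} in the simulator's
    cytosine-report schema.  Bases other than C/T on a plus-strand cytosine
    (or G/A at a minus-strand cytosine) are tallied as "other" and excluded.
    """
    lengths = genome.lengths
    # per (library, chrom): [plus_mod, plus_unmod, minus_mod, minus_unmod]
    acc: dict = {}
    other = 0
    for read in reads:
        tag = read.tag
        if tag is None:
            raise MalformedReadError(f"read {read.name} carries no coordinate tag")
        chrom, start, end = tag["chrom"], tag["start"], tag["end"]
        if chrom not in lengths or start < 0 or end > lengths[chrom]:
            raise ValueError(f"read {read.name}: tag outside reference bounds")
        seq = read.seq
        if tag["orient"] == "R":
            seq = seq.translate(_COMPLEMENT)[::-1]
        if len(seq) != end - start:
            raise MalformedReadError(
                f"read {read.name}: tag span {end - start} != read length {len(seq)}"
            )
        lib = tag["library"]
        if (lib, chrom) not in acc:
            acc[(lib, chrom)] = np.zeros((4, lengths[chrom]), dtype=np.int64)
        a = acc[(lib, chrom)]
        ref = genome.sequences[chrom][start:end]
        if tag["frag_strand"] == "+":
            for i, rb in enumerate(ref):
                if rb == "C":
                    b = seq[i]
                    if b == "C":
                        a[0, start + i] += 1
                    elif b == "T":
                        a[1, start + i] += 1
                    else:
                        other += 1
        else:
            for i, rb in enumerate(ref):
                if rb == "G":
                    b = seq[i]
                    if b == "G":
                        a[2, start + i] += 1
                    elif b == "A":
                        a[3, start + i] += 1
                    else:
                        other += 1

    if sites is None:
        sites = cytosine_site_table(genome)
    out = {}
    libraries = sorted({lib for lib, _ in acc})
    pos = sites["pos"].to_numpy()
    is_plus = (sites["strand"] == "+").to_numpy()
    for lib in libraries:
        mod = np.zeros(len(sites), dtype=np.int64)
        unmod = np.zeros(len(sites), dtype=np.int64)
        for chrom in lengths:
            if (lib, chrom) not in acc:
                continue
            a = acc[(lib, chrom)]
            sel = (sites["chrom"] == chrom).to_numpy()
            sp = sel & is_plus
            sm = sel & ~is_plus
            mod[sp] = a[0, pos[sp]]
            unmod[sp] = a[1, pos[sp]]
            mod[sm] = a[2, pos[sm]]
            unmod[sm] = a[3, pos[sm]]
        df = sites[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
        df["count_modified"] = mod
        df["count_unmodified"] = unmod
        out[lib] = df
    out["n_other_calls"] = other
    return out


def _to_seqrecord(read: ReadRecord) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.name, description="")
    rec.letter_annotations["phred_quality"] = [int(q) for q in read.qual]
    return rec


def write_fastq_pair(pairs, r1_path, r2_path) -> None:
    """Gzipped FASTQ output with a fixed gzip mtime so identical inputs give
    byte-identical files."""
    for path, idx in ((r1_path, 0), (r2_path, 1)):
        raw = open(path, "wb")
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            import io as _io

            text = _io.TextIOWrapper(gz)
            SeqIO.write((_to_seqrecord(p[idx]) for p in pairs), text, "fastq")
            text.flush()
        raw.close()


def read_fastq_pair(r1_path, r2_path):
    def load(path, mate):
        out = []
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                out.append(
                    ReadRecord(
                        name=rec.id,
                        seq=str(rec.seq),
                        qual=np.asarray(rec.letter_annotations["phred_quality"]),
                        mate=mate,
                    )
                )
        return out

    r1, r2 = load(r1_path, 1), load(r2_path, 2)
    if len(r1) != len(r2):
        raise MalformedReadError("R1/R2 files differ in read count")
    return list(zip(r1, r2))
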