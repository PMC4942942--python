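"""Read filtering/trimming rules and tagged-read counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxbs.chemistry import ChemistryParams
from oxbs.readqc import (
    MalformedReadError,
    ReadRecord,
    filter_read_pairs,
    make_tag,
    read_fastq_pair,
    reads_to_counts,
    trim_read_pairs,
    write_fastq_pair,
)
from oxbs.rng import substream
from oxbs.sim.genome import ReferenceGenome
from oxbs.sim.reads import simulate_read_pairs
from oxbs.sim.truth import MethylomeTruth
from oxbs.sites import cytosine_site_table


def _read(seq, qual=None, name="r", mate=1):
    qual = np.full(len(seq), 30) if qual is None else np.asarray(qual)
    return ReadRecord(name=name, seq=seq, qual=qual, mate=mate)


class TestFilter:
    def test_clean_pair_kept(self):
        pairs = [(_read("ACGT"), _read("TTTT", mate=2))]
        kept, dropped, report = filter_read_pairs(pairs)
        assert report == {"kept": 1, "quality": 0, "ambiguous": 0}

    def test_two_ambiguous_drops_pair(self):
        pairs = [(_read("ANNT"), _read("ACGT", mate=2))]
        kept, dropped, report = filter_read_pairs(pairs)
        assert report["ambiguous"] == 1 and not kept

    def test_low_mean_quality_drops_pair(self):
        pairs = [(_read("ACGT", qual=[20, 20, 30, 28]), _read("ACGT", mate=2))]
        kept, _, report = filter_read_pairs(pairs, min_q=25)
        assert report["quality"] == 1 and not kept

    def test_malformed_record_names_read(self):
        with pytest.raises(MalformedReadError, match="badread"):
            _read("ACGT", qual=[30, 30], name="badread")

    def test_idempotent(self):
        pairs = [
            (_read("ACGT"), _read("ANNT", mate=2)),
            (_read("AAAA"), _read("CCCC", mate=2)),
            (_read("ACGT", qual=[10, 10, 10, 10]), _read("ACGT", mate=2)),
        ]
        once, _, _ = filter_read_pairs(pairs)
        twice, _, report = filter_read_pairs(once)
        assert twice == once
        assert report["quality"] == report["ambiguous"] == 0

    def test_dropped_fraction_matches_generator_rate(self):
        """Configured per-base N rate predicts the pair-drop fraction."""
        rng = substream(3, "nrate")
        length, p = 60, 0.01
        n_pairs = 10_000
        pairs = []
        for i in range(n_pairs):
            mates = []
            for mate in (1, 2):
                n_mask = rng.random(length) < p
                seq = "".join("N" if x else "A" for x in n_mask)
                mates.append(_read(seq, mate=mate, name=f"r{i}"))
            pairs.append(tuple(mates))
        _, dropped, _ = filter_read_pairs(pairs, max_ambiguous=1)
        q = 1 - (1 - p) ** length - length * p * (1 - p) ** (length - 1)
        expect = 1 - (1 - q) ** 2
        se = np.sqrt(expect * (1 - expect) / n_pairs)
        assert abs(len(dropped) / n_pairs - expect) < 3 * se


class TestTrim:
    def test_lengths_and_identity(self):
        r = _read("A" * 150)
        kept, _ = trim_read_pairs([(r, r)], end_trim=3)
        assert len(kept[0][0].seq) == 144
        kept, _ = trim_read_pairs([(r, r)], end_trim=0)
        assert kept[0][0].seq == r.seq

    def test_tag_coordinates_shift(self):
        name = make_tag("chr1", 100, 180, "+", "F", "BS")
        r = _read("A" * 80, name=name)
        kept, _ = trim_read_pairs([(r, r)], end_trim=3)
        tag = kept[0][0].tag
        assert (tag["start"], tag["end"]) == (103, 177)

    def test_exhausted_read_dropped(self):
        r = _read("ACGTACG")  # 7 bp, trim 3 leaves 1 bp: kept
        kept, report = trim_read_pairs([(r, r)], end_trim=3)
        assert report["kept"] == 1 and len(kept[0][0].seq) == 1
        r6 = _read("ACGTAC")
        kept, report = trim_read_pairs([(r6, r6)], end_trim=3)
        assert report["exhausted"] == 1 and not kept


@pytest.fixture(scope="module")
def tiny_setup():
    genome = ReferenceGenome(
        sequences={"chr1": "".join(
            np.random.default_rng(4).choice(list("ACGT"), size=4000)
        )}
    )
    sites = cytosine_site_table(genome)
    m = np.full(len(sites), 0.6)
    h = np.full(len(sites), 0.2)
    truth = MethylomeTruth("s", sites, m, h)
    return genome, sites, truth


class TestReadsToCounts:
    def test_single_read_single_site(self):
        genome = ReferenceGenome(sequences={"chr1": "AACGAA"})
        name = make_tag("chr1", 0, 6, "+", "F", "BS")
        read = _read("AACGAA", name=name)
        tables = reads_to_counts([read], genome)
        bs = tables["BS"]
        site = bs[(bs["pos"] == 2) & (bs["strand"] == "+")]
        assert int(site["count_modified"].iloc[0]) == 1
        assert int(site["count_unmodified"].iloc[0]) == 0

    def test_converted_call_counts_unmodified(self):
        genome = ReferenceGenome(sequences={"chr1": "AACGAA"})
        read = _read("AATGAA", name=make_tag("chr1", 0, 6, "+", "F", "BS"))
        bs = reads_to_counts([read], genome)["BS"]
        site = bs[(bs["pos"] == 2) & (bs["strand"] == "+")]
        assert int(site["count_unmodified"].iloc[0]) == 1

    def test_empty_read_set(self):
        genome = ReferenceGenome(sequences={"chr1": "AACGAA"})
        tables = reads_to_counts([], genome)
        assert tables["n_other_calls"] == 0

    def test_out_of_bounds_tag(self):
        genome = ReferenceGenome(sequences={"chr1": "AACGAA"})
        read = _read("AACGAA", name=make_tag("chr1", 3, 9, "+", "F", "BS"))
        with pytest.raises(ValueError):
            reads_to_counts([read], genome)

    def test_two_path_equivalence_chi2(self, tiny_setup):
        """Counts via reads match the closed-form P_C: stratified chi-square
        GOF not rejected at alpha=0.01 over >= 1e3 sites."""
        genome, sites, truth = tiny_setup
        chem = ChemistryParams(beta=0.99, omega=0.97)
        pairs = simulate_read_pairs(
            genome, truth, chem, "BS", read_length=50, coverage=20,
            insert_size=120, rng=substream(8, "reads"),
        )
        bs = reads_to_counts([r for p in pairs for r in p], genome)["BS"]
        depth = (bs["count_modified"] + bs["count_unmodified"]).to_numpy()
        covered = depth > 0
        assert covered.sum() >= 1000
        from oxbs.chemistry import p_unconverted_bs

        p = np.asarray(p_unconverted_bs(truth.m, truth.h, chem))[covered]
        obs = bs["count_modified"].to_numpy()[covered]
        n = depth[covered]
        # aggregate z over the uniform-p stratum (single stratum here)
        z = (obs.sum() - (n * p).sum()) / np.sqrt((n * p * (1 - p)).sum())
        chi2 = z**2
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_trim_then_count_commutes(self, tiny_setup):
        """Counting trimmed reads == counting independently sliced reads."""
        genome, sites, truth = tiny_setup
        chem = ChemistryParams(beta=1.0, omega=1.0)
        pairs = simulate_read_pairs(
            genome, truth, chem, "BS", read_length=40, coverage=4,
            insert_size=100, rng=substream(9, "reads"),
        )
        trimmed, _ = trim_read_pairs(pairs, end_trim=3)
        via_trim = reads_to_counts([r for p in trimmed for r in p], genome)["BS"]

        manual = []
        for r1, r2 in pairs:
            for r in (r1, r2):
                tag = r.tag
                manual.append(
                    ReadRecord(
                        name=make_tag(tag["chrom"], tag["start"] + 3, tag["end"] - 3,
                                      tag["frag_strand"], tag["orient"], tag["library"]),
                        seq=r.seq[3:-3],
                        qual=r.qual[3:-3],
                        mate=r.mate,
                    )
                )
        via_slice = reads_to_counts(manual, genome)["BS"]
        pd.testing.assert_frame_equal(via_trim, via_slice)


class TestFastqIO:
    def test_round_trip_and_byte_determinism(self, tiny_setup, tmp_path):
        genome, sites, truth = tiny_setup
        pairs = simulate_read_pairs(
            genome, truth, ChemistryParams(), "oxBS", read_length=30,
            coverage=1, insert_size=80, per_base_n_rate=0.01,
            rng=substream(10, "reads"),
        )
        write_fastq_pair(pairs, tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz")
        write_fastq_pair(pairs, tmp_path / "r1b.fq.gz", tmp_path / "r2b.fq.gz")
        assert (tmp_path / "r1.fq.gz").read_bytes() == (tmp_path / "r1b.fq.gz").read_bytes()
        back = read_fastq_pair(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz")
        assert len(back) == len(pairs)
        assert back[0][0].seq == pairs[0][0].seq
        assert np.array_equal(back[0][0].qual, pairs[0][0].qual)

    def test_identical_seed_identical_reads(self, tiny_setup):
        genome, sites, truth = tiny_setup
        kwargs = dict(read_length=30, coverage=1, insert_size=80)
        a = simulate_read_pairs(genome, truth, ChemistryParams(), "BS",
                                rng=substream(11, "r"), **kwargs)
        b = simulate_read_pairs(genome, truth, ChemistryParams(), "BS",
                                rng=substream(11, "r"), **kwargs)
        assert [(x.seq, x.name) for p in a for x in p] == [
            (x.seq, x.name) for p in b for x in p
        ]

    def test_short_read_length_rejected(self, tiny_setup):
        genome, sites, truth = tiny_setup
        with pytest.raises(ValueError):
            simulate_read_pairs(genome, truth, ChemistryParams(), "BS",
                                read_length=6, rng=substream(0, "r"))
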