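"""End-to-end driver: genome -> truth -> counts -> summaries.

This is the default "study": a balanced young/old x female/male design
(n = 3 per cell), ~1.2 Mb mock genome, 10x coverage per library, default
hippocampus profile and chemistry.  Per-sample count tables are reduced to
chromosome-class, region-class and repeat summaries as they are generated
so the full run stays small in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chemistry import ChemistryParams
from .elements import (
    derive_flanks,
    promoter_superbins,
    region_aggregates,
    repeat_surrogate,
)
from .quant import chromosome_summary
from .rng import substream
from .sim.counts import simulate_counts, write_cytosine_report
from .sim.genome import GenomeConfig, build_reference
from .sim.truth import HippocampusProfile, TruthModel, make_design

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "build_endpoints"]


@dataclass
class ExperimentConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    profile: HippocampusProfile = field(default_factory=HippocampusProfile)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    coverage: float = 10.0
    n_per_cell: int = 3
    ages: tuple = ("young", "old")


@dataclass
class ExperimentResult:
    design: pd.DataFrame
    chrom_summary: pd.DataFrame     # sample x chromosome-class x context
    region_summary: pd.DataFrame    # sample x region-class (CGI flanks + promoter bins)
    repeat_summary: pd.DataFrame    # sample x repeat surrogate levels
    genome: object
    annotations: object
    truth_model: TruthModel
    counts: dict | None = None      # sample_id -> (bs, oxbs) when kept


def run_experiment(config: ExperimentConfig | None = None, seed: int = 1,
                   keep_counts: bool = False, outdir=None) -> ExperimentResult:
    config = config or ExperimentConfig()
    genome, annotations = build_reference(config.genome, seed)
    model = TruthModel(genome, annotations, config.profile)
    design = make_design(config.n_per_cell, ages=config.ages, seed=seed)

    flanks = derive_flanks(annotations.cgis, chrom_lengths=genome.lengths)
    superbins = promoter_superbins(annotations.promoters, chrom_lengths=genome.lengths)
    autosomes = config.genome.autosomes

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.write_fasta(outdir / "reference.fa")
        annotations.write_bed(outdir)
        design.to_csv(outdir / "design.tsv", sep="\t", index=False)

    chrom_rows, region_rows, repeat_rows = [], [], []
    counts = {} if keep_counts else None
    for row in design.itertuples():
        truth = model.sample_truth(
            row.sample_id, row.sex, row.age, substream(seed, "truth", row.sample_id)
        )
        bs, oxbs = simulate_counts(
            truth, config.chemistry, config.coverage,
            substream(seed, "counts", row.sample_id),
        )
        if keep_counts:
            counts[row.sample_id] = (bs, oxbs)
        if outdir is not None:
            write_cytosine_report(bs, outdir / f"{row.sample_id}.BS.cytosine.tsv")
            write_cytosine_report(oxbs, outdir / f"{row.sample_id}.oxBS.cytosine.tsv")

        chrom_rows.append(
            chromosome_summary(bs, oxbs, row.sample_id, row.sex, autosomes=autosomes)
        )
        for regions in (flanks, superbins):
            agg = region_aggregates(bs, oxbs, regions)
            agg.insert(0, "sample_id", row.sample_id)
            region_rows.append(agg)
        surrogate = repeat_surrogate(bs, annotations.repeats)
        surrogate["sample_id"] = row.sample_id
        repeat_rows.append(surrogate)

    result = ExperimentResult(
        design=design,
        chrom_summary=pd.concat(chrom_rows, ignore_index=True),
        region_summary=pd.concat(region_rows, ignore_index=True),
        repeat_summary=pd.DataFrame(repeat_rows),
        genome=genome,
        annotations=annotations,
        truth_model=model,
        counts=counts,
    )
    if outdir is not None:
        result.chrom_summary.to_csv(outdir / "chromosome_summary.tsv", sep="\t", index=False)
        result.region_summary.to_csv(outdir / "region_summary.tsv", sep="\t", index=False)
        result.repeat_summary.to_csv(outdir / "repeat_summary.tsv", sep="\t", index=False)
    return result


def build_endpoints(result: ExperimentResult) -> pd.DataFrame:
    """Long-form endpoint table (sample_id, endpoint, value) for the
    statistical layer: chromosome classes and region classes x mc/hmc."""
    rows = []
    for r in result.chrom_summary.itertuples():
        for mod in ("mc", "hmc"):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "endpoint": f"{r.chrom_class}-{mod}{r.context}",
                    "value": getattr(r, mod),
                }
            )
    for r in result.region_summary.itertuples():
        for mod in ("mc", "hmc"):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "endpoint": f"{r.region_type}-{mod}CG",
                    "value": getattr(r, mod),
                }
            )
    return pd.DataFrame(rows).dropna(subset=["value"])
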