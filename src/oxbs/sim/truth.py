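"""Ground-truth methylome: per-site 5mC/5hmC fractions with sex/age effects.

The default profile emulates adult mouse hippocampus: high mCG (~50 %
pooled), substantial hmCG (~15 %), very low mCH/hmCH, hypomethylated CpG
island interiors, hypermethylated repeats, female-biased chrX mCG,
male-biased chrX hmCG, an old-vs-young hmCG gain in CGI shores/shelves and
an old-male mCG loss around promoters.

Per-site truth is drawn from a Dirichlet over (m, h, unmodified) whose
marginals are Beta distributions around the compartment means with a
common concentration; this gives realistic site-to-site and
replicate-to-replicate variance while guaranteeing m + h <= 1.  An
infinite concentration degenerates to point masses at the means.

Compartment deviations (islands low, repeats high) would drag the pooled
genome-wide level away from the global targets, so the background CG means
are solved from the realized autosomal CG-site shares such that the pooled
autosomal expectation equals the targets exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..elements import derive_flanks
from ..intervals import membership_mask
from ..rng import substream
from ..sites import cytosine_site_table

__all__ = [
    "HippocampusProfile",
    "MethylomeTruth",
    "TruthModel",
    "make_design",
    "assign_truth",
]


@dataclass
class HippocampusProfile:
    """Compartment mean levels and effect sizes (all fractions in [0, 1])."""

    mcg: float = 0.50            # pooled autosomal CG 5mC target
    hmcg: float = 0.15           # pooled autosomal CG 5hmC target
    mch: float = 0.005           # CH-context 5mC mean
    hmch: float = 0.0005         # CH-context 5hmC mean
    cgi_mcg: float = 0.05        # CGI-interior CG means
    cgi_hmcg: float = 0.02
    repeat_mcg: float = 0.95     # repeat-element CG means
    repeat_hmcg: float = 0.03
    chry_hmcg: float = 0.05      # chrY hmCG runs well below autosomes
    chrx_female_mcg_excess: float = 0.02
    chrx_male_hmcg_excess: float = 0.02
    age_shore_shelf_hmcg: float = 0.03    # old - young, both sexes
    age_promoter_mcg: float = -0.015      # old - young, males, TSS +/- 1 kb
    concentration: float = 20.0           # Dirichlet concentration (inf = point mass)
    compensate_background: bool = True

    def validate(self) -> None:
        for name in (
            "mcg", "hmcg", "mch", "hmch", "cgi_mcg", "cgi_hmcg",
            "repeat_mcg", "repeat_hmcg", "chry_hmcg",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"profile target {name}={v} outside [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive (or inf)")


@dataclass
class MethylomeTruth:
    """Per-sample true (m, h) fractions aligned to a site table."""

    sample_id: str
    sites: pd.DataFrame
    m: np.ndarray
    h: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.m + self.h > 1.0 + 1e-12):
            raise ValueError("m_true + h_true exceeds 1 at some site")


def make_design(n_per_cell: int = 3, ages=("young", "old"), seed: int = 0) -> pd.DataFrame:
    """Balanced sex x age design table."""
    rows = []
    for sex in ("female", "male"):
        for age in ages:
            for rep in range(1, n_per_cell + 1):
                rows.append(
                    {
                        "sample_id": f"{sex[0].upper()}_{age}_{rep}",
                        "sex": sex,
                        "age": age,
                        "replicate": rep,
                    }
                )
    df = pd.DataFrame(rows)
    df["seed"] = seed
    return df


class TruthModel:
    """Site compartments plus solved background means for one genome."""

    def __init__(self, genome, annotations, profile: HippocampusProfile | None = None,
                 sites: pd.DataFrame | None = None, autosomes=None):
        self.profile = profile or HippocampusProfile()
        self.profile.validate()
        self.genome = genome
        self.annotations = annotations
        self.sites = sites if sites is not None else cytosine_site_table(genome)
        chroms = list(genome.sequences)
        self.autosomes = autosomes or [c for c in chroms if c not in ("chrX", "chrY")]

        s = self.sites
        self.is_cg = (s["context"] == "CG").to_numpy()
        self.in_repeat = membership_mask(s, annotations.repeats)
        self.in_cgi = membership_mask(s, annotations.cgis)
        flanks = derive_flanks(
            annotations.cgis, chrom_lengths=genome.lengths
        )
        shore_shelf = flanks[flanks["region_type"] != "island"]
        self.in_shore_shelf = membership_mask(s, shore_shelf)
        prom = annotations.promoters
        prom1kb = pd.DataFrame(
            {
                "chrom": prom["chrom"],
                "start": (prom["tss"] - 1000).clip(lower=0),
                "end": prom["tss"] + 1000,
            }
        )
        self.in_promoter_1kb = membership_mask(s, prom1kb)
        self.on_x = (s["chrom"] == "chrX").to_numpy()
        self.on_y = (s["chrom"] == "chrY").to_numpy()
        self.on_autosome = s["chrom"].isin(self.autosomes).to_numpy()
        self._solve_background()

    def _solve_background(self) -> None:
        """Background CG means such that E[pooled autosomal CG level] hits
        the profile's global targets given realized compartment shares."""
        p = self.profile
        cg_auto = self.is_cg & self.on_autosome
        n_tot = cg_auto.sum()
        n_rep = (cg_auto & self.in_repeat).sum()
        n_cgi = (cg_auto & self.in_cgi & ~self.in_repeat).sum()
        n_bg = n_tot - n_rep - n_cgi
        if not p.compensate_background or n_bg == 0:
            self.bg_mcg, self.bg_hmcg = p.mcg, p.hmcg
            return
        self.bg_mcg = (n_tot * p.mcg - n_cgi * p.cgi_mcg - n_rep * p.repeat_mcg) / n_bg
        self.bg_hmcg = (n_tot * p.hmcg - n_cgi * p.cgi_hmcg - n_rep * p.repeat_hmcg) / n_bg
        for name, v in (("background mCG", self.bg_mcg), ("background hmCG", self.bg_hmcg)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"compensated {name} = {v:.4f} outside [0, 1]; "
                    "compartment shares too extreme for the global targets"
                )

    def site_means(self, sex: str, age: str):
        """Expected (mu_m, mu_h) per site for one sex/age cell (after
        clipping); also returns the count of clipped sites."""
        p = self.profile
        n = len(self.sites)
        mu_m = np.full(n, p.mch)
        mu_h = np.full(n, p.hmch)

        cg = self.is_cg
        mu_m[cg] = self.bg_mcg
        mu_h[cg] = self.bg_hmcg
        mu_h[cg & self.on_y & ~self.in_repeat] = p.chry_hmcg
        sel = cg & self.in_cgi & ~self.in_repeat
        mu_m[sel] = p.cgi_mcg
        mu_h[sel] = p.cgi_hmcg
        sel = cg & self.in_repeat
        mu_m[sel] = p.repeat_mcg
        mu_h[sel] = p.repeat_hmcg

        if sex == "female":
            mu_m[cg & self.on_x] += p.chrx_female_mcg_excess
        elif sex == "male":
            mu_h[cg & self.on_x] += p.chrx_male_hmcg_excess
        else:
            raise ValueError(f"unknown sex {sex!r}")
        if age == "old":
            mu_h[cg & self.in_shore_shelf] += p.age_shore_shelf_hmcg
            if sex == "male":
                mu_m[cg & self.in_promoter_1kb] += p.age_promoter_mcg
        elif age not in ("young", "adult"):
            raise ValueError(f"unknown age {age!r}")

        clipped = (mu_m < 0) | (mu_m > 1) | (mu_h < 0) | (mu_h > 1)
        np.clip(mu_m, 0.0, 1.0, out=mu_m)
        np.clip(mu_h, 0.0, 1.0, out=mu_h)
        over = mu_m + mu_h > 1.0
        clipped |= over
        if over.any():
            mu_h[over] = 1.0 - mu_m[over]
        n_clipped = int(clipped.sum())
        if n_clipped:
            warnings.warn(f"{n_clipped} site means clipped to the unit simplex")
        return mu_m, mu_h, n_clipped

    def sample_truth(self, sample_id: str, sex: str, age: str,
                     rng: np.random.Generator) -> MethylomeTruth:
        """Draw one sample's per-site truth around the cell means."""
        mu_m, mu_h, n_clipped = self.site_means(sex, age)
        keep = ~self.on_y if sex == "female" else np.ones(len(self.sites), dtype=bool)
        mu_m, mu_h = mu_m[keep], mu_h[keep]
        c = self.profile.concentration
        if np.isinf(c):
            m, h = mu_m.copy(), mu_h.copy()
        else:
            # Dirichlet(c*mu_m, c*mu_h, c*(1-mu_m-mu_h)) via gamma draws;
            # marginals are Beta(c*mu, c*(1-mu)).
            g_m = rng.gamma(np.maximum(c * mu_m, 1e-12))
            g_h = rng.gamma(np.maximum(c * mu_h, 1e-12))
            g_r = rng.gamma(np.maximum(c * (1.0 - mu_m - mu_h), 1e-12))
            tot = g_m + g_h + g_r
            m = g_m / tot
            h = g_h / tot
        sites = self.sites.loc[keep].reset_index(drop=True)
        return MethylomeTruth(sample_id=sample_id, sites=sites, m=m, h=h,
                              n_clipped=n_clipped)


def assign_truth(genome, annotations, profile, design: pd.DataFrame, seed: int,
                 sites: pd.DataFrame | None = None) -> dict:
    """Per-sample truth for every sample in the design table."""
    model = TruthModel(genome, annotations, profile, sites=sites)
    out = {}
    for row in design.itertuples():
        rng = substream(seed, "truth", row.sample_id)
        out[row.sample_id] = model.sample_truth(row.sample_id, row.sex, row.age, rng)
    return out
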