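"""Spike-in conversion controls.

Three synthetic control sequences carry cytosines of known modification
class -- unmodified C, 5mC, and 5hmC -- and are carried through both the BS
and oxBS chemistry.  Their converted fractions anchor the bisulfite rate
(beta) and oxidation efficiency (omega) estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..chemistry import ChemistryParams, p_unconverted_bs, p_unconverted_oxbs

__all__ = ["SpikeInControl", "simulate_spikeins", "write_spikein_table", "read_spikein_table"]

_CLASS_TRUTH = {
    # (m, h) point truth per site class
    "unmodified": (0.0, 0.0),
    "mC": (1.0, 0.0),
    "hmC": (0.0, 1.0),
}

# Fixed 48-mer control sequences; C positions are the control sites.
_CONTROL_SEQS = {
    "unmodified": "AATCGTTAGCAATCGTTAGCAATCGTTAGCAATCGTTAGCAATCGTTA",
    "mC": "TTAACTTACCATTAACTTACCATTAACTTACCATTAACTTACCATTAA",
    "hmC": "AATCTTAACCAATCTTAACCAATCTTAACCAATCTTAACCAATCTTAA",
}


@dataclass
class SpikeInControl:
    """Simulated spike-in counts: one row per site x class x library."""

    counts: pd.DataFrame  # columns: control, site_class, pos, library, count_c, count_t

    def class_totals(self, site_class: str, library: str):
        sub = self.counts[
            (self.counts["site_class"] == site_class) & (self.counts["library"] == library)
        ]
        return int(sub["count_c"].sum()), int(sub["count_t"].sum())


def simulate_spikeins(chemistry: ChemistryParams, depth: int,
                      rng: np.random.Generator) -> SpikeInControl:
    """Simulate per-site BS and oxBS counts on the three control classes.

    ``depth`` is the total read depth per site class, split across that
    class's sites.
    """
    rows = []
    for site_class, seq in _CONTROL_SEQS.items():
        m, h = _CLASS_TRUTH[site_class]
        positions = [i for i, b in enumerate(seq) if b == "C"]
        per_site = max(1, depth // len(positions))
        p = {
            "BS": float(p_unconverted_bs(m, h, chemistry)),
            "oxBS": float(p_unconverted_oxbs(m, h, chemistry)),
        }
        for library in ("BS", "oxBS"):
            c_calls = rng.binomial(per_site, p[library], size=len(positions))
            for pos, c in zip(positions, c_calls):
                rows.append(
                    {
                        "control": site_class,
                        "site_class": site_class,
                        "pos": pos,
                        "library": library,
                        "count_c": int(c),
                        "count_t": int(per_site - c),
                    }
                )
    return SpikeInControl(counts=pd.DataFrame(rows))


def write_spikein_table(control: SpikeInControl, path) -> None:
    control.counts.to_csv(path, sep="\t", index=False)


def read_spikein_table(path) -> SpikeInControl:
    return SpikeInControl(counts=pd.read_csv(path, sep="\t"))
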