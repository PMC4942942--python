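"""Conversion-chemistry model shared by the simulator and the estimators.

In a bisulfite (BS) library unmodified C deaminates to U (read T) with
probability ``beta``; 5mC and 5hmC are protected apart from small failure
rates ``eps_m``/``eps_h``.  In an oxidative-bisulfite (oxBS) library 5hmC is
first oxidised to 5fC with probability ``omega``; oxidised bases then
convert like unmodified C.  The per-read probability of an unconverted (C)
call at a site with true fractions ``m`` (5mC) and ``h`` (5hmC) is

    BS:   P_C = m(1-eps_m) + h(1-eps_h) + (1-m-h)(1-beta)
    oxBS: P_C = m(1-eps_m) + h[(1-omega)(1-eps_h) + omega(1-beta)]
               + (1-m-h)(1-beta)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChemistryParams", "p_unconverted_bs", "p_unconverted_oxbs"]


@dataclass(frozen=True)
class ChemistryParams:
    """Probabilities governing BS/oxBS conversion.

    beta
        Bisulfite conversion probability of an unmodified (or oxidised) C.
    omega
        Oxidation probability 5hmC -> 5fC in the oxBS arm.
    eps_m, eps_h
        Inappropriate-conversion probabilities of protected 5mC / 5hmC.
    """

    beta: float = 0.995
    omega: float = 0.975
    eps_m: float = 0.0
    eps_h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta", "omega", "eps_m", "eps_h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"chemistry parameter {name}={v} outside [0, 1]")


def p_unconverted_bs(m, h, chem: ChemistryParams):
    """Per-read probability of a C call in the BS library."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    return (
        m * (1.0 - chem.eps_m)
        + h * (1.0 - chem.eps_h)
        + (1.0 - m - h) * (1.0 - chem.beta)
    )


def p_unconverted_oxbs(m, h, chem: ChemistryParams):
    """Per-read probability of a C call in the oxBS library."""
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    protected_h = (1.0 - chem.omega) * (1.0 - chem.eps_h) + chem.omega * (1.0 - chem.beta)
    return (
        m * (1.0 - chem.eps_m)
        + h * protected_h
        + (1.0 - m - h) * (1.0 - chem.beta)
    )
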