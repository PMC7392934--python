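"""Ideal-transformer model of middle-ear impedance matching.

The middle ear raises sound pressure between the tympanic membrane and the
cochlear fluid by two mechanisms: the area ratio between the pars tensa of
the tympanic membrane (A_TM) and the oval window / projected stapes
footplate (A_FP), and the lever ratio L1/L2 of the hinge-like rotation of
the malleus-incus complex.  Treating the chain as an ideal transformer:

    pressure gain      G      = (A_TM / A_FP) * (L1/L2)
    membrane impedance Z_TM   = Z_cochlea / ((A_TM/A_FP) * (L1/L2)^2)
    energy fraction    T      = 4 Z_air Z_TM / (Z_air + Z_TM)^2

Z_TM is the cochlear specific acoustic impedance referred back through the
transformer; T is the standard power-transmission coefficient between two
media, equal to 1 iff Z_TM = Z_air.  All impedances are specific acoustic
impedances in Pa*s/m; frequency dependence of the cochlear load is out of
scope (Z_cochlea is a scalar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransformerParams",
    "TransformerResult",
    "area_ratio",
    "pressure_gain",
    "lever_db",
    "z_tm",
    "energy_fraction",
    "evaluate",
    "species_report",
    "DEFAULT_SPECIES",
]


@dataclass(frozen=True)
class TransformerParams:
    """Per-species inputs to the ideal-transformer model."""

    a_tm: float          # tympanic-membrane (pars tensa) area, mm^2
    a_fp: float          # projected footplate / oval-window area, mm^2
    lever_ratio: float   # L1/L2, dimensionless
    z_cochlea: float = 56_000.0   # Pa*s/m
    z_air: float = 420.0          # Pa*s/m

    def __post_init__(self) -> None:
        for name in ("a_tm", "a_fp", "lever_ratio", "z_cochlea", "z_air"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class TransformerResult:
    area_ratio: float
    lever_ratio: float
    pressure_gain: float
    lever_db: float      # umbo-to-lenticular motion ratio in dB
    z_tm: float          # Pa*s/m
    energy_fraction: float


#: Default parameterization: human and sheep, with tympanic-membrane areas
#: from the comparative literature and footplate/lever values from adult
#: middle-ear morphometry (projected footplate areas; cochlear impedance
#: 56 kPa*s/m, air 420 Pa*s/m).
DEFAULT_SPECIES = {
    "human": TransformerParams(a_tm=68.3, a_fp=2.86, lever_ratio=1.25),
    "sheep": TransformerParams(a_tm=44.2, a_fp=1.45, lever_ratio=2.47),
}


def area_ratio(a_tm: float, a_fp: float) -> float:
    """Tympanic-membrane to footplate area ratio."""
    if not (a_tm > 0 and a_fp > 0):
        raise ValueError("areas must be > 0")
    return a_tm / a_fp


def pressure_gain(area_ratio: float, lever_ratio: float) -> float:
    """Expected middle-ear pressure gain: area ratio times lever ratio."""
    if not (area_ratio > 0 and lever_ratio > 0):
        raise ValueError("ratios must be > 0")
    return area_ratio * lever_ratio


def lever_db(lever_ratio: float) -> float:
    """Motion attenuation umbo -> lenticular process, 20*log10(L1/L2) dB."""
    if not (lever_ratio > 0):
        raise ValueError("lever ratio must be > 0")
    return 20.0 * np.log10(lever_ratio)


def z_tm(params: TransformerParams) -> float:
    """Specific acoustic impedance seen at the tympanic membrane, Pa*s/m.

    The cochlear impedance divided by the transformer ratio
    (area ratio) * (lever ratio)^2; strictly decreasing in both ratios.
    """
    ar = area_ratio(params.a_tm, params.a_fp)
    return params.z_cochlea / (ar * params.lever_ratio ** 2)


def energy_fraction(z_membrane: float, z_air: float) -> float:
    """Fraction of incident sound energy transmitted from air into the
    middle ear: 4 Z_air Z_TM / (Z_air + Z_TM)^2, in (0, 1], symmetric in its
    two arguments and 1 iff they are equal."""
    if not (z_membrane > 0 and z_air > 0):
        raise ValueError("impedances must be > 0")
    return 4.0 * z_air * z_membrane / (z_air + z_membrane) ** 2


def evaluate(params: TransformerParams) -> TransformerResult:
    """All transformer-model outputs for one species parameterization."""
    ar = area_ratio(params.a_tm, params.a_fp)
    zt = z_tm(params)
    return TransformerResult(
        area_ratio=ar,
        lever_ratio=params.lever_ratio,
        pressure_gain=pressure_gain(ar, params.lever_ratio),
        lever_db=lever_db(params.lever_ratio),
        z_tm=zt,
        energy_fraction=energy_fraction(zt, params.z_air),
    )


def species_report(species: dict | None = None) -> pd.DataFrame:
    """Tabulate the transformer model per species.

    `species` maps name -> TransformerParams (default: the built-in human and
    sheep parameterizations).  Returns a DataFrame indexed by species with
    columns area_ratio, lever_ratio, pressure_gain, lever_db, z_tm,
    energy_fraction.
    """
    if species is None:
        species = DEFAULT_SPECIES
    rows = {name: vars(evaluate(p)) for name, p in species.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df
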