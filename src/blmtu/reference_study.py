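"""Reference wheat root-elongation study: design and published summaries.

The package's running example is a wheat (*Triticum aestivum*) root
elongation study of Cu, Co and Cu-Co (1:100 molar) toxicity in simplified
nutrient solutions.  Twelve bioassay media were used: a Mg series (0.05,
0.5, 1.0, 2.0 mM Mg at pH 6.0) and a pH series (pH 4.5-7.6 at 0.05 mM Mg),
all with 0.08 mM K, 2.0 mM Na and 0.2 mM Ca supplied as chloride salts and
Mg as the sulfate.  This module encodes that design plus the study's
published per-medium dose-response summaries (EC50 expressed as free-ion
activity, slope beta, mixture TU50) and the published biotic-ligand
constants, which serve as reference inputs for forward simulation,
round-trip parameter recovery and regression checks.

Raw per-seedling data were never published; anything at observation level
is produced by :mod:`blmtu.synthetic_data`.
"""

from __future__ import annotations

import pandas as pd

from .blm_single import BLMParameters
from .speciation import SolutionComposition

__all__ = [
    "mg_set_media",
    "ph_set_media",
    "study_media",
    "published_summaries",
    "CU_PARAMS",
    "CO_PARAMS",
    "PUBLISHED_MIXTURE_FITS",
]

_MG_LEVELS_MM = (0.05, 0.5, 1.0, 2.0)
_PH_LEVELS = (4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.3, 7.6)

# background electrolytes, mM: KCl 0.08, NaCl 2.0, CaCl2 0.2, MgSO4 variable
_K_MM, _NA_MM, _CA_MM = 0.08, 2.0, 0.2
_CL_MM = _K_MM + _NA_MM + 2 * _CA_MM  # chloride from the three Cl salts


def _medium(mg_mM: float, pH: float, label: str,
            cu_uM: float = 0.0, co_uM: float = 0.0) -> SolutionComposition:
    mM, uM = 1e-3, 1e-6
    return SolutionComposition(
        totals={
            "K": _K_MM * mM, "Na": _NA_MM * mM, "Ca": _CA_MM * mM,
            "Mg": mg_mM * mM, "Cu": cu_uM * uM, "Co": co_uM * uM,
            "Cl": _CL_MM * mM, "SO4": mg_mM * mM,
        },
        pH=pH,
        label=label,
    )


def mg_set_media(cu_uM: float = 0.0, co_uM: float = 0.0) -> list[SolutionComposition]:
    """The four Mg-series media (pH 6.0), optionally dosed with metal."""
    return [_medium(mg, 6.0, f"Mg{mg}", cu_uM, co_uM) for mg in _MG_LEVELS_MM]


def ph_set_media(cu_uM: float = 0.0, co_uM: float = 0.0) -> list[SolutionComposition]:
    """The eight pH-series media (0.05 mM Mg), optionally dosed with metal."""
    return [_medium(0.05, ph, f"pH{ph}", cu_uM, co_uM) for ph in _PH_LEVELS]


def study_media() -> list[SolutionComposition]:
    """All twelve study media (Mg series then pH series)."""
    return mg_set_media() + ph_set_media()


def published_summaries() -> pd.DataFrame:
    """Published per-medium log-logistic summaries.

    Columns: medium label, set ("Mg"/"pH"), Mg_mM, pH, EC50 of free Cu2+
    activity (uM) and slope, EC50 of free Co2+ activity (uM) and slope, and
    the mixture TU50 and slope.  The Co EC50s at Mg 0.5 and Mg 1.0 mM are
    internally inconsistent with the study's own linearity claim and fitted
    constants (flag column ``co_ec50_flagged``); they are reproduced
    verbatim, not corrected.
    """
    rows = [
        # label,   set,  Mg_mM, pH,  EC50Cu, bCu,  EC50Co,  bCo,  TU50, bMix, flagged
        ("Mg0.05", "Mg", 0.05, 6.0, 0.41, 3.76, 64.49, 3.31, 1.03, 4.89, False),
        ("Mg0.5",  "Mg", 0.5,  6.0, 0.66, 4.52, 51.52, 3.15, 0.93, 5.77, True),
        ("Mg1.0",  "Mg", 1.0,  6.0, 0.74, 3.71, 438.34, 3.73, 1.11, 3.25, True),
        ("Mg2.0",  "Mg", 2.0,  6.0, 1.01, 2.63, 620.75, 5.50, 0.97, 5.12, False),
        ("pH4.5",  "pH", 0.05, 4.5, 0.45, 8.73, 122.60, 4.74, 0.88, 5.21, False),
        ("pH5",    "pH", 0.05, 5.0, 0.50, 3.93, 129.42, 4.63, 1.10, 6.49, False),
        ("pH5.5",  "pH", 0.05, 5.5, 0.49, 6.71, 104.01, 5.40, 1.15, 8.26, False),
        ("pH6",    "pH", 0.05, 6.0, 0.42, 3.76, 64.61, 3.35, 1.02, 4.89, False),
        ("pH6.5",  "pH", 0.05, 6.5, 0.43, 3.20, 55.11, 3.77, 1.04, 6.57, False),
        ("pH7",    "pH", 0.05, 7.0, 0.28, 2.80, 40.81, 4.37, 1.13, 6.07, False),
        ("pH7.3",  "pH", 0.05, 7.3, 0.18, 2.68, 37.19, 4.49, 1.15, 5.05, False),
        ("pH7.6",  "pH", 0.05, 7.6, 0.11, 3.16, 29.94, 4.26, 1.02, 5.69, False),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "medium", "set", "Mg_mM", "pH",
            "ec50_cu_uM", "beta_cu", "ec50_co_uM", "beta_co",
            "tu50_mix", "beta_mix", "co_ec50_flagged",
        ],
    )


#: Published Cu biotic-ligand parameters (single-metal fit).
CU_PARAMS = BLMParameters(
    metal="Cu",
    logK_MBL=5.87,
    logK_XBL={"Mg2+": 2.93},
    logK_IMBL={"CuHCO3+": 5.67, "CuCO3(aq)": 5.44, "CuOH+": 5.07},
    f50=0.28,
    beta=2.73,
)

#: Published Co biotic-ligand parameters (single-metal fit).
CO_PARAMS = BLMParameters(
    metal="Co",
    logK_MBL=4.72,
    logK_XBL={"Mg2+": 3.84},
    logK_IMBL={"CoHCO3+": 5.81},
    f50=0.66,
    beta=4.59,
)

#: Published pooled mixture dose-response fits and prediction quality
#: (model -> {x50, beta, rmse, r2}).  The RMSE/R2 values derive from the
#: unpublished raw observations and are documentation, not a test oracle.
PUBLISHED_MIXTURE_FITS = {
    "FIAM-TU": {"x50": 0.87, "beta": 1.71, "rmse": 16.31, "r2": 0.84},
    "BLM-TU": {"x50": 1.45, "beta": 4.04, "rmse": 6.70, "r2": 0.97},
}
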