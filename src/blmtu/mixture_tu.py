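"""Toxic units for Cu-Co mixtures: FIAM vs BLM concentration addition.

Two toxic-unit (TU) scales are compared on the same mixture observations:

* FIAM TU (free-ion activity model):  TU_M = {Cu2+}/EC50_Cu + {Co2+}/EC50_Co
  with one global EC50 pair — solution chemistry beyond the free ion is
  ignored.
* BLM TU:  TU_f = f_Cu/f50_Cu + f_Co/f50_Co where each f is the
  biotic-ligand site fraction occupied by that metal's toxic species,
  computed from the speciated mixture chemistry and the single-metal BLM
  constants.

Fitting the log-logistic curve of RNE against either TU gives a TU50; a
mixture is called additive when TU50 is (close to) 1, synergistic below,
antagonistic above.  Prediction quality (RMSE, R^2 on RNE percentage
points) of the two scales is compared on identical observations: when Mg
and pH vary across media, the BLM scale collapses the dose-response onto a
single curve while the FIAM scale scatters — the mechanistic signature of
competition and complex toxicity.

In mixtures each metal's f uses its own single-metal parameter set (its
K_MBL, K_IMBL, K_MgBL) on the shared solution chemistry; the two
single-metal fits yield different Mg constants, so no joint denominator
exists.  ``cross_metal_competition=True`` optionally adds the other
metal's occupancy terms to each denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blm_single import BLMParameters, fraction_occupied
from .dose_response import LogLogisticFit, LogLogisticModel
from .exceptions import InvalidInputError
from .speciation import SpeciationResult

__all__ = [
    "MixtureObservation",
    "ModelComparison",
    "InteractionCall",
    "prediction_rmse",
    "toxic_units_fiam",
    "toxic_units_blm",
    "mixture_site_fractions",
    "fit_mixture_dose_response",
    "classify_interaction",
    "compare_models",
]


@dataclass
class MixtureObservation:
    """One mixture treatment: speciated chemistry plus observed response."""

    spec: SpeciationResult
    rne_percent: float
    replicate_id: int = 0
    treatment_label: str = ""
    tu_m: float = float("nan")
    tu_f: float = float("nan")
    f_Cu: float = float("nan")
    f_Co: float = float("nan")


@dataclass
class ModelComparison:
    """Pooled TU dose-response fit and its prediction quality."""

    model: str            # "FIAM-TU" or "BLM-TU"
    x50: float            # fitted TU50
    beta: float
    rmse: float           # RNE percentage points, observed vs fitted curve
    r2: float
    n_points: int
    fit: LogLogisticFit | None = None

    def summary(self) -> str:
        return (
            f"{self.model}: TU50 = {self.x50:.3f}, beta = {self.beta:.3f}, "
            f"RMSE = {self.rmse:.2f} %, R^2 = {self.r2:.3f} (n = {self.n_points})"
        )


@dataclass
class InteractionCall:
    """Additivity classification of a mixture from its TU50."""

    tu50: float
    interval: tuple[float, float]
    label: str  # additive | synergistic | antagonistic


def prediction_rmse(observed, predicted) -> float:
    """Root mean square error between observed and predicted responses,
    in RNE percentage points."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise InvalidInputError("observed and predicted must have equal shape")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def toxic_units_fiam(spec: SpeciationResult, ec50_Cu: float, ec50_Co: float) -> float:
    """TU_M = {Cu2+}/EC50_Cu + {Co2+}/EC50_Co (free-ion activities, mol/L)."""
    if ec50_Cu <= 0 or ec50_Co <= 0:
        raise InvalidInputError("EC50 values must be > 0")
    return spec.activities["Cu2+"] / ec50_Cu + spec.activities["Co2+"] / ec50_Co


def mixture_site_fractions(spec: SpeciationResult,
                           params_Cu: BLMParameters,
                           params_Co: BLMParameters,
                           cross_metal_competition: bool = False,
                           include_unity_term: bool = True) -> tuple[float, float]:
    """(f_Cu, f_Co) in a mixture: each metal's own parameters applied to the
    shared speciated chemistry.  With ``cross_metal_competition`` the other
    metal's bound species are added to the denominator as competitors."""
    if not cross_metal_competition:
        return (
            fraction_occupied(spec, params_Cu, include_unity_term),
            fraction_occupied(spec, params_Co, include_unity_term),
        )

    def _numerator(params):
        num = 10.0 ** params.logK_MBL * spec.activities[params.free_ion]
        for im, logk in params.logK_IMBL.items():
            num += 10.0 ** logk * spec.activities[im]
        return num

    out = []
    for own, other in ((params_Cu, params_Co), (params_Co, params_Cu)):
        num = _numerator(own)
        den = num + _numerator(other)
        for x, logk in own.logK_XBL.items():
            den += 10.0 ** logk * spec.activities[x]
        if include_unity_term:
            den += 1.0
        out.append(num / den if den > 0 else 0.0)
    return tuple(out)


def toxic_units_blm(f_Cu: float, f_Co: float,
                    params_Cu: BLMParameters, params_Co: BLMParameters) -> float:
    """TU_f = f_Cu/f50_Cu + f_Co/f50_Co (concentration addition on the
    occupied-site scale)."""
    for p in (params_Cu, params_Co):
        if not 0.0 < p.f50 < 1.0:
            raise InvalidInputError("f50 values must lie in (0, 1)")
    if f_Cu < 0 or f_Co < 0:
        raise InvalidInputError("site fractions must be >= 0")
    return f_Cu / params_Cu.f50 + f_Co / params_Co.f50


def fit_mixture_dose_response(observations: Sequence[MixtureObservation],
                              which: str = "tu_f",
                              aggregate: str | None = None) -> ModelComparison:
    """Fit RNE against the chosen TU scale, pooled over all observations.

    ``which`` is "tu_f" (BLM) or "tu_m" (FIAM); the corresponding field must
    be populated on every observation.  RMSE/R^2 are computed between the
    observed RNE and the fitted curve.
    """
    key = which.lower()
    if key not in ("tu_f", "tu_m"):
        raise InvalidInputError(f"which must be 'tu_f' or 'tu_m', got {which!r}")
    tu = np.array([getattr(o, key) for o in observations], dtype=float)
    if np.any(~np.isfinite(tu)):
        raise InvalidInputError(f"observations lack populated {key} values")
    y = np.array([o.rne_percent for o in observations], dtype=float)
    fit = LogLogisticModel(tu, y, aggregate=aggregate).fit()
    return ModelComparison(
        model="BLM-TU" if key == "tu_f" else "FIAM-TU",
        x50=fit.x50, beta=fit.beta, rmse=fit.rmse, r2=fit.r2,
        n_points=fit.n_points, fit=fit,
    )


def classify_interaction(tu50: float,
                         ci: tuple[float, float] | None = None,
                         band: float = 0.2) -> InteractionCall:
    """Classify a mixture from its TU50.

    With a confidence interval the call is additive if the interval contains
    1, synergistic if entirely below, antagonistic if entirely above.
    Without one, a tolerance band [1-band, 1+band] around additivity is used
    (default +-0.2, wide enough to cover the 0.88-1.15 range typically
    declared "close to 1" in mixture studies).
    """
    if tu50 <= 0:
        raise InvalidInputError("tu50 must be > 0")
    lo, hi = ci if ci is not None else (tu50 - 0.0, tu50 + 0.0)
    if ci is None:
        interval = (1.0 - band, 1.0 + band)
        if interval[0] <= tu50 <= interval[1]:
            label = "additive"
        elif tu50 < 1.0:
            label = "synergistic"
        else:
            label = "antagonistic"
        return InteractionCall(tu50=tu50, interval=interval, label=label)
    if lo > hi:
        raise InvalidInputError("interval must satisfy lo <= hi")
    if hi < 1.0:
        label = "synergistic"
    elif lo > 1.0:
        label = "antagonistic"
    else:
        label = "additive"
    return InteractionCall(tu50=tu50, interval=(lo, hi), label=label)


def annotate_observations(observations: Sequence[MixtureObservation],
                          params_Cu: BLMParameters, params_Co: BLMParameters,
                          ec50_Cu: float, ec50_Co: float,
                          cross_metal_competition: bool = False) -> None:
    """Populate tu_m, tu_f, f_Cu, f_Co in place on each observation."""
    for o in observations:
        o.f_Cu, o.f_Co = mixture_site_fractions(
            o.spec, params_Cu, params_Co, cross_metal_competition
        )
        o.tu_f = toxic_units_blm(o.f_Cu, o.f_Co, params_Cu, params_Co)
        o.tu_m = toxic_units_fiam(o.spec, ec50_Cu, ec50_Co)


def compare_models(observations: Sequence[MixtureObservation],
                   params_Cu: BLMParameters, params_Co: BLMParameters,
                   ec50_Cu: float, ec50_Co: float,
                   cross_metal_competition: bool = False,
                   aggregate: str | None = None) -> tuple[ModelComparison, ModelComparison]:
    """Fit the FIAM-TU and BLM-TU models on identical observations.

    Returns (fiam, blm).  ``ec50_Cu``/``ec50_Co`` are the global free-ion
    EC50s (mol/L) the FIAM scale normalises by.
    """
    if len(observations) == 0:
        raise InvalidInputError("no observations supplied")
    annotate_observations(
        observations, params_Cu, params_Co, ec50_Cu, ec50_Co,
        cross_metal_competition,
    )
    fiam = fit_mixture_dose_response(observations, which="tu_m", aggregate=aggregate)
    blm = fit_mixture_dose_response(observations, which="tu_f", aggregate=aggregate)
    return fiam, blm
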