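"""Single-metal biotic ligand model: site occupancy and constant estimation.

The biotic ligand model (BLM) assumes toxicity is governed by the fraction
f of biotic-ligand (BL) sites occupied by toxic metal species, with
protective cations competing for the same sites:

    f = (K_MBL {M2+} + sum K_IMBL {IM})
        / (K_MBL {M2+} + sum K_IMBL {IM} + sum K_XBL {X^n+} + 1)

where M is the free metal ion, IM the toxic inorganic complexes (here the
hydroxide/carbonate species), X the competing cations (here Mg2+ only: the
study found K+, Na+, Ca2+ and H+ effects negligible for wheat), and the
trailing 1 represents unoccupied sites (see note below).  At 50% effect
f = f50, which solved for the free-ion activity gives the testable
prediction

    EC50{M2+} = (f50/(1-f50)) * (1 + K_MgBL {Mg2+})
                / (K_MBL + sum K_IMBL * lambda_IM),

linear in {Mg2+} at fixed pH and decreasing in each lambda_IM = {IM}/{M2+}
(the pH-dependent complex-to-free-ion activity ratios, supplied by
:mod:`blmtu.speciation`).

Identifiability note
--------------------
EC50-level data determine only S0 = (f50/(1-f50))/K_MBL, K_MgBL and the
ratios k_IM = K_IMBL/K_MBL: multiplying f50/(1-f50) and every K_*BL by a
common factor leaves all EC50s unchanged.  ``fit`` therefore estimates the
identifiable reparameterisation and converts to absolute constants using a
supplied f50 (the convention of the single-metal BLM literature, where f50
is carried over from the occupancy-scale dose-response).  Leaving f50 free
profiles it over a grid and warns that the likelihood is flat along the
ridge.

As printed in some formulations, the occupancy equation omits the "+1"
(unoccupied-site) term; without it EC50 -> 0 as {Mg2+} -> 0, contradicting
the nonzero intercepts observed in Mg series, so the unity term is included
by default and ``include_unity_term=False`` reproduces the literal form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .exceptions import (
    ConfigError,
    FitError,
    InvalidInputError,
    NonIdentifiableError,
)
from .speciation import SolutionComposition, SpeciationResult, speciate

__all__ = [
    "BLMParameters",
    "BLMFitResults",
    "SingleMetalBLM",
    "fraction_occupied",
    "predict_ec50_free_ion",
    "fit_single_metal_blm",
    "linear_mg_regression",
]

_FREE_ION = {"Cu": "Cu2+", "Co": "Co2+"}


@dataclass(frozen=True)
class BLMParameters:
    """Biotic-ligand binding constants and occupancy parameters for one metal.

    logK values are log10 of the conditional BL binding constants; f50 is
    the occupied fraction at 50% effect and beta the slope of the
    occupancy-scale dose-response.
    """

    metal: str
    logK_MBL: float
    logK_XBL: Mapping[str, float] = dc_field(default_factory=dict)
    logK_IMBL: Mapping[str, float] = dc_field(default_factory=dict)
    f50: float = 0.5
    beta: float = 3.0

    def __post_init__(self):
        if self.metal not in _FREE_ION:
            raise InvalidInputError(f"metal must be Cu or Co, got {self.metal!r}")
        if not 0.0 < self.f50 < 1.0:
            raise InvalidInputError(f"f50 must lie in (0, 1), got {self.f50}")
        for d in (self.logK_XBL, self.logK_IMBL):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise InvalidInputError(f"logK for {k} must be finite")
        if not np.isfinite(self.logK_MBL):
            raise InvalidInputError("logK_MBL must be finite")

    @property
    def free_ion(self) -> str:
        return _FREE_ION[self.metal]

    def as_dict(self) -> dict:
        return {
            "metal": self.metal,
            "logK_MBL": self.logK_MBL,
            "logK_XBL": dict(self.logK_XBL),
            "logK_IMBL": dict(self.logK_IMBL),
            "f50": self.f50,
            "beta": self.beta,
        }


def _activity(spec: SpeciationResult, species: str) -> float:
    try:
        return spec.activities[species]
    except KeyError:
        raise ConfigError(f"speciation result lacks activity for {species!r}") from None


def fraction_occupied(spec: SpeciationResult, params: BLMParameters,
                      include_unity_term: bool = True) -> float:
    """Fraction f of BL sites occupied by the metal's toxic species.

    Numerator: this metal's free-ion and complex terms only; denominator
    additionally carries the competing-cation terms and (by default) the
    unoccupied-site unity term.  Always in [0, 1].
    """
    num = 10.0 ** params.logK_MBL * _activity(spec, params.free_ion)
    for im, logk in params.logK_IMBL.items():
        num += 10.0 ** logk * _activity(spec, im)
    den = num
    for x, logk in params.logK_XBL.items():
        den += 10.0 ** logk * _activity(spec, x)
    if include_unity_term:
        den += 1.0
    if den == 0.0:
        return 0.0
    return num / den


def _lambda_ratios(spec: SpeciationResult, params: BLMParameters) -> dict[str, float]:
    """{IM}/{M2+} activity ratios for the complexes in the parameter set."""
    ratios = spec.complex_ratios.get(params.metal, {})
    out = {}
    for im in params.logK_IMBL:
        if im not in ratios:
            raise ConfigError(
                f"speciation result has no complex ratio for {im!r}; "
                "enable the species in the constants set"
            )
        out[im] = ratios[im]
    return out


def predict_ec50_free_ion(params: BLMParameters, spec: SpeciationResult,
                          include_unity_term: bool = True) -> float:
    """BLM-predicted EC50 expressed as free-ion activity (mol/L).

    Linear in {Mg2+} at fixed pH; decreasing in each complex-to-free ratio.
    """
    if not 0.0 < params.f50 < 1.0:
        raise InvalidInputError("f50 must lie in (0, 1)")
    A = params.f50 / (1.0 - params.f50)
    competition = sum(
        10.0 ** logk * _activity(spec, x) for x, logk in params.logK_XBL.items()
    )
    if include_unity_term:
        competition += 1.0
    denom = 10.0 ** params.logK_MBL
    for im, lam in _lambda_ratios(spec, params).items():
        denom += 10.0 ** params.logK_IMBL[im] * lam
    return A * competition / denom


@dataclass
class BLMFitResults:
    """Fitted BLM constants with uncertainties and residual diagnostics.

    Residuals/R^2 are on the log10 EC50 scale the loss was minimised on.
    ``f50_profiled`` flags that f50 was left free and resolved only by the
    grid tie-break (flat ridge) rather than by the data.
    """

    params: BLMParameters
    se_logK: dict[str, float]
    ec50_observed: np.ndarray
    ec50_fitted: np.ndarray
    media_labels: list[str]
    r2_log: float
    rmse_log: float
    f50_profiled: bool = False

    @property
    def residuals_log10(self) -> np.ndarray:
        return np.log10(self.ec50_observed) - np.log10(self.ec50_fitted)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Single-metal BLM fit ({p.metal}), loss on log10 EC50{{M2+}}",
            f"  n media  : {len(self.media_labels)}",
            f"  logK_{p.metal}BL : {p.logK_MBL:.3f}  (se {self.se_logK.get('logK_MBL', float('nan')):.3g})",
        ]
        for x, v in p.logK_XBL.items():
            lines.append(f"  logK_XBL[{x}] : {v:.3f}  (se {self.se_logK.get(x, float('nan')):.3g})")
        for im, v in p.logK_IMBL.items():
            lines.append(f"  logK_IMBL[{im}] : {v:.3f}  (se {self.se_logK.get(im, float('nan')):.3g})")
        lines += [
            f"  f50      : {p.f50:.3f}" + ("  (profiled: not identified by EC50 data)" if self.f50_profiled else "  (fixed)"),
            f"  R^2 (log10 EC50) : {self.r2_log:.4f}",
            f"  RMSE (log10 EC50): {self.rmse_log:.4g}",
        ]
        return "\n".join(lines)


class SingleMetalBLM:
    """Joint estimation of BL constants from EC50s across bioassay media.

    Parameters
    ----------
    assays : sequence of (SolutionComposition, ec50_or_data)
        One entry per bioassay medium.  The second element is either the
        EC50 expressed as free-ion activity (mol/L) or a pair of arrays
        (exposure, RNE%) from which the EC50 is first fitted with the
        log-logistic model.
    metal : "Cu" | "Co"
    complexes : sequence of species names whose BL constants are estimated
        (default: the carbonate/hydroxide species for Cu, the bicarbonate
        complex for Co — the species the speciation module tracks).
    constants, include_ion_pairs : forwarded to the speciation solver.
    include_unity_term : use the conventional "+1" occupancy denominator.
    """

    _DEFAULT_COMPLEXES = {
        "Cu": ("CuHCO3+", "CuCO3(aq)", "CuOH+"),
        "Co": ("CoHCO3+",),
    }

    def __init__(self, assays: Sequence, metal: str = "Cu",
                 complexes: Sequence[str] | None = None,
                 constants=None, include_ion_pairs: bool = True,
                 include_unity_term: bool = True,
                 specs: Sequence[SpeciationResult] | None = None):
        if metal not in _FREE_ION:
            raise InvalidInputError(f"metal must be Cu or Co, got {metal!r}")
        if len(assays) == 0:
            raise InvalidInputError("no assays supplied")
        self.metal = metal
        self.complexes = tuple(
            complexes if complexes is not None else self._DEFAULT_COMPLEXES[metal]
        )
        self.include_unity_term = include_unity_term
        self.media: list[SolutionComposition] = []
        ec50s = []
        for comp, payload in assays:
            self.media.append(comp)
            if np.isscalar(payload):
                ec50 = float(payload)
            else:
                from .dose_response import fit_loglogistic

                ec50 = fit_loglogistic(tuple(payload)).x50
            if ec50 <= 0:
                raise InvalidInputError("EC50 values must be > 0")
            ec50s.append(ec50)
        self.ec50s = np.asarray(ec50s)
        self._check_design()
        if specs is not None:
            if len(specs) != len(self.media):
                raise InvalidInputError("specs must match assays one-to-one")
            self.specs = list(specs)
        else:
            self.specs = [
                speciate(c, constants, include_ion_pairs=include_ion_pairs)
                for c in self.media
            ]
        self._mg_act = np.array([s.activities["Mg2+"] for s in self.specs])
        self._lam = np.array(
            [[s.complex_ratios[metal][im] for im in self.complexes] for s in self.specs]
        )

    def _check_design(self):
        ph = np.array([m.pH for m in self.media])
        mg = np.array([m.total("Mg") for m in self.media])
        mg_levels_at_fixed_ph = max(
            (np.unique(np.round(mg[ph == p], 12)).size for p in np.unique(ph)),
            default=0,
        )
        ph_levels_at_fixed_mg = max(
            (np.unique(ph[np.isclose(mg, m)]).size for m in np.unique(mg)),
            default=0,
        )
        if mg_levels_at_fixed_ph < 3:
            raise NonIdentifiableError(
                "need >= 3 Mg levels at fixed pH to identify Mg competition",
                axis="Mg",
            )
        if self.complexes and ph_levels_at_fixed_mg < 3:
            raise NonIdentifiableError(
                "need >= 3 pH levels at fixed Mg to identify complex binding",
                axis="pH",
            )

    # model on identifiable parameters:
    #   log10 EC50 = log10 S0 + log10(u + K_Mg {Mg}) - log10(1 + sum k_IM lam)
    def _model_log_ec50(self, theta):
        log_s0, log_kmg = theta[0], theta[1]
        log_k = theta[2:]
        u = 1.0 if self.include_unity_term else 0.0
        comp_term = u + 10.0 ** log_kmg * self._mg_act
        complex_term = 1.0 + self._lam @ (10.0 ** log_k)
        return log_s0 + np.log10(comp_term) - np.log10(complex_term)

    def fit(self, f50: float | None = None, f50_grid=None) -> BLMFitResults:
        """Estimate the BL constants.

        With ``f50`` given (recommended) the absolute logK values are fully
        determined.  With ``f50=None`` the identifiable fit is unchanged and
        f50 is profiled over ``f50_grid`` (default 0.1..0.9): every grid
        value reproduces the data equally well, so the spec'd tie-break
        (lowest residual, then lowest f50) applies and a warning is issued.
        """
        y = np.log10(self.ec50s)
        n_im = len(self.complexes)

        def resid(theta):
            return self._model_log_ec50(theta) - y

        lb = [-14.0, 0.0] + [-8.0] * n_im
        ub = [2.0, 10.0] + [6.0] * n_im
        med_mg = float(np.median(self._mg_act))
        best, trace = None, []
        for kmg0 in (1.0, 2.5, 4.0, 5.5):
            s0_0 = float(np.median(y) - np.log10(1.0 + 10.0 ** kmg0 * med_mg))
            for k0 in (-1.0, 1.0):
                x0 = np.clip([s0_0, kmg0] + [k0] * n_im, lb, ub)
                try:
                    sol = least_squares(
                        resid, x0=x0, bounds=(lb, ub), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    trace.append((kmg0, k0, repr(exc)))
                    continue
                trace.append((kmg0, k0, sol.cost))
                if best is None or sol.cost < best.cost - 1e-18:
                    best = sol
        if best is None:
            raise FitError("BLM fit failed from every start", trace)

        profiled = f50 is None
        if profiled:
            grid = np.asarray(f50_grid if f50_grid is not None else np.arange(0.1, 0.91, 0.1))
            # residuals are identical along the ridge; tie-break: lowest f50
            f50 = float(np.min(grid))
            warnings.warn(
                "f50 is not identifiable from EC50-level data (flat ridge with "
                "the K scale); profiled over the grid and tie-broken at the "
                "lowest f50 — supply f50 to anchor absolute constants",
                stacklevel=2,
            )
        if not 0.0 < f50 < 1.0:
            raise InvalidInputError(f"f50 must lie in (0, 1), got {f50}")

        log_A = float(np.log10(f50 / (1.0 - f50)))
        theta = best.x
        logK_MBL = log_A - theta[0]
        logK_Mg = float(theta[1])
        logK_IM = {im: float(theta[2 + i] + logK_MBL) for i, im in enumerate(self.complexes)}

        params = BLMParameters(
            metal=self.metal,
            logK_MBL=float(logK_MBL),
            logK_XBL={"Mg2+": logK_Mg},
            logK_IMBL=logK_IM,
            f50=float(f50),
        )

        # delta-method SEs: transforms of theta (f50 held fixed)
        n, p = y.size, theta.size
        se = {}
        if n > p:
            ss_res = 2.0 * best.cost
            try:
                cov = np.linalg.pinv(best.jac.T @ best.jac) * ss_res / (n - p)
                T = np.zeros((2 + n_im, p))
                T[0, 0] = -1.0                      # logK_MBL = logA - theta0
                T[1, 1] = 1.0                       # logK_Mg
                for i in range(n_im):               # logK_IM = theta_i - theta0 + logA
                    T[2 + i, 0] = -1.0
                    T[2 + i, 2 + i] = 1.0
                variances = np.clip(np.diag(T @ cov @ T.T), 0.0, None)
                names = ["logK_MBL", "Mg2+"] + list(self.complexes)
                se = {nm: float(np.sqrt(v)) for nm, v in zip(names, variances)}
            except np.linalg.LinAlgError:  # pragma: no cover
                pass

        fitted = 10.0 ** self._model_log_ec50(theta)
        ss_res = float(np.sum((y - np.log10(fitted)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return BLMFitResults(
            params=params,
            se_logK=se,
            ec50_observed=self.ec50s.copy(),
            ec50_fitted=fitted,
            media_labels=[m.label for m in self.media],
            r2_log=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            rmse_log=float(np.sqrt(ss_res / n)),
            f50_profiled=profiled,
        )


def fit_single_metal_blm(assays, metal: str = "Cu", *, f50: float | None = None,
                         complexes=None, constants=None,
                         include_unity_term: bool = True,
                         include_ion_pairs: bool = True) -> BLMFitResults:
    """Functional wrapper around :class:`SingleMetalBLM` (see its docs)."""
    model = SingleMetalBLM(
        assays, metal=metal, complexes=complexes, constants=constants,
        include_ion_pairs=include_ion_pairs, include_unity_term=include_unity_term,
    )
    return model.fit(f50=f50)


def linear_mg_regression(ec50s, mg_activities) -> dict:
    """OLS of EC50{M2+} on {Mg2+}: slope, intercept, R^2, p-value.

    Under the no-complex BLM the slope/intercept ratio estimates K_MgBL.
    Fewer than 3 points raise InvalidInputError; a design without at least
    two distinct {Mg2+} values is flagged with a rank-deficiency warning.
    """
    y = np.asarray(ec50s, dtype=float)
    x = np.asarray(mg_activities, dtype=float)
    if y.size != x.size:
        raise InvalidInputError("ec50s and mg_activities must have equal length")
    if y.size < 3:
        raise InvalidInputError("need >= 3 points for the Mg regression")
    if np.unique(x).size < 2:
        warnings.warn("rank-deficient design: all {Mg2+} values identical", stacklevel=2)
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "p": np.nan, "k_mg": np.nan}
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(res.rsquared),
        "p": float(res.pvalues[1]),
        "k_mg": float(slope / intercept) if intercept != 0 else np.inf,
    }
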