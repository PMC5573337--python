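"""Forward simulation of complete bioassay studies.

Generates synthetic single-metal and mixture root-elongation datasets with
the statistical structure the analysis pipeline assumes: the twelve study
media (Mg and pH series), geometric dose grids (seven Cu levels 0.2-12.8
uM, seven Co levels 20-1280 uM, seven 1:100 Cu:Co mixture levels, plus an
undosed control), triplicate observations, and additive Gaussian noise on
RNE (default sigma = 5 percentage points, typical root-elongation assay
scatter).

Forward models
--------------
Single metal (default, ``response_scale="free_ion"``): per medium the BLM
predicts EC50{M2+} from the binding constants, and true RNE follows the
log-logistic curve in free-ion activity — the scale on which single-metal
dose-response fits are reported.  ``response_scale="site_fraction"`` uses
RNE = 100/(1 + (f/f50)^beta) on the occupancy scale instead; note that the
occupancy curve saturates (f <= 1), so it is not exactly log-logistic in
{M2+} and, for f50 near 1, cannot reach full inhibition.

Mixture: RNE = 100/(1 + (TU_f/lambda)^beta) with TU_f the BLM toxic units
of the speciated mixture; lambda = 1 generates exact additivity, lambda < 1
synergism, lambda > 1 antagonism (the truth block records lambda).

All randomness flows from one integer seed through fixed per-purpose
spawn keys, so the order in which generators are called cannot change any
stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_study
from .blm_single import BLMParameters, predict_ec50_free_ion
from .exceptions import ConfigError, InvalidInputError
from .mixture_tu import mixture_site_fractions, toxic_units_blm
from .speciation import SolutionComposition, speciate

__all__ = [
    "StudyDesign",
    "SyntheticDataset",
    "default_design",
    "simulate_single_metal_assay",
    "simulate_mixture_assay",
]

_PURPOSE = {"single_Cu": 1, "single_Co": 2, "mixture": 3}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    if not 0 <= int(seed) < 2**31:
        raise InvalidInputError("seed must be a non-negative 31-bit integer")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_PURPOSE[purpose],)))


@dataclass(frozen=True)
class StudyDesign:
    """Media, dose grids, replication and noise of one synthetic study."""

    media: tuple[SolutionComposition, ...]
    cu_doses_uM: tuple[float, ...]
    co_doses_uM: tuple[float, ...]
    mixture_cu_doses_uM: tuple[float, ...]
    mixture_ratio: float = 100.0      # molar Co:Cu in mixture treatments
    replicates: int = 3
    noise_sd_rne: float = 5.0         # percentage points, Gaussian on RNE
    ec50_noise_cv: float = 0.10       # lognormal CV for EC50-level noise

    def __post_init__(self):
        for grid in (self.cu_doses_uM, self.co_doses_uM, self.mixture_cu_doses_uM):
            arr = np.asarray(grid)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise InvalidInputError("dose grids must be strictly increasing")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if self.mixture_ratio <= 0:
            raise InvalidInputError("mixture ratio must be > 0")
        if self.noise_sd_rne < 0 or self.ec50_noise_cv < 0:
            raise ConfigError("noise parameters must be >= 0")


def default_design() -> StudyDesign:
    """The reference study design: 12 media, 2x geometric dose grids,
    triplicates, 5%-point RNE noise."""
    two_fold = tuple(0.2 * 2.0 ** k for k in range(7))           # 0.2 .. 12.8 uM
    return StudyDesign(
        media=tuple(reference_study.study_media()),
        cu_doses_uM=two_fold,
        co_doses_uM=tuple(100.0 * d for d in two_fold),          # 20 .. 1280 uM
        mixture_cu_doses_uM=two_fold,
        mixture_ratio=100.0,
        replicates=3,
    )


@dataclass
class SyntheticDataset:
    """Observation table plus the generating truth.

    ``data`` has one row per (medium, dose, replicate) with the exposure
    metric, the noise-free response and the noisy response; ``truth`` holds
    everything needed to score any estimator (parameters, per-medium true
    EC50s, lambda, seed).
    """

    data: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(directory / "bioassay.csv", index=False)
        with open(directory / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def _dosed(medium: SolutionComposition, cu_uM: float, co_uM: float) -> SolutionComposition:
    totals = dict(medium.totals)
    totals["Cu"] = cu_uM * 1e-6
    totals["Co"] = co_uM * 1e-6
    return replace(medium, totals=totals)


def simulate_single_metal_assay(design: StudyDesign, params: BLMParameters,
                                *, beta: float | None = None,
                                noise_sd: float | None = None,
                                seed: int = 0,
                                response_scale: str = "free_ion",
                                constants=None) -> SyntheticDataset:
    """Simulate the single-metal assay for ``params.metal`` over all media.

    Same seed => identical dataset.  ``noise_sd`` overrides the design's
    RNE noise (0 gives noise-free data); ``beta`` overrides the slope in
    ``params``.
    """
    if response_scale not in ("free_ion", "site_fraction"):
        raise ConfigError(f"unknown response_scale {response_scale!r}")
    metal = params.metal
    beta = float(beta if beta is not None else params.beta)
    sd = design.noise_sd_rne if noise_sd is None else float(noise_sd)
    rng = _rng(seed, f"single_{metal}")
    doses = design.cu_doses_uM if metal == "Cu" else design.co_doses_uM

    rows = []
    truth_ec50 = {}
    for medium in design.media:
        blank = speciate(medium, constants)
        ec50 = predict_ec50_free_ion(params, blank)
        truth_ec50[medium.label] = ec50
        for dose in (0.0, *doses):
            dosed = medium if dose == 0.0 else _dosed(
                medium, dose if metal == "Cu" else 0.0,
                dose if metal == "Co" else 0.0,
            )
            spec = blank if dose == 0.0 else speciate(dosed, constants)
            act = spec.activities[params.free_ion]
            if response_scale == "free_ion":
                rne_true = 100.0 / (1.0 + (act / ec50) ** beta) if act > 0 else 100.0
                f = float("nan")
            else:
                from .blm_single import fraction_occupied

                f = fraction_occupied(spec, params)
                rne_true = 100.0 / (1.0 + (f / params.f50) ** beta) if f > 0 else 100.0
            noise = rng.normal(0.0, sd, size=design.replicates) if sd > 0 else np.zeros(design.replicates)
            for rep in range(design.replicates):
                rows.append({
                    "medium": medium.label, "Mg_mM": medium.total("Mg") * 1e3,
                    "pH": medium.pH, "metal": metal,
                    "dose_uM": dose, "free_ion_activity_M": act,
                    "site_fraction": f, "replicate": rep + 1,
                    "rne_true_pct": rne_true,
                    "rne_pct": rne_true + noise[rep],
                })
    data = pd.DataFrame(rows)
    truth = {
        "kind": "single_metal", "metal": metal, "beta": beta,
        "response_scale": response_scale, "noise_sd_rne": sd, "seed": int(seed),
        "params": params.as_dict(),
        "ec50_free_ion_M": truth_ec50,
    }
    return SyntheticDataset(data=data, truth=truth)


def simulate_mixture_assay(design: StudyDesign,
                           params_Cu: BLMParameters, params_Co: BLMParameters,
                           *, ratio: float | None = None,
                           interaction: float = 1.0,
                           beta: float = 4.04,
                           noise_sd: float | None = None,
                           seed: int = 0,
                           constants=None) -> SyntheticDataset:
    """Simulate the Cu-Co mixture assay (Co = ratio x Cu, default 1:100).

    ``interaction`` is the TU50 shift lambda: RNE = 100/(1+(TU_f/lambda)^beta);
    1.0 generates exact BLM additivity.
    """
    ratio = float(ratio if ratio is not None else design.mixture_ratio)
    if ratio <= 0:
        raise InvalidInputError("ratio must be > 0")
    if interaction <= 0:
        raise InvalidInputError("interaction lambda must be > 0")
    sd = design.noise_sd_rne if noise_sd is None else float(noise_sd)
    rng = _rng(seed, "mixture")

    rows = []
    for medium in design.media:
        for cu in (0.0, *design.mixture_cu_doses_uM):
            co = ratio * cu
            dosed = medium if cu == 0.0 else _dosed(medium, cu, co)
            spec = speciate(dosed, constants)
            if cu == 0.0:
                f_cu = f_co = tu_f = 0.0
            else:
                f_cu, f_co = mixture_site_fractions(spec, params_Cu, params_Co)
                tu_f = toxic_units_blm(f_cu, f_co, params_Cu, params_Co)
            rne_true = 100.0 / (1.0 + (tu_f / interaction) ** beta) if tu_f > 0 else 100.0
            noise = rng.normal(0.0, sd, size=design.replicates) if sd > 0 else np.zeros(design.replicates)
            for rep in range(design.replicates):
                rows.append({
                    "medium": medium.label, "Mg_mM": medium.total("Mg") * 1e3,
                    "pH": medium.pH,
                    "cu_dose_uM": cu, "co_dose_uM": co,
                    "cu_activity_M": spec.activities["Cu2+"],
                    "co_activity_M": spec.activities["Co2+"],
                    "f_Cu": f_cu, "f_Co": f_co, "tu_f": tu_f,
                    "replicate": rep + 1,
                    "rne_true_pct": rne_true,
                    "rne_pct": rne_true + noise[rep],
                })
    data = pd.DataFrame(rows)
    truth = {
        "kind": "mixture", "ratio_co_per_cu": ratio, "beta": beta,
        "interaction_lambda": float(interaction),
        "noise_sd_rne": sd, "seed": int(seed),
        "params_Cu": params_Cu.as_dict(), "params_Co": params_Co.as_dict(),
    }
    return SyntheticDataset(data=data, truth=truth)
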