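"""Estimation of missing partition coefficients.

Fat:blood coefficients for a gas are derived from Ostwald solubility
coefficients as (olive oil:gas)/(blood:gas) — olive-oil solubility stands
in for fat (for argon: 0.154 / 0.037 = 4.162).  Other tissue:blood
coefficients can then be predicted from fat:blood via ordinary
least-squares linear correlations trained on gases with measured values.

The shipped parameter library carries final tabulated coefficients as
data; this module is the estimator for extending the library to new gases,
not a build-time generator of the shipped tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "SolubilityRecord",
    "TissueCorrelation",
    "fat_blood_pc",
    "fit_tissue_correlation",
    "predict_tissue_pc",
    "load_solubility_records",
    "save_correlation",
    "load_correlation",
]

VALID_MEDIA = ("blood", "olive_oil")


@dataclass(frozen=True)
class SolubilityRecord:
    """Ostwald solubility coefficient of one gas in one medium (37 °C,
    dimensionless: volume of gas dissolved per volume of liquid)."""

    gas_name: str
    medium: str
    ostwald_coefficient: float

    def __post_init__(self) -> None:
        if self.medium not in VALID_MEDIA:
            raise ValueError(
                f"medium must be one of {VALID_MEDIA}, got {self.medium!r}"
            )
        if self.ostwald_coefficient <= 0:
            raise ValueError("Ostwald coefficient must be > 0")


@dataclass(frozen=True)
class TissueCorrelation:
    """OLS line tissue:blood = slope × fat:blood + intercept."""

    tissue_name: str
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float
    n_training: int

    def __post_init__(self) -> None:
        if self.n_training < 2:
            raise ValueError("a correlation needs at least two training gases")


def fat_blood_pc(
    oil_gas: SolubilityRecord, blood_gas: SolubilityRecord
) -> float:
    """Fat:blood partition coefficient as (olive oil:gas)/(blood:gas)."""
    if oil_gas.gas_name != blood_gas.gas_name:
        raise ValueError(
            f"solubility records are for different gases: "
            f"{oil_gas.gas_name!r} vs {blood_gas.gas_name!r}"
        )
    if oil_gas.medium != "olive_oil" or blood_gas.medium != "blood":
        raise ValueError("expected an olive_oil record and a blood record")
    return oil_gas.ostwald_coefficient / blood_gas.ostwald_coefficient


def fit_tissue_correlation(
    training: Sequence[tuple[float, float]], tissue_name: str = "tissue"
) -> TissueCorrelation:
    """Fit tissue:blood = slope × fat:blood + intercept by OLS.

    ``training`` holds (fat_blood_pc, tissue_blood_pc) pairs, one per gas.
    """
    if len(training) < 2:
        raise ValueError("need at least two training points")
    x = np.asarray([p[0] for p in training], dtype=float)
    y = np.asarray([p[1] for p in training], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate training set: all fat:blood values equal")
    fit = stats.linregress(x, y)
    return TissueCorrelation(
        tissue_name=tissue_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
        n_training=len(training),
    )


def predict_tissue_pc(correlation: TissueCorrelation, fat_blood: float) -> float:
    """Predict a tissue:blood PC from a fat:blood PC along the fitted line."""
    if fat_blood <= 0:
        raise ValueError("fat:blood PC must be > 0")
    pred = correlation.slope * fat_blood + correlation.intercept
    if pred <= 0:
        raise ValueError(
            f"predicted {correlation.tissue_name} PC is non-positive "
            f"({pred:.4g}); fat:blood {fat_blood:.4g} is outside the "
            f"correlation's valid range"
        )
    return float(pred)


# --- structured-text round trip (parameter-library schema) ----------------


def load_solubility_records(path: Path) -> list[SolubilityRecord]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "solubility" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'solubility' list")
    out = []
    for rec in doc["solubility"]:
        unknown = set(rec) - {"gas", "medium", "ostwald"}
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        out.append(
            SolubilityRecord(rec["gas"], rec["medium"], float(rec["ostwald"]))
        )
    return out


def save_correlation(correlation: TissueCorrelation, path: Path) -> None:
    doc = {
        "correlation": {
            "tissue": correlation.tissue_name,
            "slope": correlation.slope,
            "intercept": correlation.intercept,
            "r_squared": correlation.r_squared,
            "slope_stderr": correlation.slope_stderr,
            "intercept_stderr": correlation.intercept_stderr,
            "n_training": correlation.n_training,
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_correlation(path: Path) -> TissueCorrelation:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        c = doc["correlation"]
        return TissueCorrelation(
            tissue_name=c["tissue"],
            slope=float(c["slope"]),
            intercept=float(c["intercept"]),
            r_squared=float(c["r_squared"]),
            slope_stderr=float(c["slope_stderr"]),
            intercept_stderr=float(c["intercept_stderr"]),
            n_training=int(c["n_training"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: not a correlation file ({exc})") from exc
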