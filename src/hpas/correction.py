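"""Composition-based multi-linear correction of semiempirical properties.

A cheap tight-binding calculation (GFN1-xTB) and a DFT calculation
(CAM-B3LYP-D3BJ/def2-SVP) of the same molecule are strongly linearly
related, with offsets that depend on elemental composition — most notably a
large per-sulfur shift in the total energy.  The correction model is
therefore an 8-parameter linear map per property:

    corrected = sum_e coef_e * n_e  +  beta * baseline  +  intercept

with e over {H, C, B, S, O, N}, ``baseline`` the semiempirical value and
``beta`` a dimensionless slope.  The shipped default coefficients were
fitted on 52,000 paired calculations (80/20 train/test split); refitting on
any paired table uses plain OLS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

logger = logging.getLogger(__name__)

ELEMENTS = ("h", "c", "b", "s", "o", "n")

#: Property keys, in table order, mapped to their units.
PROPERTY_UNITS = {
    "homo": "eV",
    "lumo": "eV",
    "gap": "eV",
    "aip": "eV",
    "aea": "eV",
    "energy": "Eh",
}

# Shipped coefficients: per-property (h, c, b, s, o, n, baseline, intercept).
# Orbital/gap/AIP/AEA models are in eV, the total-energy model in Eh.  Note
# the anomalously large sulfur coefficient of the total-energy model, which
# absorbs the per-sulfur offset between the two methods.
_DEFAULT_COEFFICIENTS = {
    "homo": (0.0124, 0.0065, -0.0423, -0.0370, 0.0258, -0.0253, 1.2397, 6.2841),
    "lumo": (0.0160, -0.0079, -0.0862, -0.0303, 0.0238, -0.0093, 1.0648, 8.1821),
    "gap": (0.0263, -0.0245, -0.0358, 0.0222, 0.0190, 0.0331, 1.1815, 3.4427),
    "aip": (0.0061, 0.0088, 0.0608, 0.0824, 0.0042, 0.0538, 1.3537, -10.3931),
    "aea": (0.0504, -0.0103, -0.1113, 0.0012, 0.0469, 0.0164, 0.8820, 4.6421),
    "energy": (-0.2102, -36.3793, -23.6932, -395.1947, -71.4597, -52.1923, 0.7880, 0.1285),
}


@dataclass(frozen=True)
class CorrectionModel:
    """Linear correction for one property: 6 element terms + baseline + intercept."""

    property_key: str
    element_coefs: dict[str, float]
    baseline_coef: float
    intercept: float
    units: str = "eV"

    def __post_init__(self):
        if set(self.element_coefs) != set(ELEMENTS):
            raise ContractError("element_coefs must cover exactly h,c,b,s,o,n")

    @property
    def n_parameters(self) -> int:
        return len(self.element_coefs) + 2

    def parameter_vector(self) -> np.ndarray:
        """(coef_h, ..., coef_n, baseline_coef, intercept) as an array."""
        return np.array(
            [self.element_coefs[e] for e in ELEMENTS]
            + [self.baseline_coef, self.intercept]
        )

    def to_dict(self) -> dict:
        return {
            "property": self.property_key,
            "units": self.units,
            **{e: self.element_coefs[e] for e in ELEMENTS},
            "baseline": self.baseline_coef,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CorrectionModel":
        return cls(
            property_key=payload["property"],
            element_coefs={e: float(payload[e]) for e in ELEMENTS},
            baseline_coef=float(payload["baseline"]),
            intercept=float(payload["intercept"]),
            units=payload.get("units", "eV"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary: R^2 (None when undefined), RMSE and MAE."""

    r2: float | None
    rmse: float
    mae: float
    n_train: int = 0
    n_test: int = 0


@dataclass
class PairedPropertyTable:
    """Per-molecule element counts, baseline (semiempirical) and reference
    (DFT) values for one property.

    ``data`` must hold the columns h,c,b,s,o,n (nonnegative integers),
    ``baseline`` and ``reference`` (finite floats).
    """

    data: pd.DataFrame
    property_key: str = "homo"
    units: str = "eV"

    REQUIRED = (*ELEMENTS, "baseline", "reference")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ContractError(f"paired table lacks columns: {missing}")
        counts = self.data[list(ELEMENTS)]
        if (counts < 0).any().any():
            raise ContractError("element counts must be nonnegative")
        if not np.allclose(counts, counts.round()):
            raise ContractError("element counts must be integers")
        values = self.data[["baseline", "reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ContractError("baseline/reference values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def design_matrix(self) -> np.ndarray:
        """Regressor columns (h,...,n, baseline), without the intercept."""
        return self.data[[*ELEMENTS, "baseline"]].to_numpy(dtype=float)


def default_models() -> dict[str, CorrectionModel]:
    """The six shipped correction models (HOMO, LUMO, Gap, AIP, AEA, E_tot)."""
    models = {}
    for key, units in PROPERTY_UNITS.items():
        *elem, baseline, intercept = _DEFAULT_COEFFICIENTS[key]
        models[key] = CorrectionModel(
            property_key=key,
            element_coefs=dict(zip(ELEMENTS, elem)),
            baseline_coef=baseline,
            intercept=intercept,
            units=units,
        )
    return models


def apply_correction(
    model: CorrectionModel, counts: dict[str, int], baseline: float
) -> float:
    """Correct one baseline value given the molecule's element counts."""
    missing = [e for e in ELEMENTS if e not in counts]
    if missing:
        raise ContractError(f"missing element counts: {missing}")
    total = model.intercept + model.baseline_coef * baseline
    for e in ELEMENTS:
        total += model.element_coefs[e] * counts[e]
    return float(total)


def apply_correction_frame(model: CorrectionModel, frame: pd.DataFrame) -> pd.Series:
    """Vectorized correction over a DataFrame with h..n and ``baseline`` columns."""
    missing = [c for c in (*ELEMENTS, "baseline") if c not in frame.columns]
    if missing:
        raise ContractError(f"missing columns: {missing}")
    x = frame[[*ELEMENTS, "baseline"]].to_numpy(dtype=float)
    beta = model.parameter_vector()
    return pd.Series(x @ beta[:-1] + beta[-1], index=frame.index)


def regression_metrics(predicted, reference) -> FitMetrics:
    """R^2, RMSE and MAE of predictions against reference values."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size == 0:
        raise ContractError("predicted and reference must be equal-length, nonempty")
    residuals = predicted - reference
    rmse = float(np.sqrt(np.mean(residuals**2)))
    mae = float(np.mean(np.abs(residuals)))
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("reference values have zero variance; R^2 undefined")
        r2 = None
    else:
        r2 = float(1.0 - np.sum(residuals**2) / ss_tot)
    return FitMetrics(r2=r2, rmse=rmse, mae=mae, n_test=predicted.size)


def fit_correction(
    table: PairedPropertyTable,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[CorrectionModel, FitMetrics]:
    """Fit the 8-parameter linear correction by OLS on a random train split.

    Rows are shuffled with the given seed and split ``split_fraction`` /
    ``1 - split_fraction`` into train and test; coefficients are estimated on
    the train split by least squares and the metrics are computed on the
    held-out split.  A regressor column that is identically zero (an element
    absent from every molecule) is excluded from the solve, its coefficient
    pinned to 0, with a warning.
    """
    n = len(table)
    if n < 9:
        raise ContractError("need at least 9 rows to fit 8 parameters")
    if not 0.0 < split_fraction < 1.0:
        raise ContractError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx, test_idx = order[:n_train], order[n_train:]

    x = table.design_matrix()
    y = table.data["reference"].to_numpy(dtype=float)
    active = np.array([x[:, j].any() for j in range(x.shape[1])])
    if not active.all():
        names = [n_ for n_, a in zip((*ELEMENTS, "baseline"), active) if not a]
        logger.warning("regressors %s are identically zero; pinned to 0", names)
    design = np.column_stack([x[train_idx][:, active], np.ones(len(train_idx))])
    solution, *_ = np.linalg.lstsq(design, y[train_idx], rcond=None)

    beta = np.zeros(x.shape[1] + 1)
    beta[np.flatnonzero(active)] = solution[:-1]
    beta[-1] = solution[-1]
    model = CorrectionModel(
        property_key=table.property_key,
        element_coefs=dict(zip(ELEMENTS, beta[: len(ELEMENTS)])),
        baseline_coef=float(beta[len(ELEMENTS)]),
        intercept=float(beta[-1]),
        units=table.units,
    )
    predicted = x[test_idx] @ beta[:-1] + beta[-1]
    metrics = regression_metrics(predicted, y[test_idx])
    return model, FitMetrics(
        r2=metrics.r2,
        rmse=metrics.rmse,
        mae=metrics.mae,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
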