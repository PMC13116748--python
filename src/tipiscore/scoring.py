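"""SII and TIPI composite score computation and risk-group assignment.

The systemic immune-inflammation index (SII) is

    SII = platelets * neutrophils / lymphocytes        [counts in 1e9/L]

and the Tumor-Immune-Proliferation-Inflammation (TIPI) score is

    TIPI = (Ki-67% + stromal TILs% + 10 * grade) / (1 + SII / 1000).

The numerator aggregates tumour proliferation, local immune infiltration and
histological aggressiveness (grade is multiplied by 10 to place the 1-3
ordinal on a percentage-like scale); the denominator shrinks the score as the
systemic inflammatory burden grows, reflecting its immunosuppressive effect.
Higher TIPI therefore denotes a biology expected to favour pathological
complete response.

The risk-group cut-off is a cohort-specific constant, not part of the score:
it is normally re-derived on each dataset by Youden-index selection (see
:mod:`tipiscore.roc`), and the published 11.41 is exposed only as a config
default for reproducing the original cohort's stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TIPIComponents",
    "RiskGroup",
    "DEFAULT_CUTOFF",
    "compute_sii",
    "compute_tipi",
    "assign_risk_group",
    "TIPIScorer",
]

#: Risk-group cut-off of the original derivation cohort (Youden-optimal
#: there); data-derived in general and NOT part of the score definition.
DEFAULT_CUTOFF = 11.41


@dataclass(frozen=True)
class TIPIComponents:
    """The four score inputs plus the computed SII and TIPI values."""

    ki67_percent: float
    stromal_tils_percent: float
    grade: int
    sii: float
    tipi: float


@dataclass(frozen=True)
class RiskGroup:
    """TIPI risk-group label relative to a cut-off (high iff tipi > cutoff)."""

    label: str  # "low" | "high"
    cutoff: float


def _check_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(arr > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def compute_sii(neutrophils, lymphocytes, platelets):
    """Systemic immune-inflammation index: platelets * neutrophils / lymphocytes.

    All counts in 1e9 cells/L, strictly positive.  Accepts scalars or arrays.
    """
    for name, value in (
        ("neutrophils", neutrophils),
        ("lymphocytes", lymphocytes),
        ("platelets", platelets),
    ):
        _check_positive(name, value)
    out = np.asarray(platelets, dtype=float) * np.asarray(neutrophils, dtype=float) / np.asarray(
        lymphocytes, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def compute_tipi(ki67_percent, stromal_tils_percent, grade, sii):
    """TIPI = (Ki-67% + TILs% + 10*grade) / (1 + SII/1000).

    ``ki67_percent`` and ``stromal_tils_percent`` must lie in [0, 100],
    ``grade`` in {1, 2, 3} and ``sii`` must be positive.  Vectorised.
    """
    ki67 = np.asarray(ki67_percent, dtype=float)
    tils = np.asarray(stromal_tils_percent, dtype=float)
    grade_arr = np.asarray(grade)
    sii_arr = np.asarray(sii, dtype=float)
    if not (np.all(ki67 >= 0) and np.all(ki67 <= 100)):
        raise ValueError(f"ki67_percent must lie in [0, 100], got {ki67_percent!r}")
    if not (np.all(tils >= 0) and np.all(tils <= 100)):
        raise ValueError(f"stromal_tils_percent must lie in [0, 100], got {stromal_tils_percent!r}")
    if not np.all(np.isin(grade_arr, (1, 2, 3))):
        raise ValueError(f"grade must be in {{1,2,3}}, got {grade!r}")
    _check_positive("sii", sii_arr)
    out = (ki67 + tils + 10.0 * grade_arr.astype(float)) / (1.0 + sii_arr / 1000.0)
    return float(out) if out.ndim == 0 else out


def assign_risk_group(tipi: float, cutoff: float = DEFAULT_CUTOFF) -> RiskGroup:
    """Risk group: ``high`` iff tipi > cutoff (strict); the boundary is low."""
    if not (np.isfinite(tipi) and np.isfinite(cutoff)):
        raise ValueError("tipi and cutoff must be finite")
    return RiskGroup(label="high" if tipi > cutoff else "low", cutoff=float(cutoff))


class TIPIScorer(BaseEstimator, TransformerMixin):
    """Stateless transformer adding ``sii``, ``tipi`` and ``tipi_group`` columns.

    Parameters
    ----------
    cutoff : float or None, default None
        Risk-group cut-off.  When ``None`` no ``tipi_group`` column is added
        (use :class:`tipiscore.roc.YoudenCutoffClassifier` to derive one from
        outcomes).
    sii_unit_scale : float, default 1.0
        Multiplier applied to the computed SII before use, for inputs not in
        1e9/L.

    The transformer expects a DataFrame with ``ki67_percent``,
    ``stromal_tils_percent``, ``grade``, ``neutrophils``, ``lymphocytes`` and
    ``platelets`` columns (a :meth:`tipiscore.cohort.Cohort.to_dataframe`
    output qualifies).
    """

    def __init__(self, cutoff: float | None = None, sii_unit_scale: float = 1.0):
        self.cutoff = cutoff
        self.sii_unit_scale = sii_unit_scale

    def fit(self, X: pd.DataFrame, y=None) -> "TIPIScorer":
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate(X)
        out = X.copy()
        sii = compute_sii(
            out["neutrophils"].to_numpy(),
            out["lymphocytes"].to_numpy(),
            out["platelets"].to_numpy(),
        ) * self.sii_unit_scale
        tipi = compute_tipi(
            out["ki67_percent"].to_numpy(),
            out["stromal_tils_percent"].to_numpy(),
            out["grade"].to_numpy(),
            sii,
        )
        out["sii"] = sii
        out["tipi"] = tipi
        if self.cutoff is not None:
            out["tipi_group"] = np.where(tipi > self.cutoff, "high", "low")
        return out

    @staticmethod
    def _validate(X: pd.DataFrame) -> None:
        required = (
            "ki67_percent",
            "stromal_tils_percent",
            "grade",
            "neutrophils",
            "lymphocytes",
            "platelets",
        )
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")


def components_for(record) -> TIPIComponents:
    """Score a single :class:`tipiscore.cohort.PatientRecord`."""
    sii = compute_sii(record.neutrophils, record.lymphocytes, record.platelets)
    tipi = compute_tipi(record.ki67_percent, record.stromal_tils_percent, record.grade, sii)
    return TIPIComponents(
        ki67_percent=record.ki67_percent,
        stromal_tils_percent=record.stromal_tils_percent,
        grade=record.grade,
        sii=sii,
        tipi=tipi,
    )
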