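"""Calibration and method-agreement statistics.

The CT→DXA conversion is an ordinary least-squares calibration line
``mass_kg = slope * volume_L + intercept`` per tissue component, with 95%
confidence intervals from the t distribution on n−2 degrees of freedom.
Agreement between predicted and reference (DXA) values is quantified with
Lin's concordance correlation coefficient

    r_c = 2·s_ab / (s_a² + s_b² + (ā − b̄)²)

(n-divisor moments, Lin 1989), its 95% CI via the inverse-hyperbolic-tangent
transform with Lin's large-sample standard error, and Bland-Altman limits of
agreement on percentage differences (bias ± 1.96·SD).  Qualitative category
labels follow the conventional correlation scale (perfect / very strong /
strong / moderate / poor / negligible) and the concordance agreement scale
judged on the *lower* 95% confidence limit (near perfect / substantial /
moderate / poor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .composition import (
    COMPONENT_TISSUE,
    ValidationRowSpec,
    validation_rows,
)
from .errors import DegenerateInputError

__all__ = [
    "CalibrationModel",
    "ConcordanceResult",
    "BlandAltmanResult",
    "ReportRow",
    "ValidationReport",
    "fit_calibration",
    "predict_mass",
    "lins_ccc",
    "bland_altman_pct",
    "categorize_correlation",
    "categorize_agreement",
    "validate_thresholds",
    "reliability_agreement",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear calibration ``y = slope*x + intercept`` (kg vs L)."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    n: int
    x_label: str = "volume_L"
    y_label: str = "mass_kg"

    @property
    def pearson_r(self) -> float:
        return float(np.sign(self.slope) * np.sqrt(self.r_squared))

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return f"y = {self.slope:.2f}x {sign} {abs(self.intercept):.2f}"


@dataclass(frozen=True)
class ConcordanceResult:
    """Lin's concordance coefficient with its 95% confidence interval."""

    rc: float
    ci: tuple[float, float]
    n: int
    pearson_r: float

    @property
    def lower_cl(self) -> float:
        return self.ci[0]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman statistics on percentage differences."""

    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int
    denominator: str = "mean"


def _paired(a: Sequence[float], b: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D sequences, got shapes {a.shape} and {b.shape}")
    if a.size < min_n:
        raise ValueError(f"need at least n={min_n} pairs, got {a.size}")
    return a, b


def fit_calibration(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_label: str = "volume_L",
    y_label: str = "mass_kg",
) -> CalibrationModel:
    """Ordinary least-squares calibration of mass (kg) on volume (L).

    95% CIs come from the t distribution with n−2 degrees of freedom;
    ``r_squared`` equals the squared Pearson correlation.
    """
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant: calibration fit is singular")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return CalibrationModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(res.rsquared),
        n=int(x.size),
        x_label=x_label,
        y_label=y_label,
    )


def predict_mass(model: CalibrationModel, volume: float | np.ndarray) -> float | np.ndarray:
    """Predicted mass (kg) from an abdominal volume (L): slope·x + intercept."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("volume must be non-negative")
    out = model.slope * volume + model.intercept
    return float(out) if out.ndim == 0 else out


def lins_ccc(a: Sequence[float], b: Sequence[float]) -> ConcordanceResult:
    """Lin's concordance correlation coefficient between two measurement
    sequences, with a 95% CI.

    Uses n-divisor (population) moments; the CI is obtained on the
    atanh scale with Lin's large-sample standard error and back-transformed.
    """
    a, b = _paired(a, b, 3)
    sa2 = float(a.var())  # ddof=0
    sb2 = float(b.var())
    if sa2 == 0 or sb2 == 0:
        raise DegenerateInputError("constant input sequence: concordance undefined")
    d = float(a.mean() - b.mean())
    sab = float(((a - a.mean()) * (b - b.mean())).mean())
    rc = 2.0 * sab / (sa2 + sb2 + d * d)
    r = sab / np.sqrt(sa2 * sb2)

    n = a.size
    if abs(rc) >= 1.0 - 1e-12:
        # numerically perfect (anti)concordance: snap and use a degenerate CI
        rc = float(np.copysign(1.0, rc))
        return ConcordanceResult(rc=rc, ci=(rc, rc), n=n, pearson_r=float(r))
    if r == 0.0:
        # uncorrelated data: Lin's large-sample SE diverges
        return ConcordanceResult(rc=float(rc), ci=(-1.0, 1.0), n=n, pearson_r=0.0)

    u2 = d * d / np.sqrt(sa2 * sb2)  # u², with u the scaled location shift
    one_m_rc2 = 1.0 - rc * rc
    var_z = (
        (1.0 - r * r) * rc * rc / (one_m_rc2 * r * r)
        + 2.0 * rc**3 * (1.0 - rc) * u2 / (r * one_m_rc2**2)
        - rc**4 * u2 * u2 / (2.0 * r * r * one_m_rc2**2)
    ) / (n - 2)
    se_z = float(np.sqrt(max(var_z, 0.0)))
    z = np.arctanh(rc)
    zcrit = scipy.stats.norm.ppf(0.975)
    ci = (float(np.tanh(z - zcrit * se_z)), float(np.tanh(z + zcrit * se_z)))
    return ConcordanceResult(rc=float(rc), ci=ci, n=n, pearson_r=float(r))


def bland_altman_pct(
    measured: Sequence[float],
    reference: Sequence[float],
    *,
    denominator: Literal["mean", "reference"] = "mean",
) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement on percentage differences.

    Per pair, ``d = 100·(measured − reference) / D`` where ``D`` is the
    pairwise mean (default) or the reference value.  LOA are
    ``bias ± 1.96·SD`` with the sample (n−1) standard deviation.
    """
    m, r = _paired(measured, reference, 2)
    denom = (m + r) / 2.0 if denominator == "mean" else r
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise DegenerateInputError(f"pair(s) at index {zero.tolist()} have zero {denominator}; "
                                   "percentage difference undefined")
    d = 100.0 * (m - r) / denom
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias_pct=bias,
        sd_pct=sd,
        loa_low_pct=bias - 1.96 * sd,
        loa_high_pct=bias + 1.96 * sd,
        n=m.size,
        denominator=denominator,
    )


#: (threshold, label) correlation scale applied to |r|; boundary values go to
#: the higher (stronger) category.
_CORRELATION_SCALE = [(0.90, "very strong"), (0.70, "strong"), (0.50, "moderate"),
                      (0.30, "poor"), (0.00, "negligible")]

#: agreement scale applied to the lower 95% confidence limit of r_c
_AGREEMENT_SCALE = [(0.99, "near perfect"), (0.95, "substantial"),
                    (0.90, "moderate")]


def categorize_correlation(r: float) -> str:
    """Qualitative label for a correlation coefficient (applied to |r|)."""
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    if a >= 1.0:
        return "perfect"
    for threshold, label in _CORRELATION_SCALE:
        if a >= threshold:
            return label
    return "negligible"


def categorize_agreement(lower_cl: float) -> str:
    """Qualitative agreement label judged on the lower 95% CL of r_c."""
    if abs(lower_cl) > 1 + 1e-12:
        raise ValueError(f"|lower_cl| must be <= 1, got {lower_cl}")
    if lower_cl >= 1.0:
        return "perfect"
    for threshold, label in _AGREEMENT_SCALE:
        if lower_cl >= threshold:
            return label
    return "poor"


@dataclass(frozen=True)
class ReportRow:
    """One row of the validation report: a (component, HU range) pairing."""

    component: str
    range_label: str
    annotation: Optional[str] = None
    excluded: bool = False
    calibration: Optional[CalibrationModel] = None
    concordance: Optional[ConcordanceResult] = None
    bland_altman: Optional[BlandAltmanResult] = None
    correlation_label: Optional[str] = None
    agreement_label: Optional[str] = None


@dataclass
class ValidationReport:
    """The table-shaped CT↔DXA validation output (one row per range)."""

    rows: list[ReportRow] = field(default_factory=list)
    ba_denominator: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {
                "component": row.component,
                "range": row.range_label,
                "excluded": row.excluded,
                "annotation": row.annotation or "",
            }
            if row.calibration is not None:
                cal, cc, ba = row.calibration, row.concordance, row.bland_altman
                rec.update(
                    equation=cal.equation(),
                    slope=cal.slope,
                    intercept=cal.intercept,
                    r_squared=cal.r_squared,
                    slope_ci_low=cal.slope_ci[0],
                    slope_ci_high=cal.slope_ci[1],
                    intercept_ci_low=cal.intercept_ci[0],
                    intercept_ci_high=cal.intercept_ci[1],
                    rc=cc.rc,
                    rc_ci_low=cc.ci[0],
                    rc_ci_high=cc.ci[1],
                    bias_pct=ba.bias_pct,
                    loa_low_pct=ba.loa_low_pct,
                    loa_high_pct=ba.loa_high_pct,
                    n=cal.n,
                    correlation=row.correlation_label,
                    agreement=row.agreement_label,
                )
            recs.append(rec)
        return pd.DataFrame(recs)


def _evaluate_row(
    volumes: np.ndarray,
    masses: np.ndarray,
    spec_row: ValidationRowSpec,
    *,
    ba_denominator: str,
    loo: bool,
) -> ReportRow:
    cal = fit_calibration(volumes, masses)
    if loo:
        pred = np.empty_like(masses)
        idx = np.arange(masses.size)
        for i in idx:
            keep = idx != i
            m = fit_calibration(volumes[keep], masses[keep])
            pred[i] = predict_mass(m, volumes[i])
    else:
        pred = predict_mass(cal, volumes)
    cc = lins_ccc(pred, masses)
    ba = bland_altman_pct(pred, masses, denominator=ba_denominator)  # type: ignore[arg-type]
    return ReportRow(
        component=spec_row.component,
        range_label=spec_row.range_label,
        annotation=spec_row.annotation,
        excluded=False,
        calibration=cal,
        concordance=cc,
        bland_altman=ba,
        correlation_label=categorize_correlation(cal.pearson_r),
        agreement_label=categorize_agreement(cc.lower_cl),
    )


def validate_thresholds(
    volumes: pd.DataFrame,
    dxa: pd.DataFrame,
    *,
    rows: Sequence[ValidationRowSpec] | None = None,
    ba_denominator: Literal["mean", "reference"] = "mean",
    loo: bool = False,
) -> ValidationReport:
    """Build the full CT↔DXA validation report.

    Parameters
    ----------
    volumes
        Tidy frame with columns ``subject``, ``component`` (total / fat /
        lean / bmc), ``range`` (HU label such as ``"-250/-25"``) and
        ``volume_l``.
    dxa
        Tidy frame with columns ``subject``, ``component`` and ``mass_kg``.
    rows
        Row specifications to evaluate; defaults to the full published set
        (including excluded rows, which emit annotation-only entries).
        Rows with no matching volume data are likewise emitted
        annotation-only.
    loo
        Leave-one-out prediction instead of the default in-sample agreement.
    """
    for col in ("subject", "component", "range", "volume_l"):
        if col not in volumes.columns:
            raise ValueError(f"volumes frame missing column {col!r}")
    for col in ("subject", "component", "mass_kg"):
        if col not in dxa.columns:
            raise ValueError(f"dxa frame missing column {col!r}")

    vol_subj = set(volumes["subject"])
    dxa_subj = set(dxa["subject"])
    if vol_subj != dxa_subj:
        only_v = sorted(vol_subj - dxa_subj)
        only_d = sorted(dxa_subj - vol_subj)
        raise ValueError(
            f"subject keys differ between volumes and DXA: only in volumes {only_v}, only in DXA {only_d}"
        )

    report = ValidationReport(ba_denominator=ba_denominator)
    for spec_row in (rows if rows is not None else validation_rows()):
        if spec_row.excluded:
            report.rows.append(
                ReportRow(
                    component=spec_row.component,
                    range_label=spec_row.range_label,
                    annotation=spec_row.annotation,
                    excluded=True,
                )
            )
            continue
        sel = volumes[
            (volumes["component"] == spec_row.component) & (volumes["range"] == spec_row.range_label)
        ]
        if sel.empty:
            report.rows.append(
                ReportRow(
                    component=spec_row.component,
                    range_label=spec_row.range_label,
                    annotation=spec_row.annotation or "no volume data for this range",
                )
            )
            continue
        masses = dxa[dxa["component"] == spec_row.component].set_index("subject")["mass_kg"]
        merged = sel.set_index("subject").join(masses, how="inner")
        report.rows.append(
            _evaluate_row(
                merged["volume_l"].to_numpy(),
                merged["mass_kg"].to_numpy(),
                spec_row,
                ba_denominator=ba_denominator,
                loo=loo,
            )
        )
    return report


def reliability_agreement(
    volumes_a: Sequence[float],
    volumes_b: Sequence[float],
    *,
    ba_denominator: Literal["mean", "reference"] = "mean",
) -> tuple[ConcordanceResult, BlandAltmanResult]:
    """Repeatability / reproducibility of segmentation volumes.

    Applies Lin's concordance and percentage Bland-Altman to paired repeat
    measurements (intra- or inter-observer).
    """
    a, b = _paired(volumes_a, volumes_b, 3)
    return lins_ccc(a, b), bland_altman_pct(a, b, denominator=ba_denominator)
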