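"""Prospective corrections: age/sex normative adjustment and phantom-based
affine scanner calibration onto a reference scanner.

The scanner map is fitted in the prediction direction — reference-scanner
phantom SBR regressed on site-scanner phantom SBR, paired by true fill
ratio — because the correction converts site measurements onto the
reference scale.  Procedure standardization (re-drawing VOIs with a common
method) is an image-level operation: on real data it enters as an
externally recomputed SBR column, on synthetic data as the generator's
known procedure bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Cohort, PhantomScan, phantom_frame
from .errors import CalibrationError, DegenerateDataError, ValidationError
from .simulate import LatentTruth


@dataclass
class AgeSexModel:
    """Linear age/sex normative model fitted on healthy controls.

    corrected = observed - age_slope*(age - ref_age) - sex_offset*1[male],
    per feature.  Fitting on HCs only keeps the disease effect out of the
    normative coefficients.
    """

    feature_names: list[str]
    age_slope: np.ndarray      # per feature, SBR units per year
    sex_offset: np.ndarray     # per feature, additive male offset
    ref_age: float
    n_hc: int
    age_slope_se: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class ScannerMap:
    slope: float
    intercept: float
    n_points: int
    residual_sd: float
    r_squared: float


@dataclass
class CalibrationModel:
    """Per-scanner affine maps onto the reference scanner's scale."""

    reference_scanner: str
    maps: dict[str, ScannerMap]


def fit_age_sex(cohort: Cohort, ref_age: float = 65.0) -> AgeSexModel:
    """OLS of each SBR feature on centered age and a male indicator, HCs only."""
    hc = cohort.data[cohort.data["diagnosis"] == "HC"]
    if len(hc) < 10:
        raise DegenerateDataError(
            f"age/sex fit needs >= 10 HC records, found {len(hc)}"
        )
    age = hc["age"].to_numpy(dtype=float)
    if age.max() - age.min() < 5.0:
        raise DegenerateDataError(
            "age/sex fit needs HC ages spanning >= 5 years; "
            f"span is {age.max() - age.min():.2f}"
        )
    male = (hc["sex"] == "M").to_numpy(dtype=float)
    if age.std() == 0.0:
        raise DegenerateDataError("degenerate covariate 'age': all HC ages identical")
    if male.std() == 0.0:
        raise DegenerateDataError("degenerate covariate 'sex': single-sex HC cohort")

    X = np.column_stack([np.ones_like(age), age - ref_age, male])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDataError("rank-deficient age/sex design (age collinear with sex)")
    y = cohort.values()[(cohort.data["diagnosis"] == "HC").to_numpy()]
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(hc) - X.shape[1], 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    slope_se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return AgeSexModel(
        feature_names=cohort.feature_names,
        age_slope=coef[1], sex_offset=coef[2],
        ref_age=ref_age, n_hc=len(hc), age_slope_se=slope_se,
    )


def apply_age_sex(cohort: Cohort, model: AgeSexModel) -> Cohort:
    """Subtract the fitted age trend and male offset from every record."""
    if model.feature_names != cohort.feature_names:
        raise ValidationError(
            f"age/sex model features {model.feature_names} do not match "
            f"cohort features {cohort.feature_names}"
        )
    age = cohort.data["age"].to_numpy(dtype=float)
    male = (cohort.data["sex"] == "M").to_numpy(dtype=float)
    adj = (np.outer(age - model.ref_age, model.age_slope)
           + np.outer(male, model.sex_offset))
    return cohort.with_values(
        cohort.values() - adj, stage="age_sex_corrected",
        note={"age_sex": {"ref_age": model.ref_age,
                          "age_slope": model.age_slope.tolist(),
                          "sex_offset": model.sex_offset.tolist()}},
    )


def fit_phantom_calibration(scans: list[PhantomScan],
                            reference_scanner: str) -> CalibrationModel:
    """Fit per-scanner affine maps site -> reference from phantom scans.

    Replicate measurements are averaged within each true ratio first; the
    reference scanner's averaged measurement at each ratio is then regressed
    on each site scanner's, paired by ratio.  The reference scanner maps to
    the exact identity.
    """
    df = phantom_frame(scans)
    if reference_scanner not in set(df["scanner"]):
        raise CalibrationError(
            f"reference scanner '{reference_scanner}' has no phantom scans"
        )
    means = (df.groupby(["scanner", "true_ratio"])["measured_sbr"]
               .mean().reset_index())
    ref = means[means["scanner"] == reference_scanner].set_index("true_ratio")

    maps: dict[str, ScannerMap] = {}
    for scanner, grp in means.groupby("scanner"):
        if scanner == reference_scanner:
            maps[scanner] = ScannerMap(1.0, 0.0, len(grp), 0.0, 1.0)
            continue
        grp = grp.set_index("true_ratio")
        common = grp.index.intersection(ref.index)
        if len(common) < 2:
            raise CalibrationError(
                f"scanner '{scanner}' shares {len(common)} phantom ratio(s) with "
                f"the reference; >= 2 distinct common ratios are required"
            )
        x = grp.loc[common, "measured_sbr"].to_numpy(dtype=float)
        y = ref.loc[common, "measured_sbr"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            raise CalibrationError(
                f"scanner '{scanner}' fitted a non-positive slope ({slope:.4g}); "
                "phantom data are pathological"
            )
        pred = slope * x + intercept
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        maps[scanner] = ScannerMap(
            slope=float(slope), intercept=float(intercept), n_points=len(common),
            residual_sd=float(np.sqrt(ss_res / max(len(common) - 2, 1))),
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        )
    return CalibrationModel(reference_scanner=reference_scanner, maps=maps)


def apply_calibration(cohort: Cohort, model: CalibrationModel) -> Cohort:
    """Map every record's SBR onto the reference-scanner scale.

    Reference-scanner records pass through unchanged (identity map).
    """
    scanners = cohort.data["scanner"]
    unknown = sorted(set(scanners) - set(model.maps))
    if unknown:
        raise ValidationError(f"no calibration fitted for scanner(s) {unknown}")
    slope = scanners.map({k: m.slope for k, m in model.maps.items()}).to_numpy(dtype=float)
    intercept = scanners.map({k: m.intercept for k, m in model.maps.items()}).to_numpy(dtype=float)
    vals = slope[:, None] * cohort.values() + intercept[:, None]
    return cohort.with_values(
        vals, stage="scanner_corrected",
        note={"calibration": {"reference_scanner": model.reference_scanner,
                              "maps": {k: [m.slope, m.intercept] for k, m in model.maps.items()}}},
    )


def prospective_correct(cohort: Cohort, model: CalibrationModel,
                        standardized_sbr: pd.DataFrame | None = None,
                        truth: LatentTruth | None = None) -> Cohort:
    """Full prospective correction: procedure standardization then scanner map.

    Real-data path: ``standardized_sbr`` supplies SBRs recomputed centrally
    with a standardized VOI method (columns ``id`` plus the cohort's sbr
    columns, aligned by id).  Synthetic path: the generator's known per-site
    procedure bias from ``truth`` is subtracted.  One of the two must be
    given — procedure effects cannot be estimated from the participant table
    alone, they live in the image processing.
    """
    if standardized_sbr is not None:
        std = standardized_sbr.set_index("id") if "id" in standardized_sbr.columns \
            else standardized_sbr
        missing = [i for i in cohort.ids if i not in std.index]
        if missing:
            raise ValidationError(
                f"standardized SBR table lacks id(s) {missing[:10]}"
            )
        cols = ["sbr_" + f for f in cohort.feature_names]
        for c in cols:
            if c not in std.columns:
                raise ValidationError(f"standardized SBR table lacks column '{c}'")
        vals = std.loc[cohort.ids, cols].to_numpy(dtype=float)
        path = "standardized_column"
    elif truth is not None:
        if truth.ids != cohort.ids.tolist():
            raise ValidationError("latent truth ids do not align with the cohort")
        vals = cohort.values() - truth.procedure_bias[:, None]
        path = "generator_truth"
    else:
        raise ValidationError(
            "prospective correction needs either a standardized SBR column or "
            "generator truth: procedure standardization requires image-level "
            "recomputation and cannot be derived from the participant table"
        )
    # interim stage skips the original-stage positivity check: removing a
    # positive procedure bias may push a floored value to zero legitimately
    interim = cohort.with_values(vals, stage="age_sex_corrected")
    corrected = apply_calibration(interim, model)
    return corrected.with_values(
        corrected.values(), stage="prospective",
        note={"prospective": {"procedure_path": path}},
    )
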