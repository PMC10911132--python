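"""Parametric empirical-Bayes ComBat harmonization.

Location/scale batch model per feature g, record j in batch i:

    Y_gj = alpha_g + X_j beta_g + gamma_ig + delta_ig eps_gj

Batch locations ``gamma`` and scales ``delta**2`` are estimated per batch,
then shrunk toward pooled priors across features — normal for locations,
inverse gamma for scales, hyperparameters by the method of moments — via
the usual iterative conditional posterior means.  The diagnosis term in the
design matrix X is a protected covariate: its contribution is restored when
the adjustment is applied, while batch terms are removed.

With a single feature the across-feature prior moments are undefined, so
fitting falls back to exact (non-EB) location/scale adjustment with a
warning; the same applies when the scale moments degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .datatypes import Cohort
from .errors import DegenerateDataError, ValidationError

COVARIATE_CHOICES = ("diagnosis", "age", "sex")


@dataclass
class BatchAssignment:
    """Record-to-batch mapping (batches are sites or scanners)."""

    labels: np.ndarray          # per-record batch label, cohort row order
    batch_definition: str       # "site" or "scanner"
    batches: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.batches = sorted(set(self.labels.tolist()))
        if len(self.batches) < 2:
            raise DegenerateDataError(
                f"harmonization needs >= 2 batches, found {self.batches}"
            )
        for b in self.batches:
            if (self.labels == b).sum() < 2:
                raise DegenerateDataError(f"batch '{b}' has fewer than 2 records")

    @classmethod
    def from_cohort(cls, cohort: Cohort, batch_definition: str = "scanner") -> "BatchAssignment":
        if batch_definition not in ("site", "scanner"):
            raise ValidationError(
                f"batch_definition must be 'site' or 'scanner', got '{batch_definition}'"
            )
        return cls(cohort.data[batch_definition].to_numpy(), batch_definition)


@dataclass
class DesignInfo:
    """Covariate design (without batch columns) plus diagnostics."""

    covariates: list[str]
    matrix: np.ndarray          # (n, p) covariate columns, no intercept
    column_names: list[str]
    rank: int                   # rank of [batch one-hot | covariates]
    confounded_batches: list[str]  # batches with a single diagnosis class


def _covariate_matrix(cohort: Cohort, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    df = cohort.data
    for c in covariates:
        if c == "diagnosis":
            cols.append((df["diagnosis"] == "PD").to_numpy(dtype=float))
            names.append("diagnosis[PD]")
        elif c == "age":
            cols.append(df["age"].to_numpy(dtype=float))
            names.append("age")
        elif c == "sex":
            cols.append((df["sex"] == "M").to_numpy(dtype=float))
            names.append("sex[M]")
        else:
            raise ValidationError(
                f"unknown covariate '{c}'; choose from {COVARIATE_CHOICES}"
            )
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def build_design(cohort: Cohort, batches: BatchAssignment,
                 covariates: list[str] | None = None) -> DesignInfo:
    """Assemble the covariate design and check it against the batch block.

    The model intercept is absorbed into the batch one-hot block (weighted
    mean parameterization), so covariates enter without an intercept.  A
    batch containing a single diagnosis class (fully confounded with the
    protected covariate) is reported with a warning: its batch location
    absorbs part of the disease signal, but estimation still proceeds
    because beta is pooled across all batches.
    """
    covariates = list(covariates) if covariates is not None else ["diagnosis"]
    X, names = _covariate_matrix(cohort, covariates)
    onehot = np.column_stack(
        [(batches.labels == b).astype(float) for b in batches.batches]
    )
    full = np.hstack([onehot, X])
    rank = int(np.linalg.matrix_rank(full))
    if rank < full.shape[1]:
        raise DegenerateDataError(
            f"rank-deficient design: batch block plus covariates {names} has "
            f"rank {rank} < {full.shape[1]} columns"
        )
    confounded = []
    if "diagnosis" in covariates:
        dx = cohort.data["diagnosis"].to_numpy()
        for b in batches.batches:
            if len(set(dx[batches.labels == b])) < 2:
                confounded.append(b)
        if confounded:
            warnings.warn(
                f"batch(es) {confounded} contain a single diagnosis class; the "
                "batch location partially absorbs the diagnosis effect there",
                stacklevel=2,
            )
    return DesignInfo(covariates=covariates, matrix=X, column_names=names,
                      rank=rank, confounded_batches=confounded)


@dataclass
class CombatModel:
    """Fitted harmonization parameters (arrays indexed [batch, feature])."""

    feature_names: list[str]
    batch_definition: str
    batches: list[str]
    covariates: list[str]
    n_per_batch: np.ndarray
    alpha: np.ndarray            # (G,) feature intercepts (weighted grand mean)
    beta: np.ndarray             # (p, G) covariate coefficients
    sigma: np.ndarray            # (G,) pooled residual SDs
    gamma_hat: np.ndarray        # (I, G) naive standardized batch locations
    delta_hat_sq: np.ndarray     # (I, G) naive standardized batch variances
    gamma_bar: np.ndarray        # (I,) normal prior means
    tau_sq: np.ndarray           # (I,) normal prior variances
    lambda_: np.ndarray          # (I,) inverse-gamma shape
    theta: np.ndarray            # (I,) inverse-gamma scale
    gamma_star: np.ndarray       # (I, G) shrunken locations
    delta_star_sq: np.ndarray    # (I, G) shrunken variances
    eb: bool
    iterations: int
    converged: bool


def _eb_iterate(z_batches: list[np.ndarray], gamma_hat: np.ndarray,
                delta_hat_sq: np.ndarray, gamma_bar: np.ndarray,
                tau_sq: np.ndarray, lambda_: np.ndarray, theta: np.ndarray,
                n_per_batch: np.ndarray, tol: float,
                max_iter: int) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterate the coupled posterior means for (gamma*, delta*^2)."""
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat_sq.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_old, d_old = gamma_star.copy(), delta_star.copy()
        for i, z in enumerate(z_batches):
            n_i = n_per_batch[i]
            gamma_star[i] = (
                (n_i * tau_sq[i] * gamma_hat[i] + delta_star[i] * gamma_bar[i])
                / (n_i * tau_sq[i] + delta_star[i])
            )
            ssq = ((z - gamma_star[i]) ** 2).sum(axis=0)
            delta_star[i] = (theta[i] + 0.5 * ssq) / (n_i / 2.0 + lambda_[i] - 1.0)
        change = max(
            np.max(np.abs(gamma_star - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(delta_star - d_old) / (np.abs(d_old) + 1e-12)),
        )
        if change < tol:
            converged = True
            break
    return gamma_star, delta_star, it, converged


def fit_combat(cohort: Cohort, batches: BatchAssignment, design: DesignInfo,
               options: RunConfig | None = None) -> CombatModel:
    """Fit the location/scale batch model with optional EB shrinkage.

    Steps: pooled least squares with the weighted zero-sum constraint on
    batch locations; pooled residual variance; standardization; per-batch
    naive estimates; moment hyperparameters; iterative posterior means.
    """
    options = options or RunConfig()
    Y = cohort.values()                     # (n, G)
    n, G = Y.shape
    I = len(batches.batches)
    onehot = np.column_stack(
        [(batches.labels == b).astype(float) for b in batches.batches]
    )
    n_i = onehot.sum(axis=0)
    X = design.matrix                       # (n, p)

    full = np.hstack([onehot, X])
    B, _, _, _ = np.linalg.lstsq(full, Y, rcond=None)
    batch_coefs = B[:I]                     # (I, G) per-batch intercepts
    beta = B[I:]                            # (p, G)
    w = n_i / n
    alpha = w @ batch_coefs                 # weighted grand mean per feature
    gamma_ls = batch_coefs - alpha          # satisfies sum_i w_i gamma_i = 0

    fitted = full @ B
    sigma_sq = ((Y - fitted) ** 2).mean(axis=0)
    if np.any(sigma_sq <= 0):
        raise DegenerateDataError("zero pooled residual variance; cannot standardize")
    sigma = np.sqrt(sigma_sq)

    stand_mean = alpha + X @ beta           # (n, G), batch-free expectation
    Z = (Y - stand_mean) / sigma

    # delta uses the same 1/n convention as the pooled sigma, which makes the
    # non-EB adjustment exactly idempotent and an affine-constructed batch
    # effect removable to machine precision
    z_batches = [Z[batches.labels == b] for b in batches.batches]
    gamma_hat = np.vstack([z.mean(axis=0) for z in z_batches])
    delta_hat_sq = np.vstack([z.var(axis=0, ddof=0) for z in z_batches])
    if np.any(delta_hat_sq <= 0):
        raise DegenerateDataError("a batch has zero within-batch variance")

    eb = bool(options.eb)
    fallback_reason = None
    if eb and G < options.min_features_for_eb:
        fallback_reason = (
            f"EB needs >= {options.min_features_for_eb} features to estimate "
            f"across-feature priors; data has {G}"
        )
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1) if G > 1 else np.zeros(I)
    m_i = delta_hat_sq.mean(axis=1)
    s_sq = delta_hat_sq.var(axis=1, ddof=1) if G > 1 else np.zeros(I)
    if eb and fallback_reason is None and np.any(s_sq <= 0):
        fallback_reason = (
            "degenerate inverse-gamma moments (zero across-feature variance of "
            "batch scales)"
        )

    if eb and fallback_reason is not None:
        if options.strict:
            raise DegenerateDataError(fallback_reason)
        warnings.warn(
            f"{fallback_reason}; falling back to exact location/scale adjustment",
            stacklevel=2,
        )
        eb = False

    if eb:
        with np.errstate(divide="ignore", invalid="ignore"):
            lambda_ = (m_i ** 2 + 2.0 * s_sq) / s_sq
            theta = (m_i ** 3 + m_i * s_sq) / s_sq
        gamma_star, delta_star_sq, iterations, converged = _eb_iterate(
            z_batches, gamma_hat, delta_hat_sq, gamma_bar, tau_sq,
            lambda_, theta, n_i, options.tol, options.max_iter,
        )
    else:
        lambda_ = np.full(I, np.nan)
        theta = np.full(I, np.nan)
        gamma_star, delta_star_sq = gamma_hat.copy(), delta_hat_sq.copy()
        iterations, converged = 0, True

    return CombatModel(
        feature_names=cohort.feature_names,
        batch_definition=batches.batch_definition,
        batches=list(batches.batches),
        covariates=list(design.covariates),
        n_per_batch=n_i,
        alpha=alpha, beta=beta, sigma=sigma,
        gamma_hat=gamma_hat, delta_hat_sq=delta_hat_sq,
        gamma_bar=gamma_bar, tau_sq=tau_sq, lambda_=lambda_, theta=theta,
        gamma_star=gamma_star, delta_star_sq=delta_star_sq,
        eb=eb, iterations=iterations, converged=converged,
    )


def apply_combat(cohort: Cohort, model: CombatModel) -> Cohort:
    """Remove the (shrunken) batch location/scale effects.

    Y* = sigma_g * (Z - gamma*_i) / delta*_i + alpha_g + X beta_g — the
    covariate contribution (diagnosis, optionally age/sex) is restored,
    batch terms are not.
    """
    if model.feature_names != cohort.feature_names:
        raise ValidationError(
            f"combat model features {model.feature_names} do not match cohort "
            f"features {cohort.feature_names}"
        )
    labels = cohort.data[model.batch_definition].to_numpy()
    unknown = sorted(set(labels) - set(model.batches))
    if unknown:
        raise ValidationError(
            f"record(s) from batch(es) {unknown} absent at fit time"
        )
    X, _ = _covariate_matrix(cohort, model.covariates)
    stand_mean = model.alpha + X @ model.beta
    Z = (cohort.values() - stand_mean) / model.sigma
    idx = np.array([model.batches.index(b) for b in labels])
    adj = (Z - model.gamma_star[idx]) / np.sqrt(model.delta_star_sq[idx])
    out = adj * model.sigma + stand_mean
    return cohort.with_values(
        out, stage="combat",
        note={"combat": {"batch": model.batch_definition, "eb": model.eb,
                         "covariates": model.covariates,
                         "iterations": model.iterations}},
    )


def harmonize(cohort: Cohort, config: RunConfig,
              covariates: list[str] | None = None) -> tuple[Cohort, CombatModel]:
    """Convenience wrapper: assignment + design + fit + apply."""
    batches = BatchAssignment.from_cohort(cohort, config.batch_definition)
    design = build_design(cohort, batches, covariates)
    model = fit_combat(cohort, batches, design, config)
    return apply_combat(cohort, model), model
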