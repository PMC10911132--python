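"""Run configuration and synthetic-cohort parameters.

The default :class:`SynthConfig` encodes a four-site DAT-SPECT cohort
(72 healthy controls / 81 Parkinson's disease patients over sites NCNP,
KPUM, KU and FMU, with five scanners) whose pooled original-stage group
summaries land near 6.13 +/- 1.54 (HC) and 2.03 +/- 1.41 (PD).  Site effects
are decomposed the way a prospective phantom calibration sees them: an
affine per-scanner response (gain, offset) plus an additive per-site
procedure bias from local VOI placement conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import SchemaError


@dataclass(frozen=True)
class ScannerParams:
    """Affine response of one scanner relative to the reference scanner."""

    site: str
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise SchemaError(f"scanner gain must be > 0, got {self.gain}")


@dataclass(frozen=True)
class SiteParams:
    """Per-site sample composition and acquisition conventions.

    Age distributions are normal truncated at the 50-year inclusion floor.
    ``male_hc`` / ``male_pd`` are exact male counts (the remainder female).
    ``pd_shift`` is an additive shift of the PD latent mean expressing
    between-site differences in disease severity of the recruited patients.
    """

    n_hc: int
    n_pd: int
    age_hc: tuple[float, float] | None  # (mean, sd); None when n_hc == 0
    age_pd: tuple[float, float] | None
    male_hc: int
    male_pd: int
    procedure_bias: float = 0.0
    pd_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_pd < 0:
            raise SchemaError("site counts must be >= 0")
        if not (0 <= self.male_hc <= self.n_hc and 0 <= self.male_pd <= self.n_pd):
            raise SchemaError("male counts must lie within the group counts")
        if self.n_hc > 0 and self.age_hc is None:
            raise SchemaError("age_hc required when n_hc > 0")
        if self.n_pd > 0 and self.age_pd is None:
            raise SchemaError("age_pd required when n_pd > 0")


@dataclass
class SynthConfig:
    """Parameters of the synthetic multisite cohort generator.

    Latent model, per participant j at site k on scanner s, feature g:

        latent_gj = mu_dx + pd_shift_k·1[dx=PD] + beta_age·(age_j − ref_age)
                    + beta_sex·1[sex=M] + u_gj,   u_j ~ N(0, sigma_dx²·R(rho))
        observed_gj = gain_s·latent_gj + offset_s + bias_k + eps_gj

    where R(rho) is an equicorrelation matrix across the G features and eps
    is iid measurement noise.  All SBR units are unitless binding ratios.
    """

    # latent group means/SDs on the reference-scanner scale at the
    # female, age-`ref_age` baseline
    mu_hc: float = 7.05
    mu_pd: float = 3.50
    sigma_hc: float = 1.00
    sigma_pd: float = 0.60
    beta_age: float = -0.04     # SBR per year; binding declines with age
    beta_sex: float = -0.15     # additive offset for males
    ref_age: float = 65.0
    sigma_eps: float = 0.12     # measurement noise SD per feature
    sigma_phantom: float = 0.04  # phantom measurement noise SD
    n_features: int = 2          # left/right striatal SBR
    rho: float = 0.9             # inter-feature correlation
    floor: float = 0.05          # observed values floored here (ratios are positive)
    phantom_ratios: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    phantom_replicates: int = 3

    sites: dict[str, SiteParams] = field(default_factory=lambda: dict(DEFAULT_SITES))
    scanners: dict[str, ScannerParams] = field(default_factory=lambda: dict(DEFAULT_SCANNERS))

    def __post_init__(self) -> None:
        for nm, v in (("sigma_hc", self.sigma_hc), ("sigma_pd", self.sigma_pd),
                      ("sigma_eps", self.sigma_eps), ("sigma_phantom", self.sigma_phantom)):
            if v < 0 or (nm in ("sigma_hc", "sigma_pd") and v == 0):
                raise SchemaError(f"{nm} must be positive, got {v}")
        if not 0 <= self.rho < 1:
            raise SchemaError(f"rho must be in [0, 1), got {self.rho}")
        if self.n_features < 1:
            raise SchemaError("n_features must be >= 1")
        for name, sc in self.scanners.items():
            if sc.site not in self.sites:
                raise SchemaError(f"scanner '{name}' references unknown site '{sc.site}'")
        for site in self.sites:
            if not any(sc.site == site for sc in self.scanners.values()):
                raise SchemaError(f"site '{site}' has no scanner")

    @property
    def n_hc(self) -> int:
        return sum(s.n_hc for s in self.sites.values())

    @property
    def n_pd(self) -> int:
        return sum(s.n_pd for s in self.sites.values())


# Four-site composition: counts, age means (SD) and sex split per group.
DEFAULT_SITES: dict[str, SiteParams] = {
    "NCNP": SiteParams(n_hc=45, n_pd=16, age_hc=(67.4, 8.23), age_pd=(72.3, 7.94),
                       male_hc=25, male_pd=13, procedure_bias=0.0, pd_shift=0.30),
    "KPUM": SiteParams(n_hc=6, n_pd=5, age_hc=(68.3, 8.38), age_pd=(76.4, 6.06),
                       male_hc=3, male_pd=1, procedure_bias=0.05, pd_shift=0.35),
    "KU": SiteParams(n_hc=21, n_pd=48, age_hc=(68.6, 9.38), age_pd=(66.5, 8.64),
                     male_hc=14, male_pd=20, procedure_bias=-0.85, pd_shift=-0.38),
    "FMU": SiteParams(n_hc=0, n_pd=12, age_hc=None, age_pd=(66.5, 5.43),
                      male_hc=0, male_pd=7, procedure_bias=0.05, pd_shift=0.25),
}

# Five scanners over the four sites; NCNP hosts two and its first scanner is
# the calibration reference (gain 1, offset 0 by construction).
DEFAULT_SCANNERS: dict[str, ScannerParams] = {
    "NCNP_A": ScannerParams(site="NCNP", gain=1.00, offset=0.00),
    "NCNP_B": ScannerParams(site="NCNP", gain=1.05, offset=-0.10),
    "KPUM_A": ScannerParams(site="KPUM", gain=0.95, offset=0.30),
    "KU_A": ScannerParams(site="KU", gain=0.83, offset=-0.50),
    "FMU_A": ScannerParams(site="FMU", gain=0.92, offset=0.10),
}


@dataclass
class RunConfig:
    """Pipeline-wide options."""

    reference_scanner: str = "NCNP_A"
    batch_definition: str = "scanner"  # "scanner" or "site"
    eb: bool = True
    min_features_for_eb: int = 2
    max_iter: int = 100
    tol: float = 1e-4
    roc_low_positive: bool = True  # low SBR predicts PD
    strict: bool = False
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise SchemaError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise SchemaError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.batch_definition not in ("scanner", "site"):
            raise SchemaError(
                f"batch_definition must be 'scanner' or 'site', got '{self.batch_definition}'"
            )


# -- YAML (de)serialization -------------------------------------------------

def config_to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def _site_from_dict(d: dict) -> SiteParams:
    d = dict(d)
    for key in ("age_hc", "age_pd"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SiteParams(**d)


def synth_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "sites" in d:
        d["sites"] = {k: _site_from_dict(v) if isinstance(v, dict) else v
                      for k, v in d["sites"].items()}
    if "scanners" in d:
        d["scanners"] = {k: ScannerParams(**v) if isinstance(v, dict) else v
                         for k, v in d["scanners"].items()}
    if "phantom_ratios" in d:
        d["phantom_ratios"] = tuple(d["phantom_ratios"])
    return SynthConfig(**d)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if "synth" in d and isinstance(d["synth"], dict):
        d["synth"] = synth_from_dict(d["synth"])
    unknown = set(d) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; absent keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a YAML mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
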