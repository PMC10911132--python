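"""Core domain containers.

A :class:`Cohort` is a thin, validated wrapper around a pandas DataFrame with
one row per participant and one column per SBR feature (``sbr_<name>``).  All
correction stages return new cohorts tagged with the stage they produced,
so provenance of a table is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Allowed correction stages, in canonical pipeline order.
STAGES = (
    "original",
    "age_sex_corrected",
    "scanner_corrected",
    "prospective",
    "combat",
)

REQUIRED_COLUMNS = ("id", "site", "scanner", "diagnosis", "age", "sex")

SBR_PREFIX = "sbr_"

#: Study inclusion criterion: participants are older adults.
MIN_AGE = 50.0


@dataclass(frozen=True)
class ParticipantRecord:
    """A single participant's row, as an immutable record."""

    id: str
    site: str
    scanner: str
    diagnosis: str  # "HC" or "PD"
    age: float
    sex: str  # "M" or "F"
    sbr: dict[str, float]
    stage: str = "original"


@dataclass(frozen=True)
class PhantomScan:
    """One phantom measurement on one scanner.

    ``true_ratio`` is the known striatal-to-background activity ratio of the
    physical phantom fill; ``measured_sbr`` is what the scanner reported.
    """

    scanner: str
    true_ratio: float
    measured_sbr: float

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValidationError(f"phantom true_ratio must be > 0, got {self.true_ratio}")
        if self.measured_sbr <= 0:
            raise ValidationError(f"phantom measured_sbr must be > 0, got {self.measured_sbr}")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """SBR feature columns of a participant table, in column order."""
    return [c for c in df.columns if c.startswith(SBR_PREFIX)]


@dataclass
class Cohort:
    """A validated multisite participant table at a single correction stage.

    Parameters
    ----------
    data
        DataFrame with columns ``id, site, scanner, diagnosis, age, sex`` and
        one or more ``sbr_*`` feature columns.  Row order is meaningful and
        preserved by every operation.
    stage
        One of :data:`STAGES`.
    provenance
        Mapping of applied operations to the parameters they used.
    """

    data: pd.DataFrame
    stage: str = "original"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return [c[len(SBR_PREFIX):] for c in feature_columns(self.data)]

    @property
    def n_features(self) -> int:
        return len(feature_columns(self.data))

    @property
    def ids(self) -> pd.Series:
        return self.data["id"]

    def __len__(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        """The (n_records, n_features) SBR matrix."""
        return self.data[feature_columns(self.data)].to_numpy(dtype=float)

    def scores(self) -> np.ndarray:
        """Per-record mean over SBR features — the scalar used for diagnosis."""
        return self.values().mean(axis=1)

    def labels(self) -> np.ndarray:
        return self.data["diagnosis"].to_numpy()

    def records(self) -> Iterator[ParticipantRecord]:
        feats = feature_columns(self.data)
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield ParticipantRecord(
                id=d["id"], site=d["site"], scanner=d["scanner"],
                diagnosis=d["diagnosis"], age=d["age"], sex=d["sex"],
                sbr={c[len(SBR_PREFIX):]: d[c] for c in feats},
                stage=self.stage,
            )

    # -- derived cohorts ---------------------------------------------------

    def with_values(self, matrix: np.ndarray, stage: str, note: dict | None = None) -> "Cohort":
        """Return a new cohort with the SBR matrix replaced and stage re-tagged."""
        matrix = np.asarray(matrix, dtype=float)
        feats = feature_columns(self.data)
        if matrix.shape != (len(self.data), len(feats)):
            raise ValidationError(
                f"replacement SBR matrix has shape {matrix.shape}, "
                f"expected {(len(self.data), len(feats))}"
            )
        df = self.data.copy()
        df[feats] = matrix
        prov = dict(self.provenance)
        if note:
            prov.update(note)
        return Cohort(df, stage=stage, provenance=prov)

    def subset(self, mask: np.ndarray) -> "Cohort":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True),
                       provenance=dict(self.provenance))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"participant table is missing required column '{col}'")
        feats = feature_columns(df)
        if not feats:
            raise SchemaError("participant table has no 'sbr_*' feature column")
        if self.stage not in STAGES:
            raise SchemaError(f"unknown stage '{self.stage}'; expected one of {STAGES}")

        if df["id"].duplicated().any():
            dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
            raise ValidationError(f"duplicate participant ids: {dupes}")

        bad_dx = sorted(set(df["diagnosis"]) - {"HC", "PD"})
        if bad_dx:
            raise SchemaError(f"diagnosis must be HC or PD, found {bad_dx}")
        bad_sex = sorted(set(df["sex"]) - {"M", "F"})
        if bad_sex:
            raise SchemaError(f"sex must be M or F, found {bad_sex}")

        required_numeric = ["age", *feats]
        if df[required_numeric].isna().any().any():
            cols = [c for c in required_numeric if df[c].isna().any()]
            raise ValidationError(f"missing values in required columns {cols}")

        if (df["age"] < MIN_AGE).any():
            ids = df.loc[df["age"] < MIN_AGE, "id"].tolist()
            raise ValidationError(
                f"ages below the inclusion minimum of {MIN_AGE:g} years for ids {ids}"
            )

        # a scanner may not straddle sites
        sites_per_scanner = df.groupby("scanner")["site"].nunique()
        straddling = sites_per_scanner[sites_per_scanner > 1].index.tolist()
        if straddling:
            raise ValidationError(f"scanner(s) assigned to more than one site: {straddling}")

        if self.stage == "original":
            vals = df[feats].to_numpy(dtype=float)
            nonpos = (vals <= 0).any(axis=1)
            if nonpos.any():
                ids = df.loc[nonpos, "id"].tolist()
                raise ValidationError(f"non-positive SBR at stage 'original' for ids {ids}")

    def equals(self, other: "Cohort") -> bool:
        """Field-by-field equality of stage and table contents (provenance ignored)."""
        if self.stage != other.stage:
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_exact=False, rtol=0, atol=0)
        except AssertionError:
            return False
        return True


def phantom_frame(scans: list[PhantomScan]) -> pd.DataFrame:
    """Tabulate phantom scans as a DataFrame (scanner, true_ratio, measured_sbr)."""
    return pd.DataFrame(
        {
            "scanner": [s.scanner for s in scans],
            "true_ratio": [s.true_ratio for s in scans],
            "measured_sbr": [s.measured_sbr for s in scans],
        }
    )


def phantom_records(df: pd.DataFrame) -> list[PhantomScan]:
    for col in ("scanner", "true_ratio", "measured_sbr"):
        if col not in df.columns:
            raise SchemaError(f"phantom table is missing required column '{col}'")
    return [
        PhantomScan(str(r.scanner), float(r.true_ratio), float(r.measured_sbr))
        for r in df.itertuples(index=False)
    ]
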