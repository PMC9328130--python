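"""Observation schema, CSV ingestion, inclusion filters and result export.

The unit of analysis is one paired comparison between a cover-cropped (CC)
plot and its no-cover-crop (NCC) control: the two treatment means (nitrate
leaching in kg N ha⁻¹, or water drainage in mm), the replicate counts behind
each mean, and the categorical moderators / numeric covariates describing
the trial. Tables arrive as flat CSV files, one row per comparison, and are
validated on ingestion:

* rows whose means are non-positive are dropped (the log ratio is undefined)
  and recorded in a :class:`ValidationReport`;
* blank replicate counts are imputed as 1, the convention for studies that
  report an overall mean without replication information;
* blank moderator cells are retained as missing — such rows stay in the
  overall analysis and are excluded only from that moderator's subgroup
  analysis.

Moderator levels enter a subgroup analysis only when supported by at least
``min_articles`` distinct source articles (default 3) and at least
``min_levels`` levels survive (default 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, PreconditionError, SchemaError

logger = logging.getLogger(__name__)


class Response(str, Enum):
    """The two response variables measured in the paired comparisons."""

    NITRATE_LEACHING = "nitrate_leaching"
    WATER_DRAINAGE = "water_drainage"


class Tillage(str, Enum):
    CT = "CT"  # conventional tillage
    RT = "RT"  # reduced tillage
    NT = "NT"  # no-tillage


#: Exact column inventory of the observation CSV, in canonical order.
SCHEMA_COLUMNS: tuple[str, ...] = (
    "article_id",
    "obs_id",
    "response",
    "mean_cc",
    "mean_ncc",
    "n_cc",
    "n_ncc",
    "cc_family",
    "cc_genus",
    "soil_order",
    "soil_texture",
    "main_crop",
    "tillage",
    "rainfall_mm",
    "temp_c",
)

#: Categorical moderators eligible for subgroup analysis.
MODERATORS: tuple[str, ...] = (
    "cc_family",
    "cc_genus",
    "soil_order",
    "soil_texture",
    "main_crop",
    "tillage",
)

#: Numeric covariates eligible for meta-regression.
COVARIATES: tuple[str, ...] = ("rainfall_mm", "temp_c")


@dataclass(frozen=True)
class Observation:
    """One paired CC/NCC comparison with its moderators and covariates."""

    article_id: str
    obs_id: str
    response: Response
    mean_cc: float
    mean_ncc: float
    n_cc: int = 1
    n_ncc: int = 1
    cc_family: str | None = None
    cc_genus: str | None = None
    soil_order: str | None = None
    soil_texture: str | None = None
    main_crop: str | None = None
    tillage: str | None = None
    rainfall_mm: float | None = None
    temp_c: float | None = None

    def __post_init__(self) -> None:
        if not (self.mean_cc > 0 and self.mean_ncc > 0):
            raise DomainError(
                f"observation {self.obs_id!r}: means must be strictly positive "
                f"(got mean_cc={self.mean_cc}, mean_ncc={self.mean_ncc})"
            )
        for name in ("n_cc", "n_ncc"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise DomainError(
                    f"observation {self.obs_id!r}: {name} must be an integer >= 1, got {n!r}"
                )
        Response(self.response)
        if self.tillage is not None:
            Tillage(self.tillage)
        if self.rainfall_mm is not None and self.rainfall_mm < 0:
            raise DomainError(
                f"observation {self.obs_id!r}: rainfall_mm must be non-negative"
            )


@dataclass
class ValidationReport:
    """Bookkeeping from ingestion: accepted/rejected counts and reasons."""

    accepted: int = 0
    rejected: int = 0
    imputed_n: int = 0
    reasons: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.accepted + self.rejected


@dataclass
class ObservationSet:
    """An ordered collection of validated observations for one response.

    ``data`` is a DataFrame with the canonical schema columns; moderator
    cells that are missing hold ``NaN``. Row order is the input order.
    """

    data: pd.DataFrame
    provenance: str = ""
    validation: ValidationReport | None = None

    def __post_init__(self) -> None:
        ids = self.data["obs_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise SchemaError(f"duplicate obs_id values: {dupes[:5]}")
        responses = self.data["response"].unique()
        if len(responses) > 1:
            raise SchemaError(f"mixed response values in one set: {list(responses)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def response(self) -> Response | None:
        if len(self.data) == 0:
            return None
        return Response(self.data["response"].iloc[0])

    @classmethod
    def from_observations(
        cls, observations: Iterable[Observation], provenance: str = ""
    ) -> "ObservationSet":
        rows = []
        for o in observations:
            d = {c: getattr(o, c) for c in SCHEMA_COLUMNS}
            d["response"] = Response(o.response).value
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        return cls(data=df, provenance=provenance)

    def to_csv(self, path: str | Path) -> None:
        """Write the set back out in the canonical CSV schema."""
        out = self.data.copy()
        out.to_csv(path, index=False)


def _parse_count(value, obs_id: str, name: str) -> tuple[int, bool]:
    """Parse a replicate count cell; blank imputes 1. Returns (count, imputed)."""
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        logger.warning("observation %r: blank %s imputed as 1", obs_id, name)
        return 1, True
    x = float(value)
    if not x.is_integer():
        raise DomainError(f"{name} must be an integer, got {value!r}")
    n = int(x)
    if n < 1:
        raise DomainError(f"{name} must be >= 1, got {n}")
    return n, False


def read_observations(
    path: str | Path,
    response: Response | str,
    provenance: str | None = None,
) -> ObservationSet:
    """Read and validate an observation CSV, keeping rows for one response.

    Rules applied per row:

    * blank ``n_cc``/``n_ncc`` cells are imputed as 1 (warned, counted);
    * non-positive or non-numeric means reject the row (recorded in the
      report) rather than aborting the whole file;
    * blank moderator cells become missing values — the row is retained;
    * blank covariates become ``NaN`` — the row is excluded only from
      meta-regression on that covariate.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    OSError
        If the file cannot be read.
    """
    response = Response(response)
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ValidationReport()
    kept: list[dict] = []
    seen_ids: set[str] = set()
    for _, row in raw.iterrows():
        obs_id = row["obs_id"].strip()
        if row["response"].strip() != response.value:
            if row["response"].strip() not in {r.value for r in Response}:
                report.rejected += 1
                report.reasons.append((obs_id, "unknown response value"))
            continue  # silently skip the other response
        try:
            if obs_id in seen_ids:
                raise DomainError("duplicate obs_id")
            mean_cc = float(row["mean_cc"])
            mean_ncc = float(row["mean_ncc"])
            if not (mean_cc > 0 and mean_ncc > 0):
                raise DomainError("non-positive mean")
            n_cc, imp1 = _parse_count(row["n_cc"], obs_id, "n_cc")
            n_ncc, imp2 = _parse_count(row["n_ncc"], obs_id, "n_ncc")
            tillage = row["tillage"].strip() or None
            if tillage is not None and tillage not in {t.value for t in Tillage}:
                raise DomainError(f"unknown tillage value {tillage!r}")
            rainfall = row["rainfall_mm"].strip()
            rainfall_mm = float(rainfall) if rainfall else np.nan
            if rainfall and rainfall_mm < 0:
                raise DomainError("negative rainfall")
            temp = row["temp_c"].strip()
            temp_c = float(temp) if temp else np.nan
        except (DomainError, ValueError) as exc:
            report.rejected += 1
            report.reasons.append((obs_id, str(exc)))
            continue
        if imp1 or imp2:
            report.imputed_n += 1
        seen_ids.add(obs_id)
        report.accepted += 1
        kept.append(
            {
                "article_id": row["article_id"].strip() or np.nan,
                "obs_id": obs_id,
                "response": response.value,
                "mean_cc": mean_cc,
                "mean_ncc": mean_ncc,
                "n_cc": n_cc,
                "n_ncc": n_ncc,
                "cc_family": row["cc_family"].strip() or np.nan,
                "cc_genus": row["cc_genus"].strip() or np.nan,
                "soil_order": row["soil_order"].strip() or np.nan,
                "soil_texture": row["soil_texture"].strip() or np.nan,
                "main_crop": row["main_crop"].strip() or np.nan,
                "tillage": tillage if tillage is not None else np.nan,
                "rainfall_mm": rainfall_mm,
                "temp_c": temp_c,
            }
        )

    df = pd.DataFrame(kept, columns=list(SCHEMA_COLUMNS))
    return ObservationSet(
        data=df,
        provenance=provenance or str(path),
        validation=report,
    )


def filter_moderator_levels(
    obs_set: ObservationSet,
    moderator: str,
    min_articles: int = 3,
    min_levels: int = 2,
) -> ObservationSet:
    """Apply the moderator inclusion rule.

    Drops rows whose moderator value is missing and rows whose level is
    supported by fewer than ``min_articles`` distinct articles; when the
    article identifier is entirely missing the rule degrades to counting
    observations instead (with a warning). Idempotent.

    Raises
    ------
    PreconditionError
        If fewer than ``min_levels`` levels survive.
    SchemaError
        If ``moderator`` is not a schema moderator field.
    """
    if moderator not in MODERATORS:
        raise SchemaError(f"{moderator!r} is not a moderator field; choose from {MODERATORS}")
    df = obs_set.data
    present = df[df[moderator].notna()]
    if present["article_id"].notna().any():
        support = present.groupby(moderator, observed=True)["article_id"].nunique()
    else:
        logger.warning(
            "article_id entirely missing: level support counted in observations, not articles"
        )
        support = present.groupby(moderator, observed=True)["obs_id"].nunique()
    keep_levels = support[support >= min_articles].index
    out = present[present[moderator].isin(keep_levels)]
    if out[moderator].nunique() < min_levels:
        raise PreconditionError(
            f"moderator {moderator!r}: only {out[moderator].nunique()} level(s) have "
            f">= {min_articles} supporting articles; need >= {min_levels}"
        )
    return ObservationSet(
        data=out.reset_index(drop=True),
        provenance=f"{obs_set.provenance} | filtered {moderator} "
        f"(min_articles={min_articles})",
        validation=obs_set.validation,
    )


def write_results_table(
    rows: pd.DataFrame | Sequence[Mapping],
    path: str | Path,
) -> None:
    """Write a homogeneous result table as CSV, deterministically.

    Column order follows the input; floats are rendered with 6 significant
    digits so re-runs on identical inputs produce byte-identical files.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        raise DomainError("refusing to write an empty results table")
    rows.to_csv(path, index=False, float_format="%.6g")
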