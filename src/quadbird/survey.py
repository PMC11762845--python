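"""Domain types and I/O for quadrat land-cover tables and bird survey matrices.

A *quadrat* is a fixed-area square sampling unit (default 500 m x 500 m =
25 ha).  Each quadrat carries the extent, in hectares, of eight land-cover
categories, which must sum to the quadrat area.  A *survey session* is a
species x quadrat matrix of breeding-pair counts; presence/absence is
obtained by thresholding at one pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical order of the eight land-cover categories (hectares per quadrat).
LANDCOVER_CATEGORIES: tuple[str, ...] = (
    "arable_land",
    "continuous_urban_fabric",
    "discontinuous_urban_fabric",
    "green_urban_areas",
    "inland_waters",
    "ligneous_crops",
    "road_networks",
    "urban_woodlands",
)

N_LANDCOVER = len(LANDCOVER_CATEGORIES)

#: Default quadrat area in hectares (a 500 m x 500 m square).
DEFAULT_QUADRAT_AREA = 25.0

#: Tolerance, in hectares, for the per-quadrat area-sum invariant.
AREA_TOLERANCE = 1e-6


class Zone(str, Enum):
    """Urbanization zone of a quadrat."""

    URBAN = "urban"
    PERI_URBAN = "peri_urban"
    EXTRA_URBAN = "extra_urban"


class SurveyFormatError(ValueError):
    """Malformed input table (missing column, bad header, duplicate id)."""


class SurveyValidationError(ValueError):
    """Well-formed table whose values violate a domain invariant."""


@dataclass(frozen=True)
class QuadratRecord:
    """One sampling square: id, zone, and its 8-component land-cover vector."""

    quadrat_id: str
    zone: Zone
    landcover: np.ndarray  # shape (8,), hectares, canonical category order
    quadrat_area: float = DEFAULT_QUADRAT_AREA

    def __post_init__(self) -> None:
        lc = np.asarray(self.landcover, dtype=float)
        if lc.shape != (N_LANDCOVER,):
            raise SurveyValidationError(
                f"quadrat {self.quadrat_id!r}: landcover must have "
                f"{N_LANDCOVER} components, got shape {lc.shape}"
            )
        if np.any(lc < 0):
            raise SurveyValidationError(
                f"quadrat {self.quadrat_id!r}: negative land-cover extent"
            )
        if abs(lc.sum() - self.quadrat_area) > AREA_TOLERANCE:
            raise SurveyValidationError(
                f"quadrat {self.quadrat_id!r}: land-cover extents sum to "
                f"{lc.sum():.6f} ha, expected {self.quadrat_area} ha"
            )
        object.__setattr__(self, "landcover", lc)
        object.__setattr__(self, "zone", Zone(self.zone))


@dataclass(frozen=True)
class SurveySession:
    """Species x quadrat breeding-pair counts for one sampling session."""

    session_label: int  # 1 or 2
    species_ids: tuple[str, ...]
    quadrat_ids: tuple[str, ...]
    abundance: np.ndarray  # shape (S, Q), nonnegative integers

    def __post_init__(self) -> None:
        species = tuple(self.species_ids)
        quadrats = tuple(self.quadrat_ids)
        if len(set(species)) != len(species):
            raise SurveyValidationError("duplicate species id in session")
        if len(set(quadrats)) != len(quadrats):
            raise SurveyValidationError("duplicate quadrat id in session")
        ab = np.asarray(self.abundance)
        if ab.shape != (len(species), len(quadrats)):
            raise SurveyValidationError(
                f"abundance shape {ab.shape} does not match "
                f"{len(species)} species x {len(quadrats)} quadrats"
            )
        if not np.issubdtype(ab.dtype, np.integer):
            if not np.allclose(ab, np.round(ab)):
                bad = np.argwhere(~np.isclose(ab, np.round(ab)))[0]
                raise SurveyValidationError(
                    f"non-integer abundance at species row {bad[0]}, "
                    f"quadrat column {bad[1]}"
                )
            ab = np.round(ab).astype(np.int64)
        if np.any(ab < 0):
            bad = np.argwhere(ab < 0)[0]
            raise SurveyValidationError(
                f"negative abundance at species row {bad[0]}, "
                f"quadrat column {bad[1]}"
            )
        object.__setattr__(self, "species_ids", species)
        object.__setattr__(self, "quadrat_ids", quadrats)
        object.__setattr__(self, "abundance", ab.astype(np.int64))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_quadrats(self) -> int:
        return len(self.quadrat_ids)


@dataclass(frozen=True)
class ResponseVector:
    """Per-quadrat responses: Y1 = richness (species), Y2 = breeding pairs.

    Both are the maximum over the sampling sessions, taken per quadrat.
    """

    quadrat_ids: tuple[str, ...]
    y1_richness: np.ndarray
    y2_abundance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "quadrat_ids", tuple(self.quadrat_ids))
        object.__setattr__(
            self, "y1_richness", np.asarray(self.y1_richness, dtype=np.int64)
        )
        object.__setattr__(
            self, "y2_abundance", np.asarray(self.y2_abundance, dtype=np.int64)
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def incidence(session: SurveySession | np.ndarray) -> np.ndarray:
    """Presence/absence matrix: 1 where at least one breeding pair was seen."""
    ab = session.abundance if isinstance(session, SurveySession) else session
    return (np.asarray(ab) >= 1).astype(np.int8)


def max_response(sessions: Sequence[SurveySession]) -> ResponseVector:
    """Per-quadrat maxima of richness (Y1) and total pairs (Y2) over sessions.

    Sessions must share the same quadrat ids (species lists may differ: a
    species absent from a session simply contributes zero there).
    """
    if len(sessions) == 0:
        raise SurveyValidationError("max_response needs at least one session")
    quadrat_ids = sessions[0].quadrat_ids
    for s in sessions[1:]:
        if s.quadrat_ids != quadrat_ids:
            raise SurveyValidationError(
                "sessions do not share the same quadrat ids"
            )
    richness = np.stack(
        [incidence(s).sum(axis=0) for s in sessions]
    )  # (n_sessions, Q)
    pairs = np.stack([s.abundance.sum(axis=0) for s in sessions])
    return ResponseVector(
        quadrat_ids=quadrat_ids,
        y1_richness=richness.max(axis=0),
        y2_abundance=pairs.max(axis=0),
    )


# ---------------------------------------------------------------------------
# Readers / writers (delimited text with a header row)
# ---------------------------------------------------------------------------


def read_landcover_table(
    path,
    quadrat_area: float = DEFAULT_QUADRAT_AREA,
    delimiter: str = ",",
) -> list[QuadratRecord]:
    """Read a land-cover table: quadrat_id, zone, then the 8 category columns."""
    df = pd.read_csv(path, sep=delimiter)
    required = ("quadrat_id", "zone") + LANDCOVER_CATEGORIES
    for col in required:
        if col not in df.columns:
            raise SurveyFormatError(f"missing column {col!r} in {path}")
    records = []
    for _, row in df.iterrows():
        records.append(
            QuadratRecord(
                quadrat_id=str(row["quadrat_id"]),
                zone=Zone(row["zone"]),
                landcover=np.array(
                    [float(row[c]) for c in LANDCOVER_CATEGORIES]
                ),
                quadrat_area=quadrat_area,
            )
        )
    return records


def write_landcover_table(records: Iterable[QuadratRecord], path, delimiter=","):
    records = list(records)
    df = pd.DataFrame(
        {
            "quadrat_id": [r.quadrat_id for r in records],
            "zone": [r.zone.value for r in records],
            **{
                c: [r.landcover[i] for r in records]
                for i, c in enumerate(LANDCOVER_CATEGORIES)
            },
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_survey(path, session_label: int = 1, delimiter: str = ",") -> SurveySession:
    """Read a survey matrix: first column species_id, one column per quadrat."""
    df = pd.read_csv(path, sep=delimiter)
    if df.columns[0] != "species_id":
        raise SurveyFormatError(
            f"first column must be 'species_id', got {df.columns[0]!r}"
        )
    species = [str(s) for s in df["species_id"]]
    quadrats = [str(q) for q in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy()
    return SurveySession(
        session_label=session_label,
        species_ids=tuple(species),
        quadrat_ids=tuple(quadrats),
        abundance=values,
    )


def write_survey(session: SurveySession, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        session.abundance,
        index=pd.Index(session.species_ids, name="species_id"),
        columns=list(session.quadrat_ids),
    )
    df.to_csv(path, sep=delimiter)


def landcover_matrix(records: Sequence[QuadratRecord]) -> np.ndarray:
    """Stack quadrat land-cover vectors into a Q x 8 matrix (record order)."""
    return np.stack([r.landcover for r in records])
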