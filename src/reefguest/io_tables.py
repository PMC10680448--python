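"""Reading, validation and summarisation of interaction tables.

The raw input is an edge list of sponge host / guest associations, one row
per literature record, carrying the ecoregion, coordinates and bibliographic
reference of each record.  This module validates those rows, keeps only
species-level host names, and collapses them into the binary hosts x guests
incidence matrix that every downstream stage consumes.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("reefguest")

#: Default mapping from logical field names to CSV column headers.
DEFAULT_SCHEMA: dict[str, str] = {
    "host_species": "host_species",
    "guest_species": "guest_species",
    "ecoregion": "ecoregion",
    "latitude": "latitude",
    "longitude": "longitude",
    "reference": "reference",
}

#: Coordinate precision (decimal places) defining a "location" when counting
#: unique sampling locations per ecoregion.
LOCATION_PRECISION = 3

# Species-level binomial: "Genus species", optionally with a parenthesised
# subgenus token, e.g. "Callyspongia (Cladochalina) aculeata".  Entries such
# as "Ircinia sp.", "Ircinia spp." or single-token names are not species level.
_BINOMIAL_RE = re.compile(
    r"^[A-Z][a-zA-Z\-]+(?:\s+\([A-Z][a-zA-Z\-]+\))?\s+[a-z][a-z\-]+$"
)
_OPEN_NOMENCLATURE_RE = re.compile(r"\bspp?\.?$")


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """One or more rows failed record-level validation."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


class EmptyInputError(ValueError):
    """An operation received no records to work with."""


@dataclass(frozen=True)
class InteractionRecord:
    """A single literature record of a host-guest association."""

    host_species: str
    guest_species: str
    ecoregion: str
    latitude: float
    longitude: float
    reference: str
    guest_phylum: str = ""


@dataclass
class IncidenceMatrix:
    """Binary hosts x guests matrix; the network's single source of truth.

    ``cells[i, j] == 1`` iff at least one record links host ``hosts[i]`` to
    guest ``guests[j]``.  Hosts and guests are stored in lexicographic order
    so that every downstream seeded algorithm sees a deterministic layout.
    """

    hosts: list[str]
    guests: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.hosts), len(self.guests)):
            raise ValueError("cell block shape does not match species lists")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def m(self) -> int:
        """Total number of links (1-cells)."""
        return int(self.cells.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def host_degrees(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def guest_degrees(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def host_index(self, host: str) -> int:
        try:
            return self.hosts.index(host)
        except ValueError:
            raise KeyError(f"unknown host species: {host!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.hosts, columns=self.guests)

    def to_edge_list(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.cells)
        return pd.DataFrame(
            {
                "host_species": [self.hosts[i] for i in rows],
                "guest_species": [self.guests[j] for j in cols],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="host_species")


@dataclass
class DatasetSummary:
    """Dataset-level counts, overall and stratified by ecoregion."""

    n_interactions: int
    n_hosts: int
    n_guests: int
    per_ecoregion: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            self.per_ecoregion,
            orient="index",
            columns=["interactions", "locations", "publications"],
        ).rename_axis("ecoregion")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_interactions": self.n_interactions,
            "n_hosts": self.n_hosts,
            "n_guests": self.n_guests,
            "per_ecoregion": {
                k: {"interactions": a, "locations": b, "publications": c}
                for k, (a, b, c) in self.per_ecoregion.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def is_species_level(name: str) -> bool:
    """Whether a host name is a species-level binomial.

    Accepts "Genus species" and "Genus (Subgenus) species"; rejects open
    nomenclature ("Genus sp.", "Genus spp.") and single-token names.
    """
    name = name.strip()
    if _OPEN_NOMENCLATURE_RE.search(name):
        return False
    return bool(_BINOMIAL_RE.match(name))


def read_interactions(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read an interaction edge list CSV into validated records.

    Rows failing validation are collected and reported together in a single
    :class:`ValidationError` listing the offending row numbers (0-based data
    rows); they are never silently dropped.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns and c]
    # guest_phylum is optional
    missing = [c for c in missing if c != colmap.get("guest_phylum", "guest_phylum")]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[InteractionRecord] = []
    bad_rows: list[int] = []
    problems: list[str] = []
    phylum_col = colmap.get("guest_phylum", "guest_phylum")
    for idx, row in df.iterrows():
        try:
            lat = float(row[colmap["latitude"]])
            lon = float(row[colmap["longitude"]])
        except (TypeError, ValueError):
            bad_rows.append(int(idx))
            problems.append(f"row {idx}: unparsable coordinates")
            continue
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            bad_rows.append(int(idx))
            problems.append(f"row {idx}: coordinates out of bounds ({lat}, {lon})")
            continue
        host = str(row[colmap["host_species"]]).strip()
        guest = str(row[colmap["guest_species"]]).strip()
        if not host or not guest:
            bad_rows.append(int(idx))
            problems.append(f"row {idx}: empty species name")
            continue
        records.append(
            InteractionRecord(
                host_species=host,
                guest_species=guest,
                ecoregion=str(row[colmap["ecoregion"]]).strip(),
                latitude=lat,
                longitude=lon,
                reference=str(row[colmap["reference"]]).strip(),
                guest_phylum=str(row.get(phylum_col, "")).strip(),
            )
        )
    if bad_rows:
        raise ValidationError(
            "invalid interaction rows: " + "; ".join(problems), rows=bad_rows
        )
    return records


def filter_species_level(
    records: Iterable[InteractionRecord],
) -> list[InteractionRecord]:
    """Keep only records whose host is identified to species level."""
    records = list(records)
    kept = [r for r in records if is_species_level(r.host_species)]
    removed = len(records) - len(kept)
    if removed:
        logger.info("species-level filter removed %d record(s)", removed)
    return kept


def build_incidence(records: Iterable[InteractionRecord]) -> IncidenceMatrix:
    """Collapse records into the binary incidence matrix.

    Duplicate (host, guest) pairs — the same association reported from
    several ecoregions or publications — collapse to a single 1-cell.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot build an incidence matrix from no records")
    pairs = {(r.host_species, r.guest_species) for r in records}
    hosts = sorted({h for h, _ in pairs})
    guests = sorted({g for _, g in pairs})
    hidx = {h: i for i, h in enumerate(hosts)}
    gidx = {g: j for j, g in enumerate(guests)}
    cells = np.zeros((len(hosts), len(guests)), dtype=np.int8)
    for h, g in pairs:
        cells[hidx[h], gidx[g]] = 1
    return IncidenceMatrix(hosts=hosts, guests=guests, cells=cells)


def summarize_dataset(
    records: Iterable[InteractionRecord],
    known_ecoregions: Sequence[str] | None = None,
    location_precision: int = LOCATION_PRECISION,
) -> DatasetSummary:
    """Overall and per-ecoregion counts of interactions, locations, publications.

    A "location" is a unique (lat, lon) pair rounded to ``location_precision``
    decimal places; a "publication" is a unique reference string.  A pair
    recorded in several ecoregions counts once per ecoregion, so per-ecoregion
    interaction counts may sum to more than the matrix fill.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot summarise an empty record list")
    pairs = {(r.host_species, r.guest_species) for r in records}
    per: dict[str, dict[str, set]] = {}
    for r in records:
        eco = r.ecoregion
        if known_ecoregions is not None and eco not in known_ecoregions:
            logger.warning("unknown ecoregion %r; bucketed under 'unclassified'", eco)
            eco = "unclassified"
        bucket = per.setdefault(
            eco, {"pairs": set(), "locations": set(), "refs": set()}
        )
        bucket["pairs"].add((r.host_species, r.guest_species))
        bucket["locations"].add(
            (round(r.latitude, location_precision), round(r.longitude, location_precision))
        )
        bucket["refs"].add(r.reference)
    return DatasetSummary(
        n_interactions=len(pairs),
        n_hosts=len({h for h, _ in pairs}),
        n_guests=len({g for _, g in pairs}),
        per_ecoregion={
            eco: (len(b["pairs"]), len(b["locations"]), len(b["refs"]))
            for eco, b in sorted(per.items())
        },
    )


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Round-trip helper: records back to the canonical CSV layout."""
    return pd.DataFrame([r.__dict__ for r in records])
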