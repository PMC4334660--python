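"""Core domain types, file formats and run reporting.

All downstream stages consume the types defined here (:class:`Alignment`,
:class:`LocalityTable`, :class:`StraitGraph`, :class:`Raster`) rather than
reading files themselves.  Conventions, stated once:

* coordinates are WGS84 decimal degrees everywhere;
* rasters use a lower-left corner origin (``x_origin``/``y_origin``) with
  row 0 being the *northernmost* row, matching the ESRI ASCII grid layout;
* CSV files are comma-separated UTF-8 with a mandatory header row;
* a strait distance that is not listed is "no direct crossing" and is stored
  as ``inf``, never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file did not conform to its expected on-disk format."""


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (e.g. unequal lengths)."""


class ConfigError(ValueError):
    """A run or strait configuration is inconsistent."""


#: Characters accepted in aligned nucleotide sequences.
IUPAC_AMBIGUITY = set("RYSWKMBDHV")
VALID_ALPHABET = set("ACGTN-") | IUPAC_AMBIGUITY
#: Unambiguous nucleotide states (everything else counts as missing).
UNAMBIGUOUS = set("ACGT")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of nucleotide sequences keyed by specimen id."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids: {dupes}")
        length = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != length:
                raise AlignmentError(
                    f"record {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise AlignmentError(
                    f"record {rid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment([(r, s) for r, s in self.records if r in keep])


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Ids are the first whitespace-delimited token of each header; sequences
    are upper-cased.  Raises :class:`AlignmentError` if lengths differ and
    :class:`FormatError` on an empty file.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Alignment(records)


def write_fasta(path: str | Path, aln: Alignment) -> None:
    recs = [SeqRecord(Seq(s), id=r, description="") for r, s in aln.records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Locality table
# ---------------------------------------------------------------------------

LOCALITY_COLUMNS = ["specimen_id", "species", "lat", "lon", "locality_name", "land_unit"]


@dataclass
class LocalityTable:
    """Specimen coordinates, species labels and (optional) land units."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in LOCALITY_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise FormatError(f"locality table missing columns: {missing}")
        if "land_unit" not in df.columns:
            df = df.assign(land_unit=pd.NA)
        df = df.copy()
        df["lat"] = df["lat"].astype(float)
        df["lon"] = df["lon"].astype(float)
        if df["specimen_id"].duplicated().any():
            dupes = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"])
            raise FormatError(f"duplicate specimen ids in locality table: {dupes}")
        if not df["lat"].between(-90, 90).all():
            raise FormatError("latitude out of [-90, 90]")
        if not df["lon"].between(-180, 180).all():
            raise FormatError("longitude out of [-180, 180]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def coords_for(self, specimen_id: str) -> tuple[float, float]:
        """Return (lat, lon) of a specimen."""
        row = self.df.loc[self.df["specimen_id"] == specimen_id]
        if row.empty:
            raise KeyError(specimen_id)
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])

    def unit_for(self, specimen_id: str) -> str | None:
        row = self.df.loc[self.df["specimen_id"] == specimen_id]
        if row.empty:
            raise KeyError(specimen_id)
        val = row["land_unit"].iloc[0]
        return None if pd.isna(val) else str(val)

    def subset(self, ids: Iterable[str]) -> "LocalityTable":
        keep = set(ids)
        return LocalityTable(self.df[self.df["specimen_id"].isin(keep)].copy())


def read_locality_csv(path: str | Path) -> LocalityTable:
    df = pd.read_csv(path)
    return LocalityTable(df)


def write_locality_csv(path: str | Path, loc: LocalityTable) -> None:
    loc.df.to_csv(path, index=False)


def read_occurrence_csv(path: str | Path) -> pd.DataFrame:
    """Read occurrence points: columns ``species, lon, lat``."""
    df = pd.read_csv(path)
    missing = [c for c in ("species", "lon", "lat") if c not in df.columns]
    if missing:
        raise FormatError(f"occurrence table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Strait graph
# ---------------------------------------------------------------------------

@dataclass
class StraitGraph:
    """Land units with pairwise sea-crossing distances at the -50 m isobath.

    ``distances[i, j]`` is km of open sea between units i and j; ``inf``
    means no direct strait is listed.  Merged pairs have distance 0.
    """

    units: list[str]
    merges: list[tuple[str, str]] = field(default_factory=list)
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.units)
        if len(set(self.units)) != n:
            raise ConfigError("duplicate land-unit names")
        if self.distances is None:
            self.distances = np.full((n, n), np.inf)
            np.fill_diagonal(self.distances, 0.0)
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (n, n):
            raise ConfigError("distance matrix shape does not match unit count")
        if not np.allclose(d, d.T, equal_nan=True):
            raise ConfigError("strait distance matrix is not symmetric")
        finite = d[np.isfinite(d)]
        if (finite < 0).any():
            raise ConfigError("negative strait distance")
        known = set(self.units)
        for a, b in self.merges:
            if a not in known or b not in known:
                raise ConfigError(f"merge references unknown unit: {(a, b)}")
        self.distances = d
        self._index = {u: i for i, u in enumerate(self.units)}
        # merged pairs cross no sea
        for a, b in self.merges:
            i, j = self._index[a], self._index[b]
            self.distances[i, j] = self.distances[j, i] = 0.0

    def index(self, unit: str) -> int:
        try:
            return self._index[unit]
        except KeyError:
            raise ConfigError(f"unknown land unit {unit!r}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.distances[self.index(a), self.index(b)])


def read_strait_config(path: str | Path) -> StraitGraph:
    """Read a strait configuration CSV.

    Rows have columns ``record_type,a,b,km``: ``unit`` rows declare a land
    unit (in ``a``), ``merge`` rows absorb unit ``a`` into ``b``, and
    ``distance`` rows give the sea-crossing width ``km`` between ``a`` and
    ``b``.  Distances are symmetrized; conflicting duplicate entries raise
    :class:`ConfigError`; unlisted pairs are "no direct strait" (infinite).
    """
    df = pd.read_csv(path, dtype={"record_type": str, "a": str, "b": str})
    missing = [c for c in ("record_type", "a", "b") if c not in df.columns]
    if missing:
        raise FormatError(f"strait config missing columns: {missing}")
    units = [r["a"] for _, r in df.iterrows() if r["record_type"] == "unit"]
    sg = StraitGraph(units=units)
    seen: dict[tuple[int, int], float] = {}
    merges: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        kind = row["record_type"]
        if kind == "unit":
            continue
        if kind == "merge":
            merges.append((row["a"], row["b"]))
            continue
        if kind == "distance":
            km = float(row["km"])
            if km < 0:
                raise ConfigError(f"negative strait distance: {row['a']}-{row['b']}")
            i, j = sg.index(row["a"]), sg.index(row["b"])
            key = (min(i, j), max(i, j))
            if key in seen and not math.isclose(seen[key], km):
                raise ConfigError(
                    f"conflicting distances for {row['a']}-{row['b']}: "
                    f"{seen[key]} vs {km}"
                )
            seen[key] = km
            sg.distances[i, j] = sg.distances[j, i] = km
            continue
        raise FormatError(f"unknown record_type {kind!r}")
    return StraitGraph(units=sg.units, merges=merges, distances=sg.distances)


def write_strait_config(path: str | Path, sg: StraitGraph) -> None:
    rows = [{"record_type": "unit", "a": u, "b": "", "km": ""} for u in sg.units]
    rows += [{"record_type": "merge", "a": a, "b": b, "km": ""} for a, b in sg.merges]
    merged_pairs = {frozenset(m) for m in sg.merges}
    for i, a in enumerate(sg.units):
        for j in range(i + 1, len(sg.units)):
            b = sg.units[j]
            d = sg.distances[i, j]
            if np.isfinite(d) and frozenset((a, b)) not in merged_pairs:
                rows.append({"record_type": "distance", "a": a, "b": b, "km": d})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A regular lon/lat grid in ESRI ASCII layout (row 0 = north)."""

    nrows: int
    ncols: int
    x_origin: float  # xllcorner
    y_origin: float  # yllcorner
    cell_size: float
    nodata: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        if self.values.shape != (self.nrows, self.ncols):
            raise FormatError(
                f"raster body is {self.values.shape}, header says "
                f"({self.nrows}, {self.ncols})"
            )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.nrows, self.ncols, self.x_origin, self.y_origin,
                      self.cell_size, self.nodata, np.asarray(values, dtype=float))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (nrows, ncols) for every cell center."""
        lon = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        lat = self.y_origin + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def cell_index(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """(row, col) of the cell containing a point; may fall outside grid."""
        col = np.floor((np.asarray(lon) - self.x_origin) / self.cell_size).astype(int)
        row = (self.nrows - 1
               - np.floor((np.asarray(lat) - self.y_origin) / self.cell_size).astype(int))
        return row, col

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    body: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for line in lines[i:]:
        body.extend(float(tok) for tok in line.split())
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(body) != nrows * ncols:
        raise FormatError(
            f"{path}: body has {len(body)} values, header implies {nrows * ncols}"
        )
    return Raster(
        nrows=nrows,
        ncols=ncols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
        values=np.array(body).reshape(nrows, ncols),
    )


def write_raster(path: str | Path, raster: Raster) -> None:
    """Write an ESRI ASCII grid; values printed with 6 decimal places."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x_origin:.6f}\n")
        fh.write(f"yllcorner {raster.y_origin:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:.6f}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

class RunReport:
    """Machine-parsable audit trail of a pipeline run.

    Every stage records its input counts, exclusions and selected
    parameters; results that hinge on exclusion decisions must be auditable
    from this report alone.
    """

    def __init__(self) -> None:
        self.stages: list[dict] = []

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **_jsonable(info)})

    def to_dict(self) -> dict:
        return {"stages": self.stages}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


# ---------------------------------------------------------------------------
# Geographic helpers
# ---------------------------------------------------------------------------

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.minimum(1.0, np.sqrt(a)))
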