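"""Reading and writing landmark configurations and specimen metadata.

Two landmark dialects are supported:

* **TPS** — ``LM3=k`` (or ``LM=k`` for 2D) blocks, one coordinate row per
  landmark in scheme order, terminated by an ``ID=<specimen>`` line.
  ``SCALE=`` lines are accepted and ignored (scale is removed by the
  superimposition anyway).
* **CSV** — a *long* layout ``specimen_id,landmark,x,y[,z]`` with one row per
  landmark, or a *wide* layout with one row per specimen and columns
  ``<name>_x, <name>_y[, <name>_z]``.

Metadata is a plain CSV keyed by ``specimen_id``.  Optional columns
(``island``, ``age_years``, ``generation``) may be absent or empty; they are
kept as missing, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scheme import LandmarkScheme

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "JoinedDataset",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
    "metadata_to_frame",
    "join_dataset",
    "packaged_population_table",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's named landmark coordinates (k x d, in file units)."""

    specimen_id: str
    coords: np.ndarray
    scheme: LandmarkScheme

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        k, d = self.coords.shape
        if k != len(self.scheme):
            raise ValueError(
                f"specimen {self.specimen_id!r}: {k} landmarks, scheme "
                f"expects {len(self.scheme)}"
            )
        if d != self.scheme.dimension:
            raise ValueError(
                f"specimen {self.specimen_id!r}: dimension {d} does not "
                f"match scheme dimension {self.scheme.dimension}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )


_REQUIRED_META = ("specimen_id", "sex", "age_class", "captivity", "population")
_OPTIONAL_META = (
    "latitude",
    "longitude",
    "temperature",
    "precipitation",
    "island",
    "age_years",
    "generation",
)


@dataclass
class SpecimenMetadata:
    """Covariates for one specimen.

    Codes follow the study design: ``sex`` 0 female / 1 male; ``age_class``
    0 young adult / 1 adult; ``captivity`` 0 wild / 1 founder / 2
    captive-born; ``island`` 0 non-island / 1 island (optional).
    """

    specimen_id: str
    sex: int
    age_class: int
    captivity: int
    population: str
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    temperature: Optional[float] = None
    precipitation: Optional[float] = None
    island: Optional[int] = None
    age_years: Optional[float] = None
    generation: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(
                f"specimen {self.specimen_id!r}: sex must be 0 or 1, got {self.sex}"
            )
        if self.age_class not in (0, 1):
            raise ValueError(
                f"specimen {self.specimen_id!r}: age_class must be 0 or 1, "
                f"got {self.age_class}"
            )
        if self.captivity not in (0, 1, 2):
            raise ValueError(
                f"specimen {self.specimen_id!r}: captivity must be 0, 1 or 2, "
                f"got {self.captivity}"
            )
        if self.island is not None and self.island not in (0, 1):
            raise ValueError(
                f"specimen {self.specimen_id!r}: island must be 0 or 1, "
                f"got {self.island}"
            )
        if not self.population:
            raise ValueError(f"specimen {self.specimen_id!r}: empty population")


# ---------------------------------------------------------------------------
# landmark files
# ---------------------------------------------------------------------------


def read_landmarks(
    path: str | Path, scheme: LandmarkScheme
) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or CSV file.

    Coordinates are remapped from file order to scheme order; missing or
    duplicate landmarks and specimen ids are errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".tps":
        configs = _read_tps(path, scheme)
    else:
        configs = _read_csv(path, scheme)
    ids = [c.specimen_id for c in configs]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate specimen ids: {sorted(dupes)}")
    return configs


def _read_tps(path: Path, scheme: LandmarkScheme) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    rows: list[list[float]] = []
    expected: int | None = None
    specimen: str | None = None

    def flush(line_no: int) -> None:
        nonlocal rows, expected, specimen
        if expected is None:
            return
        if specimen is None:
            raise ValueError(f"{path}: block before line {line_no} has no ID=")
        if len(rows) != expected:
            raise ValueError(
                f"{path}: specimen {specimen!r} has {len(rows)} coordinate "
                f"rows, LM declares {expected}"
            )
        if expected != len(scheme):
            raise ValueError(
                f"{path}: specimen {specimen!r} has {expected} landmarks, "
                f"scheme expects {len(scheme)}"
            )
        configs.append(
            LandmarkConfiguration(specimen, np.asarray(rows, dtype=float), scheme)
        )
        rows, expected, specimen = [], None, None

    with open(path, "r", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(i)
                expected = int(line.split("=", 1)[1])
                dim = 3 if upper.startswith("LM3=") else 2
                if dim != scheme.dimension:
                    raise ValueError(
                        f"{path}:{i}: {dim}D block, scheme is "
                        f"{scheme.dimension}D"
                    )
            elif upper.startswith("ID="):
                specimen = line.split("=", 1)[1].strip()
                flush(i)
            elif upper.startswith("SCALE="):
                continue  # units assumed mm
            else:
                vals = [float(v) for v in line.split()]
                if len(vals) != scheme.dimension:
                    raise ValueError(
                        f"{path}:{i}: expected {scheme.dimension} coordinates, "
                        f"got {len(vals)}"
                    )
                rows.append(vals)
    flush(-1)
    return configs


_AXES = ("x", "y", "z")


def _read_csv(path: Path, scheme: LandmarkScheme) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "landmark" in df.columns:
        return _read_csv_long(path, df, scheme)
    return _read_csv_wide(path, df, scheme)


def _read_csv_long(
    path: Path, df: pd.DataFrame, scheme: LandmarkScheme
) -> list[LandmarkConfiguration]:
    axes = _AXES[: scheme.dimension]
    missing_cols = [c for c in ("specimen_id", "landmark", *axes) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    configs = []
    for specimen, grp in df.groupby("specimen_id", sort=False):
        lm_index = {}
        for _, row in grp.iterrows():
            name = row["landmark"]
            if name not in scheme.names:
                raise ValueError(
                    f"{path}: specimen {specimen!r}: unknown landmark {name!r}"
                )
            if name in lm_index:
                raise ValueError(
                    f"{path}: specimen {specimen!r}: duplicate landmark {name!r}"
                )
            lm_index[name] = [float(row[a]) for a in axes]
        absent = [n for n in scheme.names if n not in lm_index]
        if absent:
            raise ValueError(
                f"{path}: specimen {specimen!r}: missing landmark(s) {absent}"
            )
        coords = np.array([lm_index[n] for n in scheme.names])
        configs.append(LandmarkConfiguration(str(specimen), coords, scheme))
    return configs


def _read_csv_wide(
    path: Path, df: pd.DataFrame, scheme: LandmarkScheme
) -> list[LandmarkConfiguration]:
    axes = _AXES[: scheme.dimension]
    if "specimen_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'specimen_id'")
    configs = []
    for _, row in df.iterrows():
        specimen = str(row["specimen_id"])
        coords = np.empty((len(scheme), scheme.dimension))
        for i, name in enumerate(scheme.names):
            for j, a in enumerate(axes):
                col = f"{name}_{a}"
                if col not in df.columns or pd.isna(row[col]):
                    raise ValueError(
                        f"{path}: specimen {specimen!r}: missing landmark "
                        f"{name!r} (column {col!r})"
                    )
                coords[i, j] = float(row[col])
        configs.append(LandmarkConfiguration(specimen, coords, scheme))
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration],
    path: str | Path,
    layout: str = "long",
) -> None:
    """Write configurations as TPS (``.tps`` suffix) or CSV (long/wide)."""
    path = Path(path)
    if path.suffix.lower() == ".tps":
        _write_tps(configs, path)
        return
    scheme = configs[0].scheme
    axes = _AXES[: scheme.dimension]
    # repr() gives the shortest exact decimal representation, so files
    # round-trip bit-exactly (pandas' float formatter can be 1 ulp off)
    if layout == "long":
        rows = []
        for c in configs:
            for i, name in enumerate(scheme.names):
                rows.append(
                    {"specimen_id": c.specimen_id, "landmark": name}
                    | {a: repr(float(c.coords[i, j])) for j, a in enumerate(axes)}
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    elif layout == "wide":
        rows = []
        for c in configs:
            row: dict[str, object] = {"specimen_id": c.specimen_id}
            for i, name in enumerate(scheme.names):
                for j, a in enumerate(axes):
                    row[f"{name}_{a}"] = repr(float(c.coords[i, j]))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _write_tps(configs: Sequence[LandmarkConfiguration], path: Path) -> None:
    dim = configs[0].scheme.dimension
    tag = "LM3" if dim == 3 else "LM"
    with open(path, "w", encoding="utf-8") as fh:
        for c in configs:
            fh.write(f"{tag}={len(c.scheme)}\n")
            for row in c.coords:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SpecimenMetadata]:
    """Read the specimen covariate table from CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[SpecimenMetadata] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row["specimen_id"])
        if sid in seen:
            raise ValueError(f"{path}: row {idx}: duplicate specimen_id {sid!r}")
        seen.add(sid)

        def opt(col: str, cast):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        try:
            rec = SpecimenMetadata(
                specimen_id=sid,
                sex=int(row["sex"]),
                age_class=int(row["age_class"]),
                captivity=int(row["captivity"]),
                population=str(row["population"]),
                latitude=opt("latitude", float),
                longitude=opt("longitude", float),
                temperature=opt("temperature", float),
                precipitation=opt("precipitation", float),
                island=opt("island", int),
                age_years=opt("age_years", float),
                generation=opt("generation", int),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return records


def metadata_to_frame(records: Sequence[SpecimenMetadata]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df


def write_metadata(records: Sequence[SpecimenMetadata], path: str | Path) -> None:
    metadata_to_frame(records).to_csv(path, index=False)


def packaged_population_table() -> pd.DataFrame:
    """The packaged 23-population sampling design (prefecture, population,
    wild/captive environment, coordinates and sex/age counts)."""
    from importlib import resources

    ref = resources.files("mandmorph.data").joinpath("populations.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# joining
# ---------------------------------------------------------------------------


@dataclass
class JoinedDataset:
    """Inner join of landmark configurations and metadata on specimen id."""

    configs: list[LandmarkConfiguration]
    metadata: pd.DataFrame  # one row per retained specimen, config order
    unmatched_configs: list[str] = field(default_factory=list)
    unmatched_metadata: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.configs)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configs]


def join_dataset(
    configs: Sequence[LandmarkConfiguration],
    meta: Sequence[SpecimenMetadata] | pd.DataFrame,
) -> JoinedDataset:
    """Inner-join configurations with metadata; unmatched ids are reported
    on both sides and an empty intersection is an error."""
    meta_df = meta if isinstance(meta, pd.DataFrame) else metadata_to_frame(meta)
    meta_df = meta_df.copy()
    meta_df["specimen_id"] = meta_df["specimen_id"].astype(str)
    meta_ids = set(meta_df["specimen_id"])
    config_ids = [c.specimen_id for c in configs]
    matched = [c for c in configs if c.specimen_id in meta_ids]
    if not matched:
        raise ValueError("no specimen ids shared between landmarks and metadata")
    kept_ids = [c.specimen_id for c in matched]
    meta_kept = (
        meta_df.set_index("specimen_id").loc[kept_ids].reset_index()
    )
    return JoinedDataset(
        configs=list(matched),
        metadata=meta_kept,
        unmatched_configs=[s for s in config_ids if s not in meta_ids],
        unmatched_metadata=sorted(meta_ids - set(config_ids)),
    )
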