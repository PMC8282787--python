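"""Reading, validation and seriation of per-vertebra landmark datasets.

A dataset is a flat collection of :class:`VertebraRecord` objects (one 3D
landmark configuration per vertebra per specimen) plus a per-species
metadata table with regional vertebral counts.  Two seriation schemes map
vertebrae into cross-species comparison groups:

``by_number``
    All vertebrae sharing a numeric position within a region are compared
    (all C03, all T14, ...).  Positions beyond the minimum shared count
    (T14, T15, T16, L05-L07) are restricted to the species that possess them.

``by_position``
    A fixed set of anatomically defined positions is compared irrespective
    of count: C03-C07, Tfirst, Tmid, Tdiaph, Tlast, Lfirst, Lmid, Llast.
    The intermediate thoracic is T06 for species with 13 or 14 thoracics and
    T07 for 15 or 16; the intermediate lumbar is L03 for 4 or 5 lumbars and
    L04 for 6 or 7.  The diaphragmatic vertebra is per-species metadata.
"""

from __future__ import annotations

import glob
import json
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError, ParseError

REGIONS = ("cervical", "thoracic", "lumbar")
REGION_PREFIX = {"cervical": "C", "thoracic": "T", "lumbar": "L"}
PREFIX_REGION = {v: k for k, v in REGION_PREFIX.items()}

#: default number of landmarks digitised per region
DEFAULT_K = {"cervical": 34, "thoracic": 32, "lumbar": 36}

#: first digitised element per region (cervicals start at C03)
FIRST_POSITION = {"cervical": 3, "thoracic": 1, "lumbar": 1}

#: loader accepts thoracics up to T16 and lumbars up to L07
MAX_POSITION = {"cervical": 7, "thoracic": 16, "lumbar": 7}

BY_POSITION_KEYS = (
    "C03", "C04", "C05", "C06", "C07",
    "Tfirst", "Tmid", "Tdiaph", "Tlast",
    "Lfirst", "Lmid", "Llast",
)


def position_label(region: str, position: int) -> str:
    """Format ``("thoracic", 14)`` as the conventional label ``"T14"``."""
    return f"{REGION_PREFIX[region]}{position:02d}"


def parse_position_label(label: str) -> tuple[str, int]:
    """Parse ``"T14"`` into ``("thoracic", 14)``."""
    m = re.fullmatch(r"([CTL])(\d{1,2})", label.strip())
    if not m:
        raise ParseError(f"unrecognised vertebra label {label!r}")
    region = PREFIX_REGION[m.group(1)]
    pos = int(m.group(2))
    if not FIRST_POSITION[region] <= pos <= MAX_POSITION[region]:
        raise ParseError(
            f"position {label!r} outside the accepted range for {region} "
            f"({FIRST_POSITION[region]}..{MAX_POSITION[region]})"
        )
    return region, pos


@dataclass
class VertebraRecord:
    """One landmark configuration tied to specimen, species and serial position."""

    specimen_id: str
    species: str
    region: str
    position: int
    coords: np.ndarray  # (K, 3)
    landmark_labels: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError(
                f"{self.label}: coordinates must be a K x 3 matrix, "
                f"got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise DimensionError(f"{self.label}: non-finite coordinates")
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def label(self) -> str:
        return f"{self.species}/{self.specimen_id}/{position_label(self.region, self.position)}"

    def validate_k(self, expected_k: dict[str, int]) -> None:
        exp = expected_k[self.region]
        if self.k != exp:
            raise DimensionError(
                f"{self.label}: expected {exp} landmarks for {self.region} "
                f"vertebrae, observed {self.k}"
            )


@dataclass
class SpeciesMeta:
    """Per-species vertebral formula and diaphragmatic position."""

    species: str
    n_cervical: int = 7
    n_thoracic: int = 13
    n_lumbar: int = 7
    diaphragmatic_position: int | None = None
    ecology_source_category: str | None = None
    count_exception: bool = False  # explicit flag for formulas not summing to 20

    def validate(self) -> None:
        if self.n_thoracic + self.n_lumbar != 20 and not self.count_exception:
            raise ConfigurationError(
                f"{self.species}: thoracolumbar count "
                f"{self.n_thoracic}T + {self.n_lumbar}L != 20 and the species "
                "is not flagged as a declared count exception"
            )
        if not 13 <= self.n_thoracic <= 16:
            raise ConfigurationError(
                f"{self.species}: thoracic count {self.n_thoracic} outside 13..16"
            )
        if not 4 <= self.n_lumbar <= 7:
            raise ConfigurationError(
                f"{self.species}: lumbar count {self.n_lumbar} outside 4..7"
            )
        if self.diaphragmatic_position is not None and not (
            1 <= self.diaphragmatic_position <= self.n_thoracic
        ):
            raise ConfigurationError(
                f"{self.species}: diaphragmatic position "
                f"T{self.diaphragmatic_position:02d} outside the thoracic series"
            )


@dataclass
class LandmarkPairing:
    """Bilateral landmark pairing: (left, right) index pairs plus midline indices.

    Indices are 0-based and must partition ``0..K-1``.
    """

    paired: list[tuple[int, int]]
    midline: list[int]

    @property
    def k(self) -> int:
        return 2 * len(self.paired) + len(self.midline)

    def validate(self, k: int) -> None:
        seen = list(self.midline)
        for l, r in self.paired:
            seen.extend((l, r))
        if sorted(seen) != list(range(k)):
            raise ConfigurationError(
                f"pairing does not partition 0..{k - 1}: indices {sorted(seen)}"
            )

    def swap_permutation(self, k: int) -> np.ndarray:
        """Row permutation exchanging each left landmark with its right partner."""
        self.validate(k)
        perm = np.arange(k)
        for l, r in self.paired:
            perm[l], perm[r] = r, l
        return perm


@dataclass
class SeriationScheme:
    """Mapping of vertebrae into comparison groups under one sampling rule."""

    name: str  # "by_number" | "by_position"
    groups: dict  # key -> list of (species, region, position)
    order: list = field(default_factory=list)  # canonical key order

    def group_label(self, key) -> str:
        if isinstance(key, tuple):
            return position_label(*key)
        return str(key)

    def region_of(self, key) -> str:
        if isinstance(key, tuple):
            return key[0]
        if key.startswith("C"):
            return "cervical"
        return "thoracic" if key.startswith("T") else "lumbar"


# ---------------------------------------------------------------------------
# File IO

_FILENAME_RE = re.compile(r"(?P<species>.+?)__(?P<specimen>.+?)__(?P<label>[CTL]\d{1,2})")


def _parse_record_name(name: str):
    m = _FILENAME_RE.fullmatch(name)
    if not m:
        raise ParseError(
            f"cannot parse record identity from {name!r}; expected "
            "'<species>__<specimen>__<region><pos>' (e.g. Canis_lupus__UMA001__C03)"
        )
    region, pos = parse_position_label(m.group("label"))
    return m.group("species"), m.group("specimen"), region, pos


def _parse_xyz_lines(lines, path):
    coords, labels = [], []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) == 4:  # optional leading landmark label
            labels.append(parts[0])
            parts = parts[1:]
        elif len(parts) != 3:
            raise ParseError(
                f"malformed coordinate line {line!r} (expected 3 numbers)",
                path=path, line=ln,
            )
        try:
            coords.append([float(v) for v in parts])
        except ValueError:
            raise ParseError(
                f"non-numeric coordinate in line {line!r}", path=path, line=ln
            ) from None
    if not coords:
        raise ParseError("no coordinate lines found", path=path)
    return np.asarray(coords, float), (labels if len(labels) == len(coords) else None)


def read_landmark_table(
    path: str,
    dialect: str = "xyz_text",
    expected_k: dict[str, int] | None = None,
) -> list[VertebraRecord]:
    """Read one landmark file into a list of :class:`VertebraRecord`.

    ``xyz_text`` files hold one vertebra: one landmark per line as
    whitespace- or comma-separated ``x y z`` (optionally preceded by a label),
    with identity encoded in the file name
    ``<species>__<specimen>__<region><pos>.txt``.  The ``tps`` dialect uses
    ``LM3=`` headers and ``ID=`` identity lines and may hold several vertebrae.

    Coordinates are preserved exactly as parsed (no rescaling or rounding).
    """
    expected_k = dict(DEFAULT_K if expected_k is None else expected_k)
    if not os.path.exists(path):
        raise ParseError("file does not exist", path=path)
    if dialect == "xyz_text":
        name = os.path.splitext(os.path.basename(path))[0]
        species, specimen, region, pos = _parse_record_name(name)
        with open(path) as fh:
            coords, labels = _parse_xyz_lines(fh, path)
        rec = VertebraRecord(specimen, species, region, pos, coords, labels)
        rec.validate_k(expected_k)
        return [rec]
    if dialect == "tps":
        return _read_tps(path, expected_k)
    raise ConfigurationError(f"unknown landmark dialect {dialect!r}")


def _read_tps(path, expected_k):
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.fullmatch(r"LM3\s*=\s*(\d+)", line, flags=re.IGNORECASE)
        if not m:
            raise ParseError(f"expected 'LM3=' header, found {line!r}", path=path, line=i + 1)
        k = int(m.group(1))
        if i + k >= n:
            raise ParseError(f"truncated block: {k} landmarks declared", path=path, line=i + 1)
        coords, _ = _parse_xyz_lines(lines[i + 1 : i + 1 + k], path)
        if coords.shape[0] != k:
            raise ParseError(
                f"block declares {k} landmarks but {coords.shape[0]} parsed",
                path=path, line=i + 1,
            )
        i += 1 + k
        ident = None
        while i < n and lines[i].strip():
            km = re.fullmatch(r"(\w+)\s*=\s*(.*)", lines[i].strip())
            if not km:
                break
            if km.group(1).upper() == "ID":
                ident = km.group(2).strip()
            i += 1
        if ident is None:
            raise ParseError("TPS block without an ID= line", path=path, line=i)
        species, specimen, region, pos = _parse_record_name(ident)
        rec = VertebraRecord(specimen, species, region, pos, coords)
        rec.validate_k(expected_k)
        records.append(rec)
    return records


def write_landmark_table(record: VertebraRecord, path: str) -> None:
    """Write one record in the plain ``x y z`` text dialect (full precision)."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(record.coords):
            label = (
                record.landmark_labels[i]
                if record.landmark_labels is not None
                else None
            )
            prefix = f"{label} " if label else ""
            # repr of Python floats is the shortest exact round-trip form
            fh.write(f"{prefix}{float(x)!r} {float(y)!r} {float(z)!r}\n")


def record_filename(record: VertebraRecord) -> str:
    return (
        f"{record.species}__{record.specimen_id}__"
        f"{position_label(record.region, record.position)}.txt"
    )


def read_dataset_dir(
    path: str, expected_k: dict[str, int] | None = None
) -> list[VertebraRecord]:
    """Read every ``*.txt`` landmark file under ``path`` (sorted for determinism)."""
    records = []
    for fn in sorted(glob.glob(os.path.join(path, "*.txt"))):
        records.extend(read_landmark_table(fn, "xyz_text", expected_k))
    if not records:
        raise ParseError("no landmark files found", path=path)
    return records


def read_species_meta(path: str) -> list[SpeciesMeta]:
    """Read the species metadata CSV (one row per species)."""
    df = pd.read_csv(path)
    required = {"species", "n_thoracic", "n_lumbar"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata CSV missing columns {sorted(missing)}", path=path)
    metas = []
    for _, row in df.iterrows():
        diaph = row.get("diaphragmatic_position")
        metas.append(
            SpeciesMeta(
                species=str(row["species"]),
                n_cervical=int(row.get("n_cervical", 7)),
                n_thoracic=int(row["n_thoracic"]),
                n_lumbar=int(row["n_lumbar"]),
                diaphragmatic_position=None if pd.isna(diaph) else int(diaph),
                ecology_source_category=(
                    None
                    if "ecology_source_category" not in df.columns
                    or pd.isna(row["ecology_source_category"])
                    else str(row["ecology_source_category"])
                ),
                count_exception=bool(row.get("count_exception", False)),
            )
        )
    for m in metas:
        m.validate()
    return metas


def species_meta_frame(metas: list[SpeciesMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [m.species for m in metas],
            "n_cervical": [m.n_cervical for m in metas],
            "n_thoracic": [m.n_thoracic for m in metas],
            "n_lumbar": [m.n_lumbar for m in metas],
            "diaphragmatic_position": [m.diaphragmatic_position for m in metas],
            "ecology_source_category": [m.ecology_source_category for m in metas],
            "count_exception": [m.count_exception for m in metas],
        }
    )


def dataset_manifest(records: list[VertebraRecord]) -> pd.DataFrame:
    """Tabular manifest of a validated dataset (one row per record)."""
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "specimen_id": [r.specimen_id for r in records],
            "region": [r.region for r in records],
            "position": [r.position for r in records],
            "label": [position_label(r.region, r.position) for r in records],
            "n_landmarks": [r.k for r in records],
        }
    )


def write_manifest(records: list[VertebraRecord], path: str) -> None:
    df = dataset_manifest(records)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation

def expected_positions(meta: SpeciesMeta) -> list[tuple[str, int]]:
    """All (region, position) pairs a species should contribute."""
    out = [("cervical", p) for p in range(3, meta.n_cervical + 1)]
    out += [("thoracic", p) for p in range(1, meta.n_thoracic + 1)]
    out += [("lumbar", p) for p in range(1, meta.n_lumbar + 1)]
    return out


def validate_dataset(
    records: list[VertebraRecord],
    meta: list[SpeciesMeta],
    expected_k: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Validate records against metadata; returns the manifest.

    Checks landmark counts, duplicate records, that positions within each
    specimen's region are consecutive from the region's first digitised
    element, and that positions do not exceed the species' counts.
    Missing vertebrae (relative to the species formula) raise a warning
    listing the gaps, not an error: downstream grouping simply skips them.
    """
    expected_k = dict(DEFAULT_K if expected_k is None else expected_k)
    meta_by_species = {m.species: m for m in meta}
    seen = set()
    for r in records:
        r.validate_k(expected_k)
        key = (r.species, r.specimen_id, r.region, r.position)
        if key in seen:
            raise ConfigurationError(f"duplicate record {r.label}")
        seen.add(key)
        m = meta_by_species.get(r.species)
        if m is None:
            raise ConfigurationError(f"{r.label}: species absent from metadata")
        counts = {"cervical": m.n_cervical, "thoracic": m.n_thoracic, "lumbar": m.n_lumbar}
        if r.position > counts[r.region]:
            raise ConfigurationError(
                f"{r.label}: position exceeds the species' {r.region} count "
                f"({counts[r.region]})"
            )
    # consecutive positions per specimen region
    by_specimen: dict[tuple, list[int]] = {}
    for r in records:
        by_specimen.setdefault((r.species, r.specimen_id, r.region), []).append(r.position)
    for (sp, spec, region), positions in by_specimen.items():
        positions = sorted(positions)
        first = positions[0]
        if positions != list(range(first, first + len(positions))):
            raise ConfigurationError(
                f"{sp}/{spec}: {region} positions {positions} are not consecutive"
            )
        if first != FIRST_POSITION[region]:
            raise ConfigurationError(
                f"{sp}/{spec}: {region} series starts at {first}, expected "
                f"{FIRST_POSITION[region]}"
            )
    gaps = []
    present = {(r.species, r.region, r.position) for r in records}
    for m in meta:
        if m.species not in {r.species for r in records}:
            continue
        for region, pos in expected_positions(m):
            if (m.species, region, pos) not in present:
                gaps.append(f"{m.species}:{position_label(region, pos)}")
    if gaps:
        warnings.warn(
            f"dataset is missing {len(gaps)} expected vertebrae: "
            + ", ".join(gaps[:20]) + ("..." if len(gaps) > 20 else ""),
            stacklevel=2,
        )
    return dataset_manifest(records)


# ---------------------------------------------------------------------------
# Seriation schemes

def _species_entries(records, meta):
    """Unique (species, region, position) triples present in the dataset."""
    meta_by_species = {m.species: m for m in meta}
    entries = sorted({(r.species, r.region, r.position) for r in records})
    for sp, _, _ in entries:
        if sp not in meta_by_species:
            raise ConfigurationError(f"species {sp!r} absent from metadata")
    return entries, meta_by_species


def build_by_number_groups(
    records: list[VertebraRecord], meta: list[SpeciesMeta]
) -> SeriationScheme:
    """Group vertebrae by numeric position within each region.

    Positions present in only a subset of species (T14-T16, L05-L07) yield
    groups restricted to the species that possess them.  Species that should
    have a vertebra per their formula but lack it in the dataset trigger a
    completeness warning (emitted by :func:`validate_dataset`).
    """
    entries, _ = _species_entries(records, meta)
    groups: dict[tuple, list] = {}
    for sp, region, pos in entries:
        groups.setdefault((region, pos), []).append((sp, region, pos))
    order = sorted(
        groups, key=lambda k: (REGIONS.index(k[0]), k[1])
    )
    return SeriationScheme("by_number", groups, order)


def mid_thoracic(n_thoracic: int) -> int:
    """Intermediate thoracic: T06 for 13-14 thoracics, T07 for 15-16."""
    if n_thoracic in (13, 14):
        return 6
    if n_thoracic in (15, 16):
        return 7
    raise ConfigurationError(f"thoracic count {n_thoracic} outside 13..16")


def mid_lumbar(n_lumbar: int) -> int:
    """Intermediate lumbar: L03 for 4-5 lumbars, L04 for 6-7."""
    if n_lumbar in (4, 5):
        return 3
    if n_lumbar in (6, 7):
        return 4
    raise ConfigurationError(f"lumbar count {n_lumbar} outside 4..7")


def build_by_position_groups(
    records: list[VertebraRecord], meta: list[SpeciesMeta]
) -> SeriationScheme:
    """Group a fixed set of anatomically defined positions irrespective of count."""
    entries, meta_by_species = _species_entries(records, meta)
    present = set(entries)
    species = sorted({e[0] for e in entries})
    for sp in species:
        if meta_by_species[sp].diaphragmatic_position is None:
            raise ConfigurationError(
                f"{sp}: diaphragmatic_position missing from metadata; the "
                "by_position scheme requires it (no heuristic guessing)"
            )
    groups: dict[str, list] = {k: [] for k in BY_POSITION_KEYS}
    for sp in species:
        m = meta_by_species[sp]
        targets = {
            "Tfirst": ("thoracic", 1),
            "Tmid": ("thoracic", mid_thoracic(m.n_thoracic)),
            "Tdiaph": ("thoracic", m.diaphragmatic_position),
            "Tlast": ("thoracic", m.n_thoracic),
            "Lfirst": ("lumbar", 1),
            "Lmid": ("lumbar", mid_lumbar(m.n_lumbar)),
            "Llast": ("lumbar", m.n_lumbar),
        }
        for p in range(3, 8):
            targets[f"C{p:02d}"] = ("cervical", p)
        for key, (region, pos) in targets.items():
            if (sp, region, pos) in present:
                groups[key].append((sp, region, pos))
    groups = {k: v for k, v in groups.items() if v}
    order = [k for k in BY_POSITION_KEYS if k in groups]
    return SeriationScheme("by_position", groups, order)
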