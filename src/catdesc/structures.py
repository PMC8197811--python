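"""Geometries, charge tables, and environment series.

The unit of ingestion is a stationary point of an SN2 reaction — reactant
complex (RC), transition state (TS), or product complex (PC) — given as an
XYZ geometry plus an optional CSV table of atomic partial charges.  A
:class:`ReactionRecord` bundles the three stationary points of one
environment (e.g. the enzyme active site with three, two, one, or zero
aromatic residues, or bulk water) together with the atom selections that
define the breaking bond (C1–Cl1), the forming bond (O1–C1), and the
nucleophile group, plus the activation barrier for that environment.

Conventions, fixed throughout the package: distances in Å, charges in
units of the elementary charge e, energies in kcal/mol.  Atom indices in
all user-facing files are 1-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "Geometry",
    "ChargeTable",
    "StationaryPoint",
    "ReactionRecord",
    "EnvironmentSeries",
    "XYZParseError",
    "ChargeTableError",
    "SeriesConfigError",
    "read_xyz",
    "write_xyz",
    "read_charge_table",
    "write_charge_table",
    "bond_length",
    "load_series",
]


class XYZParseError(ValueError):
    """Malformed XYZ file; the message names the offending line."""


class ChargeTableError(ValueError):
    """Malformed or inconsistent charge CSV."""


class SeriesConfigError(ValueError):
    """Invalid series configuration."""


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol and Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.element}: {pos}")
        object.__setattr__(self, "position", pos)


@dataclass
class Geometry:
    """An ordered collection of atoms with a free-text comment line.

    Atom indices are 1-based in every public interface, matching the
    convention of XYZ files and of how atoms like C1/Cl1/O1 are labelled
    in structural chemistry.
    """

    atoms: list[Atom]
    comment: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a Geometry requires at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> Atom:
        """Return the atom at a 1-based index."""
        if not 1 <= index <= len(self.atoms):
            raise IndexError(
                f"atom index {index} out of range 1..{len(self.atoms)}"
            )
        return self.atoms[index - 1]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class ChargeTable:
    """Atomic partial charges keyed by 1-based atom index.

    Each entry carries a label (atom or group name) and a signed charge in
    e.  A grouped row — a whole fragment like CH3CO2 reported as a single
    value — is representable as one pseudo-atom entry; group summation
    then reduces to the singleton case.
    """

    entries: dict[int, tuple[str, float]]
    scheme: str | None = None  # population-analysis scheme, metadata only

    def __post_init__(self) -> None:
        for idx, (label, q) in self.entries.items():
            if not math.isfinite(q):
                raise ChargeTableError(
                    f"non-finite charge {q!r} at index {idx} ({label})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def charge(self, index: int) -> float:
        try:
            return self.entries[index][1]
        except KeyError:
            raise ChargeTableError(
                f"atom index {index} missing from charge table"
            ) from None


@dataclass
class StationaryPoint:
    """A stationary point (RC, TS or PC) with geometry and optional data."""

    role: str
    geometry: Geometry
    charges: ChargeTable | None = None
    energy: float | None = None  # kcal/mol

    ROLES = ("RC", "TS", "PC")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {self.role!r}")


@dataclass
class ReactionRecord:
    """One reaction environment: stationary points, bond selections, barrier.

    ``leaving_bond`` is the (C1, Cl1) index pair of the breaking bond and
    ``forming_bond`` the (O1, C1) pair of the forming bond; they must share
    exactly one atom, the electrophilic carbon C1.  ``barrier`` is the
    activation barrier in kcal/mol (free-energy by default; a series-level
    flag selects potential-energy barriers).  ``descriptors`` names which
    descriptors this environment supports — an environment whose TS bond
    lengths are unknown can still contribute charge-transfer data.
    """

    label: str
    ts: StationaryPoint
    rc: StationaryPoint | None = None
    pc: StationaryPoint | None = None
    leaving_bond: tuple[int, int] = (2, 3)
    forming_bond: tuple[int, int] = (1, 2)
    nucleophile_selection: frozenset[int] = frozenset({1})
    barrier: float | None = None
    role: str = "fit"  # "fit" or "predict" (held out of scaling fits)
    descriptors: frozenset[str] = frozenset({"dcat", "qcat"})

    def __post_init__(self) -> None:
        self.nucleophile_selection = frozenset(self.nucleophile_selection)
        self.descriptors = frozenset(self.descriptors)
        shared = set(self.leaving_bond) & set(self.forming_bond)
        if len(shared) != 1:
            raise SeriesConfigError(
                f"environment {self.label!r}: leaving bond {self.leaving_bond} and "
                f"forming bond {self.forming_bond} must share exactly one atom (C1), "
                f"shared {sorted(shared)}"
            )
        if not self.nucleophile_selection:
            raise SeriesConfigError(
                f"environment {self.label!r}: empty nucleophile selection"
            )
        cl1 = self.leaving_bond[1]
        if cl1 in self.nucleophile_selection:
            raise SeriesConfigError(
                f"environment {self.label!r}: nucleophile selection must not "
                f"contain the leaving-group atom Cl1 (index {cl1})"
            )
        if self.role not in ("fit", "predict"):
            raise SeriesConfigError(
                f"environment {self.label!r}: role must be 'fit' or 'predict'"
            )
        bad = self.descriptors - {"dcat", "qcat"}
        if bad:
            raise SeriesConfigError(
                f"environment {self.label!r}: unknown descriptors {sorted(bad)}"
            )
        if self.barrier is not None and not math.isfinite(self.barrier):
            raise SeriesConfigError(
                f"environment {self.label!r}: non-finite barrier {self.barrier}"
            )

    @property
    def c1(self) -> int:
        return next(iter(set(self.leaving_bond) & set(self.forming_bond)))

    @property
    def cl1(self) -> int:
        return self.leaving_bond[1]

    @property
    def o1(self) -> int:
        pair = set(self.forming_bond) - {self.c1}
        return next(iter(pair))


@dataclass
class EnvironmentSeries:
    """An ordered series of reaction environments with unique labels."""

    records: list[ReactionRecord]
    barrier_kind: str = "free_energy"  # or "potential_energy"

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise SeriesConfigError(f"duplicate environment labels: {sorted(dupes)}")
        if self.barrier_kind not in ("free_energy", "potential_energy"):
            raise SeriesConfigError(
                f"barrier_kind must be 'free_energy' or 'potential_energy', "
                f"got {self.barrier_kind!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, label: str) -> ReactionRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(f"no environment labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]


# ---------------------------------------------------------------------------
# File I/O


def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file (count line, comment line, element x y z rows).

    Coordinates are in Å.  Raises :class:`XYZParseError` naming the line on
    any malformed content, including a count-line mismatch.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(
            f"{path}, line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    if n_atoms < 1:
        raise XYZParseError(f"{path}, line 1: atom count must be >= 1, got {n_atoms}")
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [l for l in lines[2:] if l.strip()]
    if len(atom_lines) != n_atoms:
        raise XYZParseError(
            f"{path}: count line says {n_atoms} atoms but found {len(atom_lines)} atom rows"
        )
    atoms = []
    for i, line in enumerate(atom_lines, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(
                f"{path}, line {i}: expected 'element x y z', got {line!r}"
            )
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"{path}, line {i}: non-numeric coordinate in {line!r}"
            ) from None
        atoms.append(Atom(parts[0], np.array(xyz)))
    return Geometry(atoms=atoms, comment=comment)


def write_xyz(geometry: Geometry, path: str | Path) -> None:
    """Write a Geometry as standard XYZ with 6-decimal coordinates.

    The fixed formatting makes output bit-stable: writing the same
    geometry twice yields identical bytes, and a write/read round trip
    preserves coordinates to better than 1e-6 Å.
    """
    path = Path(path)
    lines = [str(len(geometry)), geometry.comment]
    for atom in geometry.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_charge_table(path: str | Path) -> ChargeTable:
    """Read a charge CSV with mandatory header ``index,label,charge``.

    One row per atom (or per pseudo-atom group); 1-based indices; duplicate
    indices and non-numeric charges are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"index": "Int64", "label": str})
    except pd.errors.EmptyDataError:
        raise ChargeTableError(f"{path}: no rows") from None
    required = ["index", "label", "charge"]
    if list(df.columns[:3]) != required:
        raise ChargeTableError(
            f"{path}: header must be 'index,label,charge', got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ChargeTableError(f"{path}: no rows")
    if df["index"].isna().any():
        raise ChargeTableError(f"{path}: missing or non-integer atom index")
    charges = pd.to_numeric(df["charge"], errors="coerce")
    if charges.isna().any():
        bad = df.loc[charges.isna(), "charge"].iloc[0]
        raise ChargeTableError(f"{path}: non-numeric charge {bad!r}")
    idx = df["index"].astype(int)
    if idx.duplicated().any():
        dup = int(idx[idx.duplicated()].iloc[0])
        raise ChargeTableError(f"{path}: duplicate atom index {dup}")
    entries = {
        int(i): (str(l), float(q))
        for i, l, q in zip(idx, df["label"], charges)
    }
    return ChargeTable(entries=entries)


def write_charge_table(table: ChargeTable, path: str | Path) -> None:
    """Write a ChargeTable as ``index,label,charge`` CSV (sorted by index)."""
    path = Path(path)
    rows = ["index,label,charge"]
    for idx in sorted(table.entries):
        label, q = table.entries[idx]
        rows.append(f"{idx},{label},{q:.6f}")
    path.write_text("\n".join(rows) + "\n")


def bond_length(geometry: Geometry, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms at 1-based indices i and j."""
    if i == j:
        raise ValueError(f"bond requires two distinct atoms, got i == j == {i}")
    return float(np.linalg.norm(geometry.atom(i).position - geometry.atom(j).position))


# ---------------------------------------------------------------------------
# Series configuration


_ENV_REQUIRED = ("label", "ts_xyz", "c1", "cl1", "o1", "nucleophile_indices")


def load_series(config: str | Path) -> EnvironmentSeries:
    """Load an :class:`EnvironmentSeries` from a YAML or JSON config file.

    The config lists environments, each with paths to its XYZ geometries
    and charge CSVs (relative paths resolve against the config file's
    directory), the C1/Cl1/O1 atom indices, the nucleophile atom
    selection, and the barrier in kcal/mol.  All referenced files are
    loaded eagerly and every selection is checked against the geometries,
    so a series that loads is fully usable downstream.
    """
    config = Path(config)
    if not config.exists():
        raise SeriesConfigError(f"config file not found: {config}")
    text = config.read_text()
    data = json.loads(text) if config.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping) or "environments" not in data:
        raise SeriesConfigError(f"{config}: expected a mapping with 'environments'")
    base = config.parent
    barrier_kind = data.get("barrier_kind", "free_energy")

    records = []
    for env in data["environments"]:
        missing = [k for k in _ENV_REQUIRED if k not in env]
        if missing:
            raise SeriesConfigError(
                f"{config}: environment entry missing keys {missing}: {env}"
            )
        label = str(env["label"])

        def _load_point(role: str, xyz_key: str, charge_key: str) -> StationaryPoint | None:
            xyz = env.get(xyz_key)
            if xyz is None:
                return None
            xyz_path = base / xyz
            if not xyz_path.exists():
                raise SeriesConfigError(
                    f"{config}: environment {label!r}: missing file {xyz_path}"
                )
            geom = read_xyz(xyz_path)
            charges = None
            if env.get(charge_key) is not None:
                cpath = base / env[charge_key]
                if not cpath.exists():
                    raise SeriesConfigError(
                        f"{config}: environment {label!r}: missing file {cpath}"
                    )
                charges = read_charge_table(cpath)
            return StationaryPoint(role=role, geometry=geom, charges=charges)

        ts = _load_point("TS", "ts_xyz", "ts_charges")
        rc = _load_point("RC", "rc_xyz", "rc_charges")
        pc = _load_point("PC", "pc_xyz", "pc_charges")

        c1, cl1, o1 = int(env["c1"]), int(env["cl1"]), int(env["o1"])
        nucleophile = frozenset(int(i) for i in env["nucleophile_indices"])
        for point in (ts, rc, pc):
            if point is None:
                continue
            n = len(point.geometry)
            for idx in {c1, cl1, o1} | nucleophile:
                if not 1 <= idx <= n:
                    raise SeriesConfigError(
                        f"{config}: environment {label!r}: atom index {idx} out of "
                        f"range 1..{n} in {point.role} geometry"
                    )
        barrier = env.get("barrier_kcal_mol")
        record = ReactionRecord(
            label=label,
            ts=ts,
            rc=rc,
            pc=pc,
            leaving_bond=(c1, cl1),
            forming_bond=(o1, c1),
            nucleophile_selection=nucleophile,
            barrier=None if barrier is None else float(barrier),
            role=env.get("role", "fit"),
            descriptors=frozenset(env.get("descriptors", ("dcat", "qcat"))),
        )
        records.append(record)
    return EnvironmentSeries(records=records, barrier_kind=barrier_kind)
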