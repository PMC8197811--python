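"""Synthetic environment series with prescribed descriptor values.

Downstream stages (descriptor computation, scaling fits, the CLI report)
need complete, loadable input series — geometries, charge tables, barrier
values — but no deposited structures exist for the truncated active-site
models this package analyses.  This module fabricates them: minimal
collinear O1–C1–Cl1 geometries whose transition-state bond lengths encode
an exact target Dcat, and RC/TS charge tables whose nucleophile group
sums differ by an exact target Qcat.  Barriers are the prescribed values
plus optional Gaussian noise drawn from an explicit seed; with σ = 0 the
generated series round-trips every number exactly, which is the basis of
the loader and descriptor tests.

Chemical realism is deliberately not attempted: the descriptor
computations read two interatomic distances and a handful of charges, so
three collinear atoms (plus inert padding on request) carry everything
the statistics see.  What the synthetic data cannot represent is
discussed in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .structures import (
    Atom,
    ChargeTable,
    EnvironmentSeries,
    Geometry,
    ReactionRecord,
    StationaryPoint,
    load_series,
    write_charge_table,
    write_xyz,
)

__all__ = [
    "EnvironmentTarget",
    "SeriesSpec",
    "ChargeEvolutionParams",
    "charge_evolution",
    "generate_record",
    "generate_series",
    "enzyme_demo_spec",
]

# Geometry construction constants (Å).  The forming O1-C1 distance at the
# TS is fixed; the leaving C1-Cl1 distance is base + target Dcat, so the
# descriptor is encoded exactly.
TS_FORMING_DISTANCE = 2.0
RC_FORMING_DISTANCE = 3.0
RC_LEAVING_DISTANCE = 1.80
PC_FORMING_DISTANCE = 1.45
PC_LEAVING_DISTANCE = 3.20

# Default nucleophile group charge at the reactant complex, e (an
# acetate-like anion that has donated little charge yet).
DEFAULT_RC_CHARGE = -0.94


@dataclass
class ChargeEvolutionParams:
    """Logistic charge-transfer profile along the reaction coordinate.

    As an SN2 reaction proceeds, the nucleophile's negative charge flows
    to the leaving group; this parameterizes that transfer as a logistic
    switch in normalized arc length s ∈ [0, 1] from ``start`` (RC charge)
    to ``end`` (PC charge), centred at ``midpoint`` with ``width``
    controlling steepness.
    """

    start: float = DEFAULT_RC_CHARGE
    end: float = -0.20
    midpoint: float = 0.5
    width: float = 0.15

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if not 0.0 < self.midpoint < 1.0:
            raise ValueError(f"midpoint must lie in (0, 1), got {self.midpoint}")


def charge_evolution(s: float, params: ChargeEvolutionParams) -> float:
    """Nucleophile group charge at normalized arc length s ∈ [0, 1].

    A logistic interpolation rescaled so the endpoints are met exactly:
    s = 0 gives the start charge, s = 1 the end charge, and for a centred
    midpoint the halfway point gives their mean.  Monotone in s.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"arc length s must lie in [0, 1], got {s}")

    def sigma(t: float) -> float:
        return 1.0 / (1.0 + math.exp(-t))

    lo = sigma((0.0 - params.midpoint) / params.width)
    hi = sigma((1.0 - params.midpoint) / params.width)
    frac = (sigma((s - params.midpoint) / params.width) - lo) / (hi - lo)
    return params.start + (params.end - params.start) * frac


@dataclass
class EnvironmentTarget:
    """Prescribed values for one synthetic environment.

    target_dcat may be None for an environment contributing only
    charge-transfer data (its TS geometry then carries a neutral
    placeholder and the dcat descriptor is not requested).
    """

    label: str
    barrier: float | None  # kcal/mol; None for predict-only environments
    target_dcat: float | None = None
    target_qcat: float | None = None
    role: str = "fit"

    def __post_init__(self) -> None:
        if self.target_dcat is None and self.target_qcat is None:
            raise ValueError(
                f"environment {self.label!r}: need at least one descriptor target"
            )


@dataclass
class SeriesSpec:
    """Full specification of a synthetic series.

    barrier_sigma is the standard deviation (kcal/mol) of Gaussian noise
    added to each prescribed barrier; 0 reproduces barriers exactly.  The
    seed is mandatory so every generated byte is reproducible.
    """

    environments: list[EnvironmentTarget]
    seed: int
    barrier_sigma: float = 0.0
    charge_params: ChargeEvolutionParams = field(default_factory=ChargeEvolutionParams)
    barrier_kind: str = "free_energy"
    n_padding_atoms: int = 0

    def __post_init__(self) -> None:
        labels = [e.label for e in self.environments]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate environment labels in spec: {labels}")
        if self.barrier_sigma < 0:
            raise ValueError(f"barrier_sigma must be >= 0, got {self.barrier_sigma}")


def _collinear_geometry(
    d_forming: float, d_leaving: float, comment: str, n_padding: int = 0
) -> Geometry:
    """O1 at the origin, C1 and Cl1 further along +x; optional inert padding."""
    atoms = [
        Atom("O", np.array([0.0, 0.0, 0.0])),
        Atom("C", np.array([d_forming, 0.0, 0.0])),
        Atom("Cl", np.array([d_forming + d_leaving, 0.0, 0.0])),
    ]
    for k in range(n_padding):
        # He spectators well off the reaction axis; never selected.
        atoms.append(Atom("He", np.array([float(k), 5.0, 5.0])))
    return Geometry(atoms=atoms, comment=comment)


def _charge_tables(
    target_qcat: float | None, params: ChargeEvolutionParams, n_padding: int
) -> tuple[ChargeTable, ChargeTable]:
    """RC and TS tables whose nucleophile (atom 1) sums differ by target_qcat."""
    q_rc = params.start
    q_ts = q_rc if target_qcat is None else q_rc + target_qcat
    total = -1.0  # overall anionic complex; Cl balances

    def table(q_nuc: float) -> ChargeTable:
        entries = {
            1: ("O1_nucleophile", q_nuc),
            2: ("C1", 0.25),
            3: ("Cl1", total - q_nuc - 0.25),
        }
        for k in range(n_padding):
            entries[4 + k] = (f"pad{k + 1}", 0.0)
        return ChargeTable(entries=entries)

    return table(q_rc), table(q_ts)


def generate_record(
    label: str,
    target_dcat: float | None,
    target_qcat: float | None,
    barrier: float | None,
    *,
    role: str = "fit",
    charge_params: ChargeEvolutionParams | None = None,
    n_padding_atoms: int = 0,
) -> ReactionRecord:
    """Build an in-memory ReactionRecord with exact descriptor targets.

    The TS geometry places O1–C1 at 2.0 Å and C1–Cl1 at 2.0 + target_dcat
    Å on a line, so compute_dcat recovers the target to machine precision;
    the RC/TS charge tables encode target_qcat the same way.  RC and PC
    geometries are stretched/compressed analogues for completeness.
    """
    params = charge_params or ChargeEvolutionParams()
    dcat = 0.0 if target_dcat is None else target_dcat
    for name, value in (("target_dcat", dcat), ("target_qcat", target_qcat)):
        if value is not None and not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")

    ts_geom = _collinear_geometry(
        TS_FORMING_DISTANCE,
        TS_FORMING_DISTANCE + dcat,
        f"synthetic TS label={label}",
        n_padding_atoms,
    )
    rc_geom = _collinear_geometry(
        RC_FORMING_DISTANCE, RC_LEAVING_DISTANCE,
        f"synthetic RC label={label}", n_padding_atoms,
    )
    pc_geom = _collinear_geometry(
        PC_FORMING_DISTANCE, PC_LEAVING_DISTANCE,
        f"synthetic PC label={label}", n_padding_atoms,
    )
    rc_charges, ts_charges = _charge_tables(target_qcat, params, n_padding_atoms)

    descriptors = set()
    if target_dcat is not None:
        descriptors.add("dcat")
    if target_qcat is not None:
        descriptors.add("qcat")

    return ReactionRecord(
        label=label,
        ts=StationaryPoint("TS", ts_geom, charges=ts_charges),
        rc=StationaryPoint("RC", rc_geom, charges=rc_charges),
        pc=StationaryPoint("PC", pc_geom),
        leaving_bond=(2, 3),
        forming_bond=(1, 2),
        nucleophile_selection=frozenset({1}),
        barrier=barrier,
        role=role,
        descriptors=frozenset(descriptors),
    )


def generate_series(spec: SeriesSpec, outdir: str | Path) -> tuple[EnvironmentSeries, Path]:
    """Write a complete series to disk and load it back.

    Emits per-environment XYZ files and charge CSVs plus a ``series.yaml``
    consumable by :func:`catdesc.structures.load_series`.  Barrier noise
    is drawn once per environment from ``default_rng(seed)`` in spec
    order, so identical specs produce byte-identical trees.  Returns the
    loaded series and the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    env_entries = []
    for target in spec.environments:
        record = generate_record(
            target.label,
            target.target_dcat,
            target.target_qcat,
            target.barrier,
            role=target.role,
            charge_params=spec.charge_params,
            n_padding_atoms=spec.n_padding_atoms,
        )
        barrier = target.barrier
        if barrier is not None and spec.barrier_sigma > 0:
            barrier = barrier + rng.normal(0.0, spec.barrier_sigma)
        stem = f"env_{target.label}"
        write_xyz(record.rc.geometry, outdir / f"{stem}_rc.xyz")
        write_xyz(record.ts.geometry, outdir / f"{stem}_ts.xyz")
        write_xyz(record.pc.geometry, outdir / f"{stem}_pc.xyz")
        write_charge_table(record.rc.charges, outdir / f"{stem}_rc_charges.csv")
        write_charge_table(record.ts.charges, outdir / f"{stem}_ts_charges.csv")
        entry = {
            "label": target.label,
            "rc_xyz": f"{stem}_rc.xyz",
            "ts_xyz": f"{stem}_ts.xyz",
            "pc_xyz": f"{stem}_pc.xyz",
            "rc_charges": f"{stem}_rc_charges.csv",
            "ts_charges": f"{stem}_ts_charges.csv",
            "o1": 1,
            "c1": 2,
            "cl1": 3,
            "nucleophile_indices": [1],
            "role": target.role,
            "descriptors": sorted(record.descriptors),
        }
        if barrier is not None:
            entry["barrier_kcal_mol"] = round(float(barrier), 9)
        env_entries.append(entry)

    config = {"barrier_kind": spec.barrier_kind, "environments": env_entries}
    config_path = outdir / "series.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return load_series(config_path), config_path


def enzyme_demo_spec(seed: int = 0, barrier_sigma: float = 0.0) -> SeriesSpec:
    """A ready-made active-site truncation series.

    Five environments: the acetate + dichloroethane SN2 step surrounded by
    three, two, one, or zero aromatic residues, plus bulk water as a
    held-out prediction target.  Descriptor targets and free-energy
    barriers follow the published values for this system; the
    zero-residue environment contributes charge-transfer data only, its
    TS bond lengths being unavailable.
    """
    envs = [
        EnvironmentTarget("3", barrier=15.4, target_dcat=0.43, target_qcat=0.21),
        EnvironmentTarget("2", barrier=17.1, target_dcat=0.30, target_qcat=0.17),
        EnvironmentTarget("1", barrier=19.3, target_dcat=0.04, target_qcat=0.09),
        EnvironmentTarget("0", barrier=24.3, target_dcat=None, target_qcat=0.05),
        EnvironmentTarget(
            "water", barrier=None, target_dcat=-0.10, target_qcat=0.04,
            role="predict",
        ),
    ]
    return SeriesSpec(environments=envs, seed=seed, barrier_sigma=barrier_sigma)
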