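"""The two reactive descriptors for SN2 catalytic power.

``Dcat`` is the distance-difference descriptor: the length of the breaking
C1–Cl1 bond minus the length of the forming O1–C1 bond, both measured at
the transition state.  A larger Dcat means a "later", more product-like
transition state and higher reactivity.

``Qcat`` is the charge-transfer descriptor: the summed signed partial
charge of the nucleophile group at the transition state minus the same sum
at the reactant complex.  A larger Qcat means more negative charge has
already flowed from the nucleophile toward the leaving group at the TS,
again indicating higher reactivity.

Both descriptors decrease the activation barrier linearly across a series
of active-site environments, which is what the :mod:`catdesc.scaling`
module fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .structures import (
    ChargeTable,
    ChargeTableError,
    EnvironmentSeries,
    ReactionRecord,
    bond_length,
)

__all__ = [
    "DescriptorRow",
    "DescriptorError",
    "OrderingReport",
    "compute_dcat",
    "group_charge",
    "compute_qcat",
    "descriptor_table",
    "reactivity_order",
    "format_descriptor_table",
]


class DescriptorError(ValueError):
    """A descriptor could not be computed from the given record."""


@dataclass
class DescriptorRow:
    """One environment's descriptor values and barrier.

    dcat in Å, qcat in e, barrier in kcal/mol.  Either descriptor may be
    absent (None) for a given environment, but not both.
    """

    label: str
    dcat: float | None
    qcat: float | None
    barrier: float | None
    role: str = "fit"

    def __post_init__(self) -> None:
        if self.dcat is None and self.qcat is None:
            raise DescriptorError(
                f"environment {self.label!r}: at least one of dcat/qcat required"
            )
        if self.barrier is not None and not math.isfinite(self.barrier):
            raise DescriptorError(
                f"environment {self.label!r}: non-finite barrier {self.barrier}"
            )


def compute_dcat(record: ReactionRecord) -> float:
    """Distance descriptor: d(C1–Cl1) − d(O1–C1) at the transition state, Å.

    Both distances are transition-state internal quantities; the RC and PC
    geometries play no part.
    """
    if record.ts is None:
        raise DescriptorError(
            f"environment {record.label!r}: no TS geometry, cannot compute Dcat"
        )
    geom = record.ts.geometry
    try:
        d_leaving = bond_length(geom, *record.leaving_bond)
        d_forming = bond_length(geom, *record.forming_bond)
    except IndexError as exc:
        raise DescriptorError(f"environment {record.label!r}: {exc}") from exc
    return d_leaving - d_forming


def group_charge(charges: ChargeTable, selection: frozenset[int] | set[int]) -> float:
    """Sum of signed atomic charges over a selection of 1-based indices, in e."""
    if not selection:
        raise DescriptorError("empty atom selection for group charge")
    total = 0.0
    for idx in sorted(selection):
        total += charges.charge(idx)  # raises naming the missing index
    return total


def compute_qcat(record: ReactionRecord) -> float:
    """Charge-transfer descriptor: nucleophile group charge at TS minus RC, e."""
    if record.ts is None or record.ts.charges is None:
        raise DescriptorError(
            f"environment {record.label!r}: no TS charge table, cannot compute Qcat"
        )
    if record.rc is None or record.rc.charges is None:
        raise DescriptorError(
            f"environment {record.label!r}: no RC charge table, cannot compute Qcat"
        )
    try:
        q_ts = group_charge(record.ts.charges, record.nucleophile_selection)
        q_rc = group_charge(record.rc.charges, record.nucleophile_selection)
    except ChargeTableError as exc:
        raise DescriptorError(f"environment {record.label!r}: {exc}") from exc
    return q_ts - q_rc


def descriptor_table(series: EnvironmentSeries) -> list[DescriptorRow]:
    """Compute one DescriptorRow per environment, preserving series order.

    Each record declares which descriptors it supports; a descriptor that
    the record does not request is reported as None rather than an error.
    Failures inside a requested descriptor propagate with the environment
    label attached.
    """
    if len(series) == 0:
        raise DescriptorError("descriptor table requires >= 1 record")
    rows = []
    for record in series:
        dcat = compute_dcat(record) if "dcat" in record.descriptors else None
        qcat = compute_qcat(record) if "qcat" in record.descriptors else None
        rows.append(
            DescriptorRow(
                label=record.label,
                dcat=dcat,
                qcat=qcat,
                barrier=record.barrier,
                role=record.role,
            )
        )
    return rows


@dataclass
class OrderingReport:
    """Reactivity ordering by one descriptor.

    ``labels`` are sorted by descending descriptor value (most reactive
    first).  ``monotone`` is True iff the barrier strictly increases as
    the descriptor decreases along that order — the signature of a
    well-behaved descriptor–barrier relationship.  Tied descriptor values
    are reported in ``ties`` rather than silently ordered.
    """

    descriptor: str
    labels: list[str]
    values: list[float]
    barriers: list[float | None]
    monotone: bool
    ties: list[tuple[str, str]]


def reactivity_order(rows: list[DescriptorRow], descriptor: str) -> OrderingReport:
    """Order environments by descending descriptor and check barrier monotonicity."""
    if descriptor not in ("dcat", "qcat"):
        raise ValueError(f"descriptor must be 'dcat' or 'qcat', got {descriptor!r}")
    usable = [r for r in rows if getattr(r, descriptor) is not None]
    if len(usable) < 2:
        raise DescriptorError(
            f"reactivity ordering needs >= 2 rows with {descriptor}, got {len(usable)}"
        )
    ordered = sorted(usable, key=lambda r: -getattr(r, descriptor))
    values = [getattr(r, descriptor) for r in ordered]
    barriers = [r.barrier for r in ordered]
    ties = [
        (ordered[i].label, ordered[i + 1].label)
        for i in range(len(ordered) - 1)
        if values[i] == values[i + 1]
    ]
    monotone = not ties and all(
        b1 is not None and b2 is not None and b2 > b1
        for b1, b2 in zip(barriers, barriers[1:])
    )
    return OrderingReport(
        descriptor=descriptor,
        labels=[r.label for r in ordered],
        values=values,
        barriers=barriers,
        monotone=monotone,
        ties=ties,
    )


def format_descriptor_table(rows: list[DescriptorRow]) -> str:
    """Render rows as TSV with 2-decimal descriptor presentation.

    Descriptors are computed and stored at full precision; only this
    report layer rounds.
    """
    out = ["label\tdcat_angstrom\tqcat_e\tbarrier_kcal_mol\trole"]
    for r in rows:
        dcat = "" if r.dcat is None else f"{r.dcat:.2f}"
        qcat = "" if r.qcat is None else f"{r.qcat:.2f}"
        barrier = "" if r.barrier is None else f"{r.barrier:.1f}"
        out.append(f"{r.label}\t{dcat}\t{qcat}\t{barrier}\t{r.role}")
    return "\n".join(out) + "\n"
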