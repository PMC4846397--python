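"""Envelope volume, Matthews coefficient and solvent-cavity fraction.

A negative-stain EM envelope of monomeric huntingtin is roughly a
sphere of 115 Å diameter (130 Å × 100 Å at its extremes). Dividing the
measured outer volume by the molecular weight gives a Matthews
coefficient V_M (Å³/Da); comparing it with the volume-per-dalton of
packed protein alone (V_M = 1.23 Å³/Da) bounds the solvent cavity
fraction: cavity = 1 − V_M(protein)/V_M(observed).

The measured outer volume is always accepted as a direct input — a
stated envelope volume is the measurement of record and is never
silently recomputed from nominal dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "VM_PROTEIN",
    "GeometryModel",
    "envelope_volume",
    "matthews_coefficient",
    "cavity_fraction",
    "cavity_percent",
    "geometry_report",
]

#: Volume per dalton of packed protein with no solvent, Å³/Da.
VM_PROTEIN = 1.23


def envelope_volume(shape: str, dimensions: float | Sequence[float]) -> float:
    """Closed-form envelope volume in Å³.

    ``sphere`` takes one diameter; ``ellipsoid`` takes the three axis
    lengths (full axes, not semi-axes): V = (π/6)·a·b·c.
    """
    if shape == "sphere":
        if isinstance(dimensions, (int, float)):
            dims = [float(dimensions)]
        else:
            dims = [float(d) for d in dimensions]
        if len(dims) != 1:
            raise ValueError("sphere takes a single diameter")
        (d,) = dims
        if d <= 0:
            raise ValueError("diameter must be positive")
        return math.pi / 6.0 * d**3
    if shape == "ellipsoid":
        dims = [float(d) for d in dimensions]
        if len(dims) != 3:
            raise ValueError("ellipsoid takes three axis lengths")
        if any(d <= 0 for d in dims):
            raise ValueError("axis lengths must be positive")
        a, b, c = dims
        return math.pi / 6.0 * a * b * c
    raise ValueError(f"unknown shape {shape!r}; expected 'sphere' or 'ellipsoid'")


def matthews_coefficient(outer_volume: float, molecular_weight: float) -> float:
    """V_M = outer volume (Å³) / molecular weight (Da), in Å³/Da."""
    if outer_volume <= 0 or molecular_weight <= 0:
        raise ValueError("volume and molecular weight must be positive")
    return outer_volume / molecular_weight


def cavity_fraction(vm_observed: float, vm_protein: float = VM_PROTEIN) -> float:
    """Solvent-cavity volume fraction 1 − vm_protein/vm_observed.

    Strictly increasing in ``vm_observed`` and always < 1. A V_M below
    the protein-only value implies no cavity and is rejected.
    """
    if vm_protein <= 0:
        raise ValueError("protein V_M must be positive")
    if vm_observed < vm_protein:
        raise ValueError(
            f"observed V_M {vm_observed} below protein-only V_M {vm_protein}: "
            "no cavity implied"
        )
    return 1.0 - vm_protein / vm_observed


def cavity_percent(vm_observed: float, vm_protein: float = VM_PROTEIN) -> int:
    """Cavity fraction as an integer percent, rounding half up."""
    frac = cavity_fraction(vm_observed, vm_protein)
    return int(math.floor(100.0 * frac + 0.5))


@dataclass(frozen=True)
class GeometryModel:
    """One particle-envelope geometry summary."""

    shape: str
    dimensions: tuple[float, ...]
    outer_volume: float
    molecular_weight: float
    vm_observed: float
    vm_protein: float
    cavity_fraction: float

    def as_dict(self) -> dict:
        return {
            "shape": self.shape,
            "dimensions_A": list(self.dimensions),
            "outer_volume_A3": self.outer_volume,
            "molecular_weight_Da": self.molecular_weight,
            "vm_observed_A3_per_Da": round(self.vm_observed, 4),
            "vm_protein_A3_per_Da": self.vm_protein,
            "cavity_fraction": round(self.cavity_fraction, 4),
            "cavity_percent": cavity_percent(self.vm_observed, self.vm_protein),
        }


def geometry_report(
    molecular_weight: float,
    shape: str = "sphere",
    dimensions: float | Sequence[float] = 115.0,
    outer_volume: float | None = None,
    vm_protein: float = VM_PROTEIN,
) -> GeometryModel:
    """Full geometry block for one particle.

    If ``outer_volume`` is given it is used as-is (the measured value
    takes precedence over the nominal shape); otherwise it is computed
    from the shape by :func:`envelope_volume`.
    """
    if outer_volume is None:
        outer_volume = envelope_volume(shape, dimensions)
    vm = matthews_coefficient(outer_volume, molecular_weight)
    if isinstance(dimensions, (int, float)):
        dims = (float(dimensions),)
    else:
        dims = tuple(float(d) for d in dimensions)
    return GeometryModel(
        shape=shape,
        dimensions=dims,
        outer_volume=float(outer_volume),
        molecular_weight=float(molecular_weight),
        vm_observed=vm,
        vm_protein=vm_protein,
        cavity_fraction=cavity_fraction(vm, vm_protein),
    )
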