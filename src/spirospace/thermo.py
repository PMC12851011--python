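"""Reaction free-energy bookkeeping from externally computed free energies.

The quantum-chemistry calculation itself (e.g. an M06-2X/Def2-SVP run with an
implicit-solvent model) happens out of process; this module only audits and
converts.  Species carry Gibbs energies in hartree with method/basis/solvent
provenance, and a reaction balance converts the products-minus-reactants
difference to kcal/mol (× 627.5095).  A positive ΔG is endergonic — the sign
convention under which a thermodynamically unfavorable α-elimination of a
sulfonium ylide into a carbene and a sulfide shows up as ΔG > 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HARTREE_TO_KCAL = 627.5095

__all__ = ["ThermoSpecies", "ReactionFreeEnergy", "ThermoError",
           "reaction_free_energy", "parse_energy_table", "write_energy_table"]


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class ThermoSpecies:
    """One species with its Gibbs free energy (hartree) and provenance."""

    label: str
    gibbs_hartree: float
    method: str = ""
    basis: str = ""
    solvent: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.gibbs_hartree):
            raise ThermoError(f"{self.label}: non-finite energy")
        if not (self.method or self.basis):
            raise ThermoError(f"{self.label}: provenance (method/basis) must be recorded")


@dataclass
class ReactionFreeEnergy:
    """A balanced reaction with its free-energy change in kcal/mol."""

    reactants: list[ThermoSpecies]
    products: list[ThermoSpecies]
    delta_g_kcal: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ThermoError("both reaction sides must be non-empty")
        dg_hartree = sum(s.gibbs_hartree for s in self.products) - sum(
            s.gibbs_hartree for s in self.reactants
        )
        self.delta_g_kcal = float(dg_hartree * HARTREE_TO_KCAL)

    def to_dict(self) -> dict:
        return {
            "reactants": [s.label for s in self.reactants],
            "products": [s.label for s in self.products],
            "delta_g_kcal_per_mol": self.delta_g_kcal,
        }


def reaction_free_energy(
    reactants: list[ThermoSpecies], products: list[ThermoSpecies]
) -> ReactionFreeEnergy:
    """ΔG (kcal/mol) = (Σ products − Σ reactants) × 627.5095; positive = endergonic."""
    return ReactionFreeEnergy(reactants=list(reactants), products=list(products))


def parse_energy_table(path: str | Path) -> list[ThermoSpecies]:
    """Read species from CSV columns ``label, gibbs_hartree, method, basis, solvent``."""
    path = Path(path)
    species: list[ThermoSpecies] = []
    seen: set[str] = set()
    with path.open() as fh:
        reader = csv.DictReader(fh)
        required = {"label", "gibbs_hartree"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ThermoError(f"{path.name}: header must contain {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label in seen:
                raise ThermoError(f"{path.name}:{rownum}: duplicate label {label!r}")
            seen.add(label)
            try:
                energy = float(row["gibbs_hartree"])
            except ValueError as exc:
                raise ThermoError(
                    f"{path.name}:{rownum}: non-numeric energy {row['gibbs_hartree']!r}"
                ) from exc
            species.append(
                ThermoSpecies(
                    label=label,
                    gibbs_hartree=energy,
                    method=(row.get("method") or "").strip(),
                    basis=(row.get("basis") or "").strip(),
                    solvent=(row.get("solvent") or "").strip(),
                )
            )
    return species


def write_energy_table(species: list[ThermoSpecies], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "gibbs_hartree", "method", "basis", "solvent"])
        for s in species:
            writer.writerow([s.label, f"{s.gibbs_hartree:.12f}", s.method, s.basis, s.solvent])
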