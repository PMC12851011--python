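"""3D conformer generation and import.

Two routes produce the single conformer each scaffold contributes to the
descriptor table:

* :func:`embed_and_optimize` — deterministic best-of-n distance-geometry
  embedding followed by force-field minimization (MMFF94, UFF fallback) with
  Gasteiger partial charges.  This is the self-contained route.
* :func:`import_xc_geometry` — read an externally optimized geometry (e.g.
  from a DFT run) from an XYZ file, never re-minimized, with electronic /
  Gibbs energies stored untouched in hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .library import ScaffoldRecord

__all__ = ["Conformer3D", "GeometryError", "embed_and_optimize", "import_xc_geometry", "write_xyz"]

_PERIODIC_TABLE = Chem.GetPeriodicTable()


class GeometryError(ValueError):
    """Embedding failures, malformed XYZ files, unsupported species."""


@dataclass
class Conformer3D:
    """One 3D structure: elements, Cartesian coordinates (Å), partial charges (e)."""

    scaffold_id: str
    symbols: list[str]
    coords: np.ndarray  # N x 3, Å
    charges: np.ndarray  # N, elementary charges
    provenance: str  # "forcefield" or "imported_qc"
    energy: float | None = None
    energy_unit: str = "kcal/mol"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.symbols)
        if self.coords.shape != (n, 3) or self.charges.shape != (n,):
            raise GeometryError(
                f"{self.scaffold_id}: inconsistent sizes "
                f"(symbols {n}, coords {self.coords.shape}, charges {self.charges.shape})"
            )
        if n >= 2:
            d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.5:
                raise GeometryError(f"{self.scaffold_id}: atoms closer than 0.5 Å")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def heavy_mask(self) -> np.ndarray:
        return np.array([s != "H" for s in self.symbols])


def _ff_for(mol: Chem.Mol, conf_id: int):
    """MMFF94 force field when parametrized, else UFF."""
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is not None:
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)
        if ff is not None:
            return ff, "MMFF94"
    return AllChem.UFFGetMoleculeForceField(mol, confId=conf_id), "UFF"


def embed_and_optimize(
    record: ScaffoldRecord, n_starts: int = 10, seed: int = 2025
) -> Conformer3D:
    """Best-of-``n_starts`` embed-and-minimize conformer for one scaffold.

    Each start uses the ETKDG distance-geometry embedder with seed
    ``seed + i`` and is locally minimized with MMFF94 (UFF when MMFF has no
    parameters).  The lowest-energy minimized conformer is returned, so the
    result is deterministic for fixed ``(record, n_starts, seed)`` and its
    energy is non-increasing in ``n_starts``.
    """
    if n_starts < 1:
        raise GeometryError("n_starts must be >= 1")
    mol = Chem.AddHs(record.mol())
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons():
            raise GeometryError(f"{record.id}: radicals are not supported")

    best: tuple[float, np.ndarray, str] | None = None
    params = AllChem.ETKDGv3()
    for i in range(n_starts):
        params.randomSeed = int(seed) + i
        work = Chem.Mol(mol)
        if AllChem.EmbedMolecule(work, params) != 0:
            continue
        ff, ff_name = _ff_for(work, 0)
        ff.Minimize(maxIts=2000)
        energy = float(ff.CalcEnergy())
        if best is None or energy < best[0] - 1e-12:
            best = (energy, np.array(work.GetConformer().GetPositions()), ff_name)
    if best is None:
        raise GeometryError(f"{record.id}: embedding failed after {n_starts} starts")
    energy, coords, ff_name = best

    charged = Chem.AddHs(record.mol())
    Chem.rdPartialCharges.ComputeGasteigerCharges(charged)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in charged.GetAtoms()])
    if not np.all(np.isfinite(charges)):
        raise GeometryError(f"{record.id}: Gasteiger charges undefined")

    return Conformer3D(
        scaffold_id=record.id,
        symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        charges=charges,
        provenance="forcefield",
        energy=energy,
        energy_unit="kcal/mol",
        seed=int(seed),
        meta={"forcefield": ff_name, "charge_model": "gasteiger", "n_starts": n_starts},
    )


def import_xc_geometry(
    xyz_path: str | Path,
    scaffold_id: str | None = None,
    electronic_hartree: float | None = None,
    gibbs_hartree: float | None = None,
    charges: np.ndarray | None = None,
) -> Conformer3D:
    """Read an externally optimized geometry from a standard XYZ file.

    The first line is the atom count, the second a free-form comment; each
    subsequent line is ``symbol x y z`` in Å.  Coordinates are preserved
    exactly and never re-minimized.  Energies (hartree) are stored untouched.
    Charges default to zero unless supplied (e.g. from a QC population
    analysis); dipoles computed from zero charges are meaningless, so pass
    them when you need electrostatics from an imported geometry.
    """
    path = Path(xyz_path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise GeometryError(f"{path.name}: not a valid XYZ file")
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path.name}: bad atom-count header") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n_declared:
        raise GeometryError(
            f"{path.name}: header declares {n_declared} atoms but {len(body)} listed"
        )
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path.name}: malformed atom line {ln!r}")
        sym = parts[0]
        try:
            if _PERIODIC_TABLE.GetAtomicNumber(sym) == 0:
                raise ValueError
        except Exception:
            raise GeometryError(f"{path.name}: unknown element {sym!r}") from None
        symbols.append(sym)
        coords.append([float(x) for x in parts[1:4]])
    coords_arr = np.array(coords)
    meta: dict = {"source": str(path)}
    if electronic_hartree is not None:
        meta["electronic_hartree"] = float(electronic_hartree)
    if gibbs_hartree is not None:
        meta["gibbs_hartree"] = float(gibbs_hartree)
    return Conformer3D(
        scaffold_id=scaffold_id or path.stem,
        symbols=symbols,
        coords=coords_arr,
        charges=np.zeros(len(symbols)) if charges is None else np.asarray(charges, float),
        provenance="imported_qc",
        energy=gibbs_hartree if gibbs_hartree is not None else electronic_hartree,
        energy_unit="hartree",
        meta=meta,
    )


def write_xyz(conf: Conformer3D, path: str | Path, comment: str = "") -> None:
    """Write a conformer as standard XYZ at fixed 6-decimal precision."""
    lines = [str(conf.n_atoms), comment or conf.scaffold_id]
    for sym, (x, y, z) in zip(conf.symbols, conf.coords):
        lines.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
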