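"""Molecular descriptors: the 1D/2D/3D vector each scaffold contributes.

The registry is fixed and versioned.  1D and 2D descriptors come straight from
RDKit (molecular weight, Crippen logP, TPSA, QED as the desirability-style
drug-likeness score, ...).  The 3D descriptors — plane of best fit,
asphericity, point-charge dipole, grid van-der-Waals volume and a ring-strain
proxy — are computed here from the conformer, since their exact conventions
matter for the downstream chemical-space distances:

* **PBF** (Å): mean absolute distance of the heavy atoms from their
  least-squares plane; 0 for planar systems and, by convention, for any
  molecule with ≤ 3 heavy atoms.
* **asphericity** (dimensionless): from the gyration-tensor eigenvalues
  λ1 ≥ λ2 ≥ λ3 of the unweighted coordinates,
  A = [(λ1−λ2)² + (λ1−λ3)² + (λ2−λ3)²] / [2 (λ1+λ2+λ3)²];
  0 for spherically symmetric distributions, 1 for collinear ones.
* **dipole** (Debye): |Σ qᵢ rᵢ| with q in e and r in Å, scaled by
  4.80320 D/(e·Å).  Origin-dependent (hence flagged) for net-charged species.
* **volume** (Å³): grid count of points inside the union of Bondi
  van-der-Waals spheres.
* **strain energy** (kcal/mol): either an externally supplied quantum-chemistry
  difference, or a self-contained force-field proxy (ring vs. hydrogen-capped
  ring-opened analogue), always flagged with its mode.
"""

from __future__ import annotations

import hashlib

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, QED, rdMolDescriptors

from .geometry import Conformer3D, GeometryError, _ff_for
from .library import ScaffoldRecord

__all__ = [
    "DescriptorVector",
    "DESCRIPTOR_REGISTRY",
    "registry_hash",
    "compute_descriptor_vector",
    "plane_of_best_fit",
    "asphericity",
    "dipole_moment",
    "molecular_volume",
    "strain_energy",
    "EA_TO_DEBYE",
    "HARTREE_TO_KCAL",
    "BONDI_RADII",
]

#: Conversion of a charge–distance product e·Å to Debye.
EA_TO_DEBYE = 4.80320
#: Hartree to kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Bondi van-der-Waals radii (Å) for the elements the library covers.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

#: name -> (unit, dimensionality category)
DESCRIPTOR_REGISTRY: dict[str, tuple[str, str]] = {
    "mol_weight": ("g/mol", "1D"),
    "n_heteroatoms": ("count", "1D"),
    "n_heavy_atoms": ("count", "1D"),
    "logp": ("", "2D"),
    "tpsa": ("A^2", "2D"),
    "hbd": ("count", "2D"),
    "hba": ("count", "2D"),
    "rotatable_bonds": ("count", "2D"),
    "fraction_sp3": ("", "2D"),
    "ring_count": ("count", "2D"),
    "qed": ("", "2D"),
    "dipole": ("D", "3D"),
    "pbf": ("A", "3D"),
    "asphericity": ("", "3D"),
    "volume": ("A^3", "3D"),
    "strain_energy": ("kcal/mol", "3D"),
}


def registry_hash() -> str:
    """Stable fingerprint of the descriptor registry, recorded in run manifests."""
    text = ";".join(f"{k}:{u}:{c}" for k, (u, c) in sorted(DESCRIPTOR_REGISTRY.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class DescriptorError(ValueError):
    pass


class DescriptorVector:
    """Named descriptor values for one scaffold, with units and 1D/2D/3D categories."""

    def __init__(self, scaffold_id: str, values: dict[str, float]):
        missing = set(DESCRIPTOR_REGISTRY) - set(values)
        extra = set(values) - set(DESCRIPTOR_REGISTRY)
        if missing or extra:
            raise DescriptorError(
                f"{scaffold_id}: registry mismatch (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        if bad:
            raise DescriptorError(f"{scaffold_id}: non-finite descriptors {bad}")
        self.scaffold_id = scaffold_id
        self.values = {k: float(values[k]) for k in DESCRIPTOR_REGISTRY}
        self.units = {k: u for k, (u, _) in DESCRIPTOR_REGISTRY.items()}
        self.categories = {k: c for k, (_, c) in DESCRIPTOR_REGISTRY.items()}

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------------------
# 3D descriptors
# ---------------------------------------------------------------------------

def plane_of_best_fit(coords: np.ndarray) -> float:
    """Mean absolute distance (Å) of points from their least-squares plane.

    The plane passes through the centroid with normal along the eigenvector of
    the smallest eigenvalue of the coordinate covariance.  Any set of ≤ 3
    points is exactly planar, so the value is defined as 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise DescriptorError("coords must be an N x 3 array with N >= 1")
    n = coords.shape[0]
    if n <= 3:
        return 0.0
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest eigenvalue
    return float(np.abs(centered @ normal).mean())


def asphericity(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Gyration-tensor asphericity in [0, 1]; unweighted coordinates by default."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise DescriptorError("asphericity requires at least one point")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise DescriptorError("coords must be N x 3")
    w = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    centered = coords - center
    gyr = (w[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(axis=0)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    total = lam.sum()
    if total <= 0:  # all points coincident: isotropic by convention
        return 0.0
    num = (lam[0] - lam[1]) ** 2 + (lam[0] - lam[2]) ** 2 + (lam[1] - lam[2]) ** 2
    return float(num / (2.0 * total**2))


def dipole_moment(conf: Conformer3D) -> float:
    """Point-charge dipole magnitude in Debye from the conformer's charges."""
    if conf.charges is None or conf.charges.size == 0:
        raise DescriptorError(f"{conf.scaffold_id}: charges missing")
    net = conf.charges.sum()
    if abs(net) > 1e-6:
        import warnings

        warnings.warn(
            f"{conf.scaffold_id}: net charge {net:.3f} e — dipole is origin-dependent",
            stacklevel=2,
        )
    mu = (conf.charges[:, None] * conf.coords).sum(axis=0)
    return float(np.linalg.norm(mu) * EA_TO_DEBYE)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Center on the centroid and rotate into the principal axes of the coordinates.

    Axis signs are fixed by the largest-magnitude projection (ties by atom
    index), so the result — and anything computed on a grid over it — is
    independent of the molecule's input orientation.
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) == 1:
        return centered
    _, vecs = np.linalg.eigh(centered.T @ centered)
    proj = centered @ vecs
    for j in range(3):
        k = int(np.argmax(np.abs(proj[:, j])))
        if proj[k, j] < 0:
            proj[:, j] = -proj[:, j]
    return proj


def molecular_volume(conf: Conformer3D, grid_spacing: float = 0.2) -> float:
    """Van-der-Waals volume (Å³) by counting grid points inside any Bondi sphere.

    The grid is laid over the canonical principal-axes frame, so the value does
    not depend on how the conformer happens to be oriented.
    """
    return union_volume(conf.symbols, conf.coords, grid_spacing)


def union_volume(symbols: list[str], raw_coords: np.ndarray, grid_spacing: float = 0.2) -> float:
    """Grid union-of-spheres volume for an arbitrary symbol/coordinate set."""
    if grid_spacing <= 0:
        raise DescriptorError("grid_spacing must be positive")
    radii = np.array([BONDI_RADII.get(s, 1.70) for s in symbols])
    coords = _canonical_frame(np.asarray(raw_coords, float))
    pad = radii.max() + 2.0 * grid_spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside = np.zeros(len(pts), dtype=bool)
    for center, r in zip(coords, radii):
        # cheap bounding-box pre-filter keeps the distance test small
        box = np.all(np.abs(pts - center) <= r, axis=1)
        idx = np.flatnonzero(box & ~inside)
        if idx.size:
            d2 = ((pts[idx] - center) ** 2).sum(axis=1)
            inside[idx[d2 <= r * r]] = True
    return float(inside.sum() * grid_spacing**3)


# ---------------------------------------------------------------------------
# Strain energy
# ---------------------------------------------------------------------------

def _ring_opened_analogue(mol: Chem.Mol) -> Chem.Mol:
    """Hydrogen-capped acyclic analogue: cleave one bond per ring until acyclic.

    Bond-selection rule, applied after kekulization: among bonds still in a
    ring, prefer single bonds, then carbon–carbon bonds, then the pair with the
    lowest atom indices.  Valences are refilled with implicit hydrogens.
    """
    work = Chem.RWMol(mol)
    while True:
        ring_info = work.GetRingInfo()
        if ring_info.NumRings() == 0:
            break
        # kekulize each pass: sanitization after a cleavage re-perceives
        # aromaticity for the rings that remain
        Chem.Kekulize(work, clearAromaticFlags=True)
        candidates = []
        for bond in work.GetBonds():
            if not bond.IsInRing():
                continue
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            is_single = bond.GetBondType() == Chem.BondType.SINGLE
            both_c = a.GetAtomicNum() == 6 and b.GetAtomicNum() == 6
            key = (not is_single, not both_c, min(a.GetIdx(), b.GetIdx()), max(a.GetIdx(), b.GetIdx()))
            candidates.append((key, bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        candidates.sort()
        _, ai, bi = candidates[0]
        work.RemoveBond(ai, bi)
        for idx in (ai, bi):
            atom = work.GetAtomWithIdx(idx)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        Chem.SanitizeMol(work)
    return work.GetMol()


def _ff_energy_of_smiles_mol(mol: Chem.Mol, n_starts: int, seed: int) -> float:
    """Best-of-n embedded, minimized force-field energy of a molecule (kcal/mol)."""
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    best = None
    for i in range(n_starts):
        params.randomSeed = int(seed) + i
        work = Chem.Mol(molh)
        if AllChem.EmbedMolecule(work, params) != 0:
            continue
        ff, _ = _ff_for(work, 0)
        ff.Minimize(maxIts=2000)
        e = float(ff.CalcEnergy())
        if best is None or e < best - 1e-12:
            best = e
    if best is None:
        raise GeometryError("embedding failed for ring-opened analogue")
    return best


def strain_energy(
    record: ScaffoldRecord,
    conf: Conformer3D | None = None,
    mode: str = "ff_proxy",
    qc_energies: tuple[float, float] | None = None,
    n_starts: int = 10,
    seed: int = 2025,
) -> float:
    """Ring-strain estimate in kcal/mol.

    ``mode='external_qc'`` converts a supplied ``(E_cyclic, E_reference)``
    hartree pair: ΔE = (E_cyclic − E_reference) × 627.5095.  ``mode='ff_proxy'``
    is the self-contained route: force-field energy of the ring system minus
    that of its hydrogen-capped ring-opened analogue (one bond cleaved per
    ring).  The proxy tracks strain ordering (three-membered ≫ six-membered)
    but is not a thermochemical strain energy; reports flag it as "proxy".
    """
    if mode == "external_qc":
        if qc_energies is None:
            raise DescriptorError("external_qc mode requires (E_cyclic, E_reference) in hartree")
        e_cyc, e_ref = qc_energies
        return float((e_cyc - e_ref) * HARTREE_TO_KCAL)
    if mode != "ff_proxy":
        raise DescriptorError(f"unknown strain mode {mode!r}")
    mol = record.mol()
    if mol.GetRingInfo().NumRings() == 0:
        return 0.0
    opened = _ring_opened_analogue(mol)
    e_cyclic = (
        conf.energy
        if conf is not None and conf.provenance == "forcefield" and conf.energy is not None
        else _ff_energy_of_smiles_mol(mol, n_starts, seed)
    )
    e_open = _ff_energy_of_smiles_mol(opened, n_starts, seed)
    return float(e_cyclic - e_open)


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def compute_descriptor_vector(
    record: ScaffoldRecord,
    conf: Conformer3D,
    grid_spacing: float = 0.2,
    strain_mode: str = "ff_proxy",
    strain_qc_energies: tuple[float, float] | None = None,
) -> DescriptorVector:
    """Compute the full fixed-registry descriptor vector for one scaffold."""
    if conf.scaffold_id != record.id:
        raise DescriptorError(
            f"conformer {conf.scaffold_id!r} does not belong to record {record.id!r}"
        )
    mol = record.mol()
    heavy = conf.coords[conf.heavy_mask()]
    values = {
        "mol_weight": Descriptors.MolWt(mol),
        "n_heteroatoms": float(rdMolDescriptors.CalcNumHeteroatoms(mol)),
        "n_heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "logp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hbd": float(rdMolDescriptors.CalcNumHBD(mol)),
        "hba": float(rdMolDescriptors.CalcNumHBA(mol)),
        "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "fraction_sp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "ring_count": float(rdMolDescriptors.CalcNumRings(mol)),
        "qed": QED.qed(mol),
        "dipole": dipole_moment(conf),
        "pbf": plane_of_best_fit(heavy),
        "asphericity": asphericity(conf.coords),
        "volume": molecular_volume(conf, grid_spacing),
        "strain_energy": strain_energy(
            record, conf, mode=strain_mode, qc_energies=strain_qc_energies
        ),
    }
    return DescriptorVector(record.id, values)
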