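"""Relative solvent accessibility from PDB coordinates.

Shrake-Rupley solvent-accessible surface area: a deterministic
golden-spiral point cloud is placed on each atom's solvent-expanded sphere
(van der Waals radius + probe radius) and a point counts as exposed iff it
lies outside every other atom's expanded sphere. Per-residue SASA is the
sum over member atoms, normalized by per-residue-type maximum ASA to give
RSA. RSA is not clipped; values slightly above 1 are preserved.

Hydrogens are ignored; alternate locations keep the highest-occupancy
conformer; HETATM records are skipped unless an alias (e.g. MSE -> MET)
maps them onto a standard residue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from predstack.errors import NormalizationError, RadiusTableError
from predstack.formats_io import SiteRecord

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960

#: Residue aliases applied when reading HETATM records.
DEFAULT_HETATM_ALIASES: dict[str, str] = {"MSE": "MET"}

ResidueId = tuple[str, int, str]  # (chain, residue number, insertion code)


@dataclass
class AtomRecord:
    residue_id: ResidueId
    residue_name: str
    element: str
    position: np.ndarray  # (3,) in Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bad coordinates for atom in {self.residue_id}")


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("predstack.data").joinpath(name).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


def load_vdw_radii() -> dict[str, float]:
    """Per-element van der Waals radii (Angstrom), shipped as package data."""
    return _load_table("vdw_radii.tsv")


def load_max_asa() -> dict[str, float]:
    """Per-residue maximum ASA normalization constants (Angstrom^2)."""
    return _load_table("max_asa.tsv")


def load_pdb_atoms(
    path: str | Path,
    hetatm_aliases: Mapping[str, str] | None = None,
    ignore_hydrogens: bool = True,
    model_index: int = 0,
) -> list[AtomRecord]:
    """Read heavy atoms from a PDB file via Biopython.

    Disordered atoms keep the highest-occupancy conformer. HETATM residues
    are skipped unless named in hetatm_aliases, in which case the alias
    residue name is recorded.
    """
    from Bio.PDB import PDBParser

    if hetatm_aliases is None:
        hetatm_aliases = DEFAULT_HETATM_ALIASES
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate nonstandard records
        structure = PDBParser(QUIET=True).get_structure("structure", str(path))
    model = list(structure.get_models())[model_index]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if hetflag.strip():
                if resname in hetatm_aliases:
                    resname = hetatm_aliases[resname]
                else:
                    continue
            residue_id = (chain.id, int(resseq), icode.strip())
            for atom in residue:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                element = (atom.element or "").strip().upper()
                if ignore_hydrogens and element in ("H", "D"):
                    continue
                atoms.append(AtomRecord(residue_id, resname, element, atom.get_coord()))
    return atoms


def sphere_points(n: int) -> np.ndarray:
    """n deterministic points on the unit sphere (golden-spiral layout)."""
    i = np.arange(n)
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    radius = np.sqrt(np.clip(1.0 - y * y, 0.0, None))
    theta = golden_angle * i
    return np.column_stack([np.cos(theta) * radius, y, np.sin(theta) * radius])


def shrake_rupley(
    atoms: Sequence[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    radii: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-atom SASA in Angstrom^2.

    SASA_i = (exposed points / total points) * 4 pi (r_i + probe)^2, where
    a test point on atom i's expanded sphere is exposed iff it lies outside
    every other atom's expanded sphere.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    if radii is None:
        radii = load_vdw_radii()
    try:
        expanded = np.array([radii[a.element] for a in atoms]) + probe_radius
    except KeyError as exc:
        raise RadiusTableError(f"no van der Waals radius for element {exc.args[0]!r}") from None

    centers = np.array([a.position for a in atoms])
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(centers)
    max_reach = 2.0 * expanded.max()
    sasa = np.empty(len(atoms))
    for i in range(len(atoms)):
        points = centers[i] + expanded[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(centers[i], max_reach):
            if j == i:
                continue
            d2 = np.sum((points - centers[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        sasa[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return sasa


def residue_sasa(
    per_atom_sasa: np.ndarray, atoms: Sequence[AtomRecord]
) -> dict[ResidueId, tuple[str, float]]:
    """Sum per-atom SASA by residue; returns {residue_id: (resname, sasa)}."""
    if len(per_atom_sasa) != len(atoms):
        raise ValueError("per_atom_sasa and atoms differ in length")
    totals: dict[ResidueId, tuple[str, float]] = {}
    for value, atom in zip(per_atom_sasa, atoms):
        name, acc = totals.get(atom.residue_id, (atom.residue_name, 0.0))
        totals[atom.residue_id] = (name, acc + float(value))
    return totals


def normalize_rsa(
    sasa: float, residue_name: str, table: Mapping[str, float] | None = None
) -> float:
    """RSA = SASA / max ASA of the residue type (unclipped)."""
    if table is None:
        table = load_max_asa()
    if residue_name not in table:
        raise NormalizationError(f"no max-ASA constant for residue {residue_name!r}")
    return sasa / table[residue_name]


def compute_rsa(
    pdb_path: str | Path,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    hetatm_aliases: Mapping[str, str] | None = None,
) -> list[tuple[ResidueId, str, float, float]]:
    """(residue_id, resname, sasa, rsa) per residue of a PDB file.

    Residues without a max-ASA constant are skipped with a warning.
    """
    atoms = load_pdb_atoms(pdb_path, hetatm_aliases=hetatm_aliases)
    per_atom = shrake_rupley(atoms, probe_radius, n_sphere_points)
    max_asa = load_max_asa()
    rows = []
    for residue_id, (resname, sasa) in sorted(residue_sasa(per_atom, atoms).items()):
        if resname not in max_asa:
            logger.warning("skipping residue %s %s: no max-ASA constant", residue_id, resname)
            continue
        rows.append((residue_id, resname, sasa, normalize_rsa(sasa, resname, max_asa)))
    return rows


def write_rsa_table(
    rows: Sequence[tuple[ResidueId, str, float, float]],
    path: str | Path,
    protein_id: str,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tchain\tposition\tresidue\tsasa\trsa\n")
        for (chain, resseq, icode), resname, sasa, rsa in rows:
            pos = f"{resseq}{icode}" if icode else str(resseq)
            fh.write(f"{protein_id}\t{chain}\t{pos}\t{resname}\t"
                     f"{sasa:.6g}\t{rsa:.6g}\n")
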