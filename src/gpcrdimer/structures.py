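"""Membrane-framed protein structures for pose post-processing.

The convention throughout the package: the z-axis is the membrane normal and
the membrane center sits at z = 0, so a protomer placed in its reference
frame has its transmembrane bundle roughly parallel to z.  Structures are
held as :class:`biotite.structure.AtomArray` objects wrapped in a thin
:class:`StructureModel` that adds the Cα / heavy-atom views the geometry
operations need.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["StructureModel"]


class StructureModel:
    """A protein structure in a membrane-centric reference frame.

    Parameters
    ----------
    atoms : biotite.structure.AtomArray
        Full-atom (or Cα-only) model.  Coordinates are in Å with the z-axis
        taken as the membrane normal.
    """

    def __init__(self, atoms: struc.AtomArray):
        if not isinstance(atoms, struc.AtomArray):
            raise TypeError("atoms must be a biotite AtomArray")
        if atoms.array_length() == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")
        self.atoms = atoms

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 1) -> "StructureModel":
        """Read a structure from a PDB file (first model by default)."""
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model)
        return cls(atoms)

    def to_pdb(self, path: str | Path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))

    @classmethod
    def from_arrays(
        cls,
        coords: np.ndarray,
        res_id: np.ndarray | None = None,
        atom_name: str | np.ndarray = "CA",
        res_name: str | np.ndarray = "ALA",
        element: str | np.ndarray = "C",
        chain_id: str | np.ndarray = "A",
    ) -> "StructureModel":
        """Build a structure from raw arrays (used by toys and simulators)."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        atoms = struc.AtomArray(n)
        atoms.coord = coords
        atoms.res_id = (
            np.arange(1, n + 1) if res_id is None else np.asarray(res_id, dtype=int)
        )
        for field, value in (
            ("atom_name", atom_name),
            ("res_name", res_name),
            ("element", element),
            ("chain_id", chain_id),
        ):
            arr = np.full(n, value) if isinstance(value, str) else np.asarray(value)
            setattr(atoms, field, arr)
        return cls(atoms)

    # ------------------------------------------------------------ atom views
    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def ca_mask(self) -> np.ndarray:
        return self.atoms.atom_name == "CA"

    @property
    def ca_coords(self) -> np.ndarray:
        """Cα coordinates; at least one is required by RMSD/centroid ops."""
        ca = self.atoms.coord[self.ca_mask]
        if len(ca) == 0:
            raise ValueError("structure has no CA atoms")
        return ca

    @property
    def ca_center(self) -> np.ndarray:
        """Geometric center of the Cα atoms (the pose-topology reference)."""
        return self.ca_coords.mean(axis=0)

    @property
    def heavy_mask(self) -> np.ndarray:
        """Non-hydrogen atoms; hydrogens are ignored in all distance ops."""
        elem = np.char.upper(self.atoms.element.astype(str))
        return (elem != "H") & (elem != "D")

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.atoms.coord[self.heavy_mask]

    # ---------------------------------------------------------- transforms
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped to ``R @ x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.atoms.copy()
        out.coord = self.atoms.coord @ rotation.T + translation
        return StructureModel(out)

    def anchor_ca(self, res_id: int, chain_id: str | None = None) -> np.ndarray:
        """Cα position of an anchor residue; fails loudly if absent."""
        mask = (self.atoms.res_id == res_id) & self.ca_mask
        if chain_id is not None:
            mask &= self.atoms.chain_id == chain_id
        hits = self.atoms.coord[mask]
        if len(hits) == 0:
            where = f"chain {chain_id}, " if chain_id else ""
            raise ValueError(f"anchor residue not found: {where}residue {res_id} (CA)")
        return hits[0]

    def __len__(self) -> int:
        return self.atoms.array_length()

    def __repr__(self) -> str:  # pragma: no cover
        return f"StructureModel({len(self)} atoms, {len(np.unique(self.atoms.res_id))} residues)"
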