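"""Core structural data model and PDB/mmCIF ingestion.

A protein complex is modelled as an ordered set of polypeptide chains, each
reduced to its Cα trace. Rigid-body superpositions are represented explicitly
as proper rotations plus translations; the convention throughout the library
is that a superposition maps *target* coordinates into the *query* frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureError",
    "StructureParseError",
    "EmptyStructureError",
    "DegenerateGeometryError",
    "RigidTransform",
    "ChainStructure",
    "ComplexStructure",
    "read_structure",
    "write_pdb",
    "apply_transform",
]


class StructureError(Exception):
    """Base class for structural-model errors."""


class StructureParseError(StructureError):
    """A coordinate file could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """A coordinate file contained no usable protein chain."""


class DegenerateGeometryError(StructureError):
    """A point set is too degenerate (rank < 2) to define a superposition."""


_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x -> rotation @ x + translation.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1 (the U of a
    superposition), ``translation`` a 3-vector in Å (the T).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.array(self.rotation, dtype=float).reshape(3, 3)
        trans = np.array(self.translation, dtype=float).reshape(3)
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:g})")
        det = np.linalg.det(rot)
        if abs(det - 1.0) > _ORTHO_TOL:
            raise ValueError(f"rotation is not proper (det {det:g})")
        rot.flags.writeable = False
        trans.flags.writeable = False
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_t = self.rotation.T
        return RigidTransform(rot_t, -rot_t @ self.translation)

    def as_vector12(self) -> np.ndarray:
        """Flatten to the 12-component superposition vector (9 rotation entries
        row-major, then the 3 translation components)."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Angle in degrees of the relative rotation between two transforms."""
        rel = self.rotation @ other.rotation.T
        cos = np.clip((np.trace(rel) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)))


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply ``t`` to an (n, 3) array of coordinates."""
    return t.apply(coords)


@dataclass
class ChainStructure:
    """One polypeptide chain reduced to its Cα trace.

    ``residue_numbers`` keeps the author numbering (number, insertion code) for
    reporting only; all internal indexing is 0-based positional in file order.
    """

    chain_id: str
    ca_coords: np.ndarray
    residue_names: list[str]
    residue_numbers: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        n = len(self.ca_coords)
        if n < 1:
            raise ValueError("a chain must contain at least one Cα atom")
        if len(self.residue_names) != n or len(self.residue_numbers) != n:
            raise ValueError("coordinate / residue annotation length mismatch")
        if len(set(self.residue_numbers)) != n:
            raise ValueError(f"duplicate residue identifiers in chain {self.chain_id}")

    def __len__(self) -> int:
        return len(self.ca_coords)


@dataclass
class ComplexStructure:
    """An identified set of chains constituting one complex."""

    complex_id: str
    chains: list[ChainStructure]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a complex must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in complex {self.complex_id}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    @property
    def total_length(self) -> int:
        """Total residue count; the L used for TM normalization."""
        return sum(len(c) for c in self.chains)

    def get_chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex {self.complex_id}")

    def __len__(self) -> int:
        return len(self.chains)


_FORMAT_MAP = {
    None: gemmi.CoorFormat.Detect,
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}

MIN_CHAIN_LENGTH = 3  # Kabsch needs >= 3 non-degenerate points


def _complex_id_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".pdb", ".cif", ".mmcif", ".ent"):
        if name.lower().endswith(suffix):
            name = name[: -len(suffix)]
    return name or path.stem


def read_structure(path, format_hint: str | None = None) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Only the first model of multi-model files is used; only altloc '' or 'A'
    Cα atoms are kept; chains without any amino-acid Cα (waters, ligands) are
    dropped, as are chains with fewer than three Cα atoms (with a warning).
    Author chain identifiers (auth_asym_id) are used.
    """
    path = Path(path)
    if format_hint not in _FORMAT_MAP:
        raise ValueError(f"format_hint must be 'pdb', 'mmcif' or None, got {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format_hint])
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with context
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no model")
    model = st[0]

    chains: list[ChainStructure] = []
    for chain in model:
        coords: list[list[float]] = []
        names: list[str] = []
        numbers: list[tuple[int, str]] = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_amino = res.het_flag == "A" or (info is not None and info.is_amino_acid())
            if not is_amino:
                continue
            key = (res.seqid.num, (res.seqid.icode or " ").strip())
            if key in seen:
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.element.name == "C" and atom.altloc in ("", "A", "\x00"):
                    ca = atom
                    break
            if ca is None:
                continue
            seen.add(key)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            names.append(res.name)
            numbers.append(key)
        if not coords:
            continue
        if len(coords) < MIN_CHAIN_LENGTH:
            warnings.warn(
                f"{path}: dropping chain {chain.name!r} with only {len(coords)} Cα atoms",
                stacklevel=2,
            )
            continue
        chains.append(ChainStructure(chain.name, np.array(coords), names, numbers))

    if not chains:
        raise EmptyStructureError(f"{path}: no protein chain with >= {MIN_CHAIN_LENGTH} Cα atoms")
    return ComplexStructure(_complex_id_from_path(path), chains)


def write_pdb(complex_structure: ComplexStructure, path) -> None:
    """Write a minimal Cα-only PDB file (debugging / fixtures)."""
    lines = []
    serial = 1
    for chain in complex_structure.chains:
        for (x, y, z), name, (num, icode) in zip(
            chain.ca_coords, chain.residue_names, chain.residue_numbers
        ):
            lines.append(
                f"ATOM  {serial:5d}  CA  {name:>3s} {chain.chain_id[:1]}"
                f"{num:4d}{(icode or ' ')[:1]}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residue_names[-1]:>3s} {chain.chain_id[:1]}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
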