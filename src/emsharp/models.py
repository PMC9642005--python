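"""Atomic models: a light container over (element, xyz, B, occupancy) records
with PDB/mmCIF I/O through gemmi."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = ["Atom", "AtomicModel", "read_model", "write_model"]

#: valid per-residue secondary-structure labels
SS_LABELS = ("helix", "sheet", "coil", "nucleotide")


@dataclass
class Atom:
    element: str                  # chemical symbol, e.g. "C"
    position: np.ndarray          # (x, y, z) in Å
    b_iso: float = 0.0            # Å²
    occupancy: float = 1.0
    name: str = ""                # atom name, e.g. "CA"
    res_name: str = "ALA"
    res_seq: int = 1
    chain: str = "A"
    is_hetero: bool = False       # HETATM record (waters, ligands)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.b_iso < 0:
            raise ValueError(f"b_iso must be >= 0, got {self.b_iso}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")


@dataclass
class AtomicModel:
    """An ordered collection of atoms with optional secondary-structure labels.

    ``secondary_structure`` maps residue keys ``(chain, res_seq)`` to one of
    ``helix | sheet | coil | nucleotide``; either every residue is labelled
    or the mapping is None.
    """

    atoms: list[Atom]
    secondary_structure: dict[tuple[str, int], str] | None = None

    def __post_init__(self) -> None:
        if self.secondary_structure is not None:
            missing = [k for k in self.residue_keys() if k not in self.secondary_structure]
            if missing:
                raise ValueError(
                    f"secondary-structure labels must cover all residues or none; "
                    f"missing {missing[:3]}{'...' if len(missing) > 3 else ''}"
                )
            bad = set(self.secondary_structure.values()) - set(SS_LABELS)
            if bad:
                raise ValueError(f"unknown secondary-structure labels {bad}")

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[tuple[str, int]]:
        seen, keys = set(), []
        for a in self.atoms:
            k = (a.chain, a.res_seq)
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_positions(self, positions: np.ndarray) -> "AtomicModel":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, positions)]
        return AtomicModel(atoms, dict(self.secondary_structure)
                           if self.secondary_structure else None)

    def with_b_factors(self, b: np.ndarray) -> "AtomicModel":
        b = np.asarray(b, dtype=float)
        if b.shape != (len(self.atoms),):
            raise ValueError("b must have shape (n_atoms,)")
        atoms = [replace(a, b_iso=float(bi)) for a, bi in zip(self.atoms, b)]
        return AtomicModel(atoms, dict(self.secondary_structure)
                           if self.secondary_structure else None)

    def filtered(self, *, exclude_hydrogens: bool = True,
                 polymer_only: bool = False) -> "AtomicModel":
        """Drop hydrogens and/or HETATM records (waters, ligands)."""
        atoms = [
            a for a in self.atoms
            if not (exclude_hydrogens and a.element.capitalize() in ("H", "D"))
            and not (polymer_only and a.is_hetero)
        ]
        ss = None
        if self.secondary_structure is not None:
            keep = {(a.chain, a.res_seq) for a in atoms}
            ss = {k: v for k, v in self.secondary_structure.items() if k in keep}
        return AtomicModel(atoms, ss)

    def translated(self, shift) -> "AtomicModel":
        return self.with_positions(self.positions + np.asarray(shift, float))

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


_ELEMENT_FALLBACK = {"CA": "C", "CB": "C", "CG": "C", "CD": "C", "CE": "C",
                     "CZ": "C", "OG": "O", "OD": "O", "OE": "O", "OH": "O",
                     "NE": "N", "ND": "N", "NZ": "N", "NH": "N", "SD": "S",
                     "SG": "S"}


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2] in _ELEMENT_FALLBACK:
        return _ELEMENT_FALLBACK[name[:2]]
    for ch in name:
        if ch.isalpha():
            return ch.capitalize()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_model(path: str | os.PathLike, *, exclude_hydrogens: bool = False,
               polymer_only: bool = False) -> AtomicModel:
    """Read a PDB or mmCIF file (format detected from contents/extension)."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for at in res:
                    el = at.element.name
                    if not el or el == "X":
                        el = _infer_element(at.name)
                    atoms.append(Atom(
                        element=el,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_iso=float(at.b_iso),
                        occupancy=float(at.occ),
                        name=at.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain=chain.name,
                        is_hetero=het,
                    ))
        break  # first model only
    out = AtomicModel(atoms)
    if exclude_hydrogens or polymer_only:
        out = out.filtered(exclude_hydrogens=exclude_hydrogens,
                           polymer_only=polymer_only)
    return out


def to_gemmi(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "emsharp"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        key = (a.chain, a.res_seq)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chains[a.chain].add_residue(res)
            residues[key] = chains[a.chain][-1]
        at = gemmi.Atom()
        at.name = a.name or a.element
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.b_iso = a.b_iso
        at.occ = a.occupancy
        residues[key].add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path: str | os.PathLike) -> None:
    """Write PDB (default) or mmCIF (``.cif`` extension)."""
    st = to_gemmi(model)
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
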