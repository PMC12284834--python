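"""Atomic-structure I/O and the lightweight structural data model.

Every analysis module in :mod:`coilspect` operates on :class:`StructureModel`,
a minimal chain/residue/atom hierarchy keyed by *author* residue numbering
(the numbering used in names such as K172 or D138).  Parsing and serialization
of PDB/mmCIF go through :mod:`gemmi`; this module only converts between
gemmi's rich model and the flat containers used here.

Deliberate restrictions (the synthetic inputs never produce these, and real
coiled-coil models rarely need them):

* insertion codes and alternate locations are rejected with an error,
* only the first model of a multi-model file is read,
* waters are skipped; other residues are kept as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainModel",
    "StructureModel",
    "StructureError",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "THREE_TO_ONE",
]

#: Standard 3-letter -> 1-letter amino-acid code table.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for malformed or unsupported structural input."""


@dataclass
class AtomRecord:
    """A single atom: name, element and Cartesian position in Å."""

    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )


@dataclass
class ResidueRecord:
    """One residue with author seq_id and atoms keyed by atom name."""

    seq_id: int
    res_name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def add_atom(self, atom: AtomRecord) -> None:
        if atom.atom_name in self.atoms:
            raise StructureError(
                f"duplicate atom {atom.atom_name} in residue "
                f"{self.res_name}{self.seq_id}"
            )
        self.atoms[atom.atom_name] = atom

    def get(self, atom_name: str) -> AtomRecord | None:
        return self.atoms.get(atom_name)

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms


@dataclass
class ChainModel:
    """An ordered chain of residues with strictly increasing seq_id."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_order()

    def _check_order(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise StructureError(
                f"chain {self.chain_id}: seq_id not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def residue(self, seq_id: int) -> ResidueRecord:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {seq_id}")

    def ca_positions(self) -> np.ndarray:
        """(n, 3) array of CA positions; raises if any residue lacks CA."""
        pos = []
        for r in self.residues:
            ca = r.get("CA")
            if ca is None:
                raise StructureError(
                    f"chain {self.chain_id}: residue {r.seq_id} lacks CA"
                )
            pos.append(ca.position)
        return np.array(pos, dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    """An ordered collection of chains with unique chain ids."""

    chains: list[ChainModel] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids: {ids}")

    def __iter__(self) -> Iterator[ChainModel]:
        return iter(self.chains)

    def __len__(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Author numbering is the single residue coordinate system; mmCIF
    label_seq ids are ignored.  Insertion codes and altlocs are rejected.
    Only the first model is read; waters are skipped.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    chains: list[ChainModel] = []
    for ch in model:
        residues: list[ResidueRecord] = []
        for res in ch:
            if res.is_water():
                continue
            if res.seqid.icode not in (" ", "\0", ""):
                raise StructureError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{ch.name} {res.seqid.num} not supported"
                )
            rec = ResidueRecord(seq_id=res.seqid.num, res_name=res.name)
            for atom in res:
                if atom.altloc not in ("\0", "", " ", "A"):
                    raise StructureError(
                        f"{path}: altloc {atom.altloc!r} at "
                        f"{ch.name} {res.seqid.num} {atom.name} not supported"
                    )
                rec.add_atom(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                    )
                )
            residues.append(rec)
        if residues:
            chains.append(ChainModel(chain_id=ch.name, residues=residues))
    return StructureModel(chains=chains, title=st.name or path.stem)


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "pdb") -> None:
    """Write a model to a PDB file (coordinates at 3 decimals).

    PDB chain identifiers are a single character; longer ids raise.
    Every chain must contain at least one residue with at least one atom.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if not model.chains:
        raise StructureError("cannot write a model with no chains")
    st = gemmi.Structure()
    st.name = model.title
    gm = gemmi.Model(1)
    for chain in model.chains:
        if len(chain.chain_id) > 1:
            raise StructureError(
                f"chain id {chain.chain_id!r} too long for PDB (1 char)"
            )
        if len(chain) == 0 or any(not r.atoms for r in chain):
            raise StructureError(
                f"chain {chain.chain_id}: every residue needs >=1 atom"
            )
        gc = gemmi.Chain(chain.chain_id)
        for res in chain:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_sequence(chain: ChainModel) -> str:
    """One-letter sequence of a chain; unknown residue codes map to X.

    Emits a :class:`UserWarning` listing any nonstandard residues.
    """
    seq = []
    unknown = []
    for res in chain:
        code = THREE_TO_ONE.get(res.res_name)
        if code is None:
            code = "X"
            unknown.append(f"{res.res_name}{res.seq_id}")
        seq.append(code)
    if unknown:
        warnings.warn(
            f"chain {chain.chain_id}: nonstandard residues mapped to X: "
            + ", ".join(unknown),
            stacklevel=2,
        )
    return "".join(seq)
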