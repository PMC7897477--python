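"""Reading and writing atomic coordinate files (PDB / mmCIF).

This module exposes a deliberately small data model — :class:`Atom`,
:class:`Residue`, :class:`StructureModel` — that every downstream geometry
routine consumes.  Parsing and serialization are delegated to :mod:`gemmi`;
the layer here normalizes atom naming (prime vs. star dialects), resolves
alternate locations to the highest-occupancy conformer, and tags
non-nucleotide entities (waters, ions, ligands) so that annotation can skip
them.

Deposited residue numbering is preserved verbatim: structures are referred
to by their deposited residue numbers (e.g. the bulge thymine T5), so the
reader never renumbers.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureFormatError",
    "NoModelsError",
    "CapacityError",
    "read_structure",
    "write_structure",
    "normalize_atom_name",
]

# O3'(i)-P(i+1) distances below this are treated as a covalent backbone link.
BACKBONE_BOND_CUTOFF = 2.2  # Å

_NUCLEOTIDE_NAMES = {
    "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U",
    "ADE", "CYT", "GUA", "THY", "URA",
}

_BASE_TYPE_BY_NAME = {
    "DA": "A", "A": "A", "ADE": "A",
    "DC": "C", "C": "C", "CYT": "C",
    "DG": "G", "G": "G", "GUA": "G",
    "DT": "T", "T": "T", "THY": "T",
    "DU": "U", "U": "U", "URA": "U",
}


class StructureFormatError(ValueError):
    """A coordinate file could not be parsed under the named standard."""


class NoModelsError(ValueError):
    """A coordinate file parsed but contained no atomic models."""


class CapacityError(ValueError):
    """The requested output format cannot hold the model."""


def normalize_atom_name(name: str) -> str:
    """Normalize sugar/backbone atom labels to the apostrophe convention.

    Accepts the star dialect of older PDB DNA entries (``C1*``) and the
    unicode prime (``C1′``); stores ``C1'``.
    """
    return name.strip().replace("*", "'").replace("′", "'")


@dataclass
class Atom:
    """A named atom with a position in Å."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.name = normalize_atom_name(self.name)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            self.element = _guess_element(self.name)
        self.is_hydrogen = self.is_hydrogen or self.element.upper() == "H"


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass
class Residue:
    """One residue: chain id, deposited sequence number, base type, atoms."""

    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    is_nucleotide: bool = True
    insertion_code: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.atoms:
            if a.name in seen:
                raise ValueError(
                    f"duplicate atom {a.name} in residue "
                    f"{self.chain_id}:{self.name}{self.seq_number}"
                )
            seen.add(a.name)

    @property
    def base_type(self) -> str:
        return _BASE_TYPE_BY_NAME.get(self.name.strip().upper(), "other")

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.base_type}{self.seq_number}"

    def atom(self, name: str) -> Atom | None:
        name = normalize_atom_name(name)
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def pos(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(
                f"residue {self.label} has no atom {normalize_atom_name(name)}"
            )
        return a.position

    def has_atoms(self, names: Iterable[str]) -> bool:
        return all(self.atom(n) is not None for n in names)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class StructureModel:
    """One coordinate model: ordered residues grouped by chain."""

    model_index: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            nums = [(r.seq_number, r.insertion_code) for r in residues]
            if nums != sorted(nums):
                raise ValueError(f"chain {cid}: residues not ordered by seq_number")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def nucleotides(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_nucleotide]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def find_residue(self, chain_id: str, seq_number: int) -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq_number:
                return r
        return None

    def single_chain(self, chain_id: str) -> "StructureModel":
        """A view restricted to one chain (for multi-copy asymmetric units)."""
        return StructureModel(
            model_index=self.model_index,
            chains={chain_id: self.chains[chain_id]},
            source_id=f"{self.source_id}:{chain_id}",
        )


# ---------------------------------------------------------------------------
# gemmi bridge

def _coor_format(fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")


def _residue_is_nucleotide(res: gemmi.Residue) -> bool:
    if res.name.strip().upper() in _NUCLEOTIDE_NAMES:
        return True
    names = {normalize_atom_name(a.name) for a in res}
    return {"C1'", "O4'", "C4'"}.issubset(names)


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations to the highest-occupancy conformer."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        key = normalize_atom_name(atom.name)
        prev = by_name.get(key)
        if prev is None or atom.occ > prev.occ:
            by_name[key] = atom
    return list(by_name.values())


def read_structure(path: str | os.PathLike, format: str = "auto") -> list[StructureModel]:
    """Read a PDB or mmCIF file into one :class:`StructureModel` per model.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters, ions and ligands are retained but tagged non-nucleotide.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(path, format=_coor_format(format))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path!r}: {exc}") from exc
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise NoModelsError(f"{path!r} contains no coordinate models")

    models: list[StructureModel] = []
    for mi, model in enumerate(st):
        chains: dict[str, list[Residue]] = {}
        for chain in model:
            residues: list[Residue] = []
            for res in chain:
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        is_hydrogen=a.is_hydrogen(),
                    )
                    for a in _pick_altlocs(res)
                ]
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_number=res.seqid.num,
                        name=res.name.strip(),
                        atoms=atoms,
                        is_nucleotide=_residue_is_nucleotide(res),
                        insertion_code=(res.seqid.icode or "").strip(),
                    )
                )
            if residues:
                chains[chain.name] = residues
        models.append(
            StructureModel(
                model_index=mi + 1,
                chains=chains,
                source_id=os.path.basename(path),
            )
        )
    return models


_PDB_ATOM_LIMIT = 99_999


def write_structure(
    model: StructureModel | Sequence[StructureModel],
    path: str | os.PathLike,
    format: str = "pdb",
) -> None:
    """Write one model (or an ensemble) to a PDB or mmCIF file."""
    models = [model] if isinstance(model, StructureModel) else list(model)
    if not models or all(m.atom_count() == 0 for m in models):
        raise ValueError("refusing to write an empty model")
    fmt = format.lower()
    if fmt not in ("pdb", "mmcif", "cif"):
        raise ValueError(f"unknown output format {format!r}")
    if fmt == "pdb" and any(m.atom_count() > _PDB_ATOM_LIMIT for m in models):
        raise CapacityError(
            f"model exceeds the {_PDB_ATOM_LIMIT}-atom PDB serial capacity; "
            "write mmCIF instead"
        )

    st = gemmi.Structure()
    st.name = models[0].source_id or "g4geom"
    for m in models:
        gm = gemmi.Model(str(m.model_index))
        for cid, residues in m.chains.items():
            gc = gemmi.Chain(cid)
            for r in residues:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
                for a in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.position)
                    ga.occ = a.occupancy
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    path = os.fspath(path)
    try:
        if fmt == "pdb":
            st.write_pdb(path)
        else:
            doc = st.make_mmcif_document()
            doc.write_file(path)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path!r}: {exc}") from exc


def backbone_connected(res5: Residue, res3: Residue,
                       cutoff: float = BACKBONE_BOND_CUTOFF) -> bool:
    """True when res5's O3' bonds to res3's P (5'→3' connectivity)."""
    o3 = res5.atom("O3'")
    p = res3.atom("P")
    if o3 is None or p is None:
        return False
    return math.dist(o3.position, p.position) < cutoff
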