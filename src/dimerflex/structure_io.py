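"""Macromolecular structure model and file I/O.

A thin, explicit hierarchy (Atom -> Residue -> Chain -> Structure) holding
exactly what the downstream geometry needs: coordinates, isotropic B-factors,
occupancies and author residue numbering.  Parsing and serialisation are
delegated to gemmi; everything downstream of this module never touches file
formats.

Conventions
-----------
* Author residue numbering (as printed in the file, possibly gapped) is the
  only numbering exposed; residues are addressed as ``(seq_num, icode)``.
* Alternate locations: the highest-occupancy conformer is kept per atom name,
  first-listed wins ties; the rest are dropped.
* Hydrogens are dropped on read — the geometry modules infer donors from
  heavy atoms.
* PDB is the only output dialect; mmCIF is accepted on input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Literal

import gemmi
import numpy as np

from .errors import (
    CorrespondenceError,
    EmptyModelError,
    FormatError,
    ResidueLookupError,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainModel",
    "StructureModel",
    "Correspondence",
    "read_structure",
    "write_structure",
    "select_residue",
    "map_equivalent_residues",
]

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

#: 3-letter codes treated as polymer amino acids.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE SEC PYL".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Elements classified as metals when they form single-atom hetero groups.
METAL_ELEMENTS = frozenset(
    "LI NA K RB CS MG CA SR BA MN FE CO NI CU ZN CD HG AL GA PB".split()
)


@dataclasses.dataclass
class AtomRecord:
    """One atom: name, element, position (Å), B-factor (Å²), occupancy."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_mainchain: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0, 1]")


ResidueKind = Literal["polymer", "water", "metal", "other-hetero"]


@dataclasses.dataclass
class ResidueRecord:
    """One residue, identified by author number + insertion code."""

    name: str
    seq_num: int
    icode: str = ""
    kind: ResidueKind = "polymer"
    atoms: list[AtomRecord] = dataclasses.field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.seq_num}{self.icode}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclasses.dataclass
class ChainModel:
    """An ordered list of residues under one chain identifier."""

    chain_id: str
    residues: list[ResidueRecord] = dataclasses.field(default_factory=list)

    def polymer_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.kind == "polymer"]

    def residue(self, seq_num: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)


@dataclasses.dataclass
class StructureModel:
    """One crystal structure: chains plus optional crystal metadata."""

    structure_id: str
    chains: list[ChainModel] = dataclasses.field(default_factory=list)
    resolution: float | None = None
    space_group: str | None = None

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ResidueLookupError(
            f"structure {self.structure_id!r} has no chain {chain_id!r} "
            f"(chains: {[c.chain_id for c in self.chains]})"
        )

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)

    def atoms(self) -> Iterator[tuple[ChainModel, ResidueRecord, AtomRecord]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())


@dataclasses.dataclass
class Correspondence:
    """Residue pairing between two chains: ordered (label_A, label_B) pairs."""

    pairs: list[tuple[tuple[int, str], tuple[int, str]]]
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# reading


def _classify(res: gemmi.Residue) -> ResidueKind:
    name = res.name.strip().upper()
    if name in AMINO_ACIDS:
        return "polymer"
    if name in WATER_NAMES or res.is_water():
        return "water"
    heavy = [a for a in res if not a.is_hydrogen()]
    if len(heavy) == 1 and heavy[0].element.name.upper() in METAL_ELEMENTS:
        return "metal"
    return "other-hetero"


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest occupancy per atom name; first listed wins ties."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.is_hydrogen():
            continue
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path : file path
    format : ``"PDB"``, ``"mmCIF"`` or ``"auto"`` (detect from contents).

    Waters are classified ``kind="water"``; single-atom metal hetero groups
    (Zn, Mg, ...) as ``kind="metal"``.  Only the first model of multi-model
    files is read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format.lower())
    if fmt is None:
        raise FormatError(f"unknown format {format!r} (use PDB, mmCIF or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    model = StructureModel(structure_id=st.name or path.stem)
    if st.resolution and st.resolution > 0:
        model.resolution = float(st.resolution)
    sg = st.spacegroup_hm
    if sg and sg != "P 1":
        model.space_group = sg

    if len(st) == 0:
        raise EmptyModelError(f"{path}: no atoms in file")
    for g_chain in st[0]:
        chain = ChainModel(chain_id=g_chain.name)
        for g_res in g_chain:
            kind = _classify(g_res)
            rec = ResidueRecord(
                name=g_res.name.strip().upper(),
                seq_num=g_res.seqid.num,
                icode=(g_res.seqid.icode or "").strip(),
                kind=kind,
            )
            for g_atom in _pick_altlocs(g_res):
                rec.atoms.append(
                    AtomRecord(
                        name=g_atom.name,
                        element=g_atom.element.name.upper(),
                        coords=np.array(
                            [g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]
                        ),
                        bfactor=max(float(g_atom.b_iso), 0.0),
                        occupancy=min(max(float(g_atom.occ), 0.0), 1.0),
                        altloc=(g_atom.altloc or "").strip(),
                        is_mainchain=(
                            kind == "polymer" and g_atom.name in MAINCHAIN_ATOMS
                        ),
                    )
                )
            if rec.atoms:
                chain.residues.append(rec)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_num, r.icode))
            model.chains.append(chain)
    if model.n_atoms() == 0:
        _raise_no_atoms(path)
    return model


_PDB_RECORDS = (
    "ATOM", "HETATM", "HEADER", "TITLE", "REMARK", "CRYST1", "MODEL",
    "ENDMDL", "TER", "END", "SEQRES", "HELIX", "SHEET", "CONECT", "ANISOU",
    "EXPDTA", "COMPND", "SOURCE", "AUTHOR", "REVDAT", "JRNL", "SCALE",
    "ORIGX", "MASTER", "DBREF", "SSBOND", "LINK", "MODRES", "SEQADV", "HET",
)


def _raise_no_atoms(path: Path) -> None:
    """Distinguish a truly empty model from an unparseable file."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        record = stripped.split()[0].upper()
        if stripped.startswith(("data_", "#", "loop_", "_")):
            break  # mmCIF-flavoured content: treat as empty model
        if not any(record.startswith(r) for r in _PDB_RECORDS):
            raise FormatError(
                f"{path}:{lineno}: unrecognized record {stripped[:30]!r}"
            )
    raise EmptyModelError(f"{path}: no atoms in file")


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.structure_id
    if model.resolution is not None:
        st.resolution = model.resolution
    if model.space_group is not None:
        st.spacegroup_hm = model.space_group
    g_model = gemmi.Model("1")
    for chain in model.chains:
        if len(chain.chain_id) != 1:
            raise FormatError(
                f"chain id {chain.chain_id!r} does not fit the PDB format "
                "(single character required)"
            )
        g_chain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            g_res.het_flag = "A" if res.kind == "polymer" else "H"
            for atom in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*atom.coords)
                g_atom.b_iso = atom.bfactor
                g_atom.occ = atom.occupancy
                g_atom.altloc = atom.altloc[:1] if atom.altloc else "\0"
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        g_model.add_chain(g_chain)
    st.add_model(g_model)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as standard fixed-column PDB text.

    Round-trips through :func:`read_structure` preserve atom names, residue
    numbers, coordinates (3 decimals) and B-factors (2 decimals).
    """
    if model.n_atoms() == 0:
        raise EmptyModelError("refusing to write a model with no atoms")
    st = _to_gemmi(model)
    opts = gemmi.PdbWriteOptions()
    opts.cryst1_record = False
    st.write_pdb(str(path), opts)


# ---------------------------------------------------------------------------
# queries


def select_residue(
    model: StructureModel, chain_id: str, seq_num: int, icode: str = ""
) -> ResidueRecord:
    """Return the unique residue ``(chain_id, seq_num, icode)`` or raise."""
    chain = model.chain(chain_id)
    res = chain.residue(seq_num, icode)
    if res is None:
        raise ResidueLookupError(
            f"chain {chain_id!r} has no residue {seq_num}{icode}"
        )
    return res


def map_equivalent_residues(
    chain_a: ChainModel, chain_b: ChainModel
) -> Correspondence:
    """Pair residues of two chains by author number + insertion code.

    Residues are paired when both chains contain ``(seq_num, icode)`` and
    both have a CA atom; point mutations (different residue name at the same
    number) are paired.  Residues present in only one chain are excluded and
    counted.
    """
    b_index = {
        (r.seq_num, r.icode): r for r in chain_b.polymer_residues()
    }
    pairs = []
    unmatched_a = 0
    seen_b: set[tuple[int, str]] = set()
    for res_a in chain_a.polymer_residues():
        key = (res_a.seq_num, res_a.icode)
        res_b = b_index.get(key)
        if res_b is None or res_a.ca is None or res_b.ca is None:
            unmatched_a += 1
            continue
        seen_b.add(key)
        pairs.append((key, key))
    unmatched_b = len(
        [r for r in chain_b.polymer_residues() if (r.seq_num, r.icode) not in seen_b]
    )
    if not pairs:
        raise CorrespondenceError(
            f"chains {chain_a.chain_id!r} and {chain_b.chain_id!r} share no "
            "residues with CA atoms"
        )
    return Correspondence(pairs=pairs, n_unmatched_a=unmatched_a, n_unmatched_b=unmatched_b)
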