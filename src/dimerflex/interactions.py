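"""Noncovalent interaction detection at dimer interfaces.

Distance-class criteria, matching how interface networks are drawn in
crystallographic figures of structures solved without hydrogens:

* strong hydrogen bond: donor/acceptor heavy atoms at d_min <= d < 3.0 Å
* weak hydrogen bond:   3.0 Å <= d <= 5.0 Å
* salt bridge: minimum cationic-group–anionic-group atom distance <= 5.0 Å
* water bridge: one water oxygen within 3.4 Å of polar atoms of two
  distinct protein residues

No donor–H–acceptor angle term is applied — donors are inferred from heavy
atoms.  A 2.2 Å floor excludes covalent/clash artifacts, and adjacent
mainchain N–O pairs at peptide-bond geometry (< 2.6 Å) are excluded.
Neighbour search uses a KD-tree; correctness is defined against an
exhaustive all-pairs scan with the same rules.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, EmptyModelError, ResidueLookupError
from .structure_io import ChainModel, ResidueRecord, StructureModel

__all__ = [
    "Interaction",
    "InteractionNetwork",
    "DONORS",
    "ACCEPTORS",
    "CATIONIC_GROUPS",
    "ANIONIC_GROUPS",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_water_bridges",
    "loop_interaction_summary",
    "active_site_separation",
]

# ---------------------------------------------------------------------------
# polar atom tables (heavy atoms only)

#: side-chain hydrogen-bond donor heavy atoms per residue type
DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}

#: side-chain hydrogen-bond acceptor heavy atoms per residue type
ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "MET": frozenset({"SD"}),
    "CYS": frozenset({"SG"}),
}

#: cationic side-chain group atoms (His protonation unknown at mildly basic
#: pH, so His is cationic by default; configurable)
CATIONIC_GROUPS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: anionic side-chain group atoms; C-terminal oxygens (O, OXT) are handled
#: separately because they are mainchain atoms
ANIONIC_GROUPS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

MAINCHAIN_DONOR = "N"
MAINCHAIN_ACCEPTOR = "O"

Kind = Literal["strong-hbond", "weak-hbond", "salt-bridge", "water-bridge"]
Topology = Literal["intra-chain", "inter-chain"]
BackboneClass = Literal[
    "mainchain-mainchain", "mainchain-sidechain", "sidechain-sidechain"
]


@dataclasses.dataclass(frozen=True)
class Partner:
    chain: str
    res_label: str
    res_name: str
    atom: str
    is_mainchain: bool

    def key(self) -> tuple[str, str, str]:
        return (self.chain, self.res_label, self.atom)


@dataclasses.dataclass
class Interaction:
    """One typed, distance-classed noncovalent edge."""

    kind: Kind
    partner1: Partner
    partner2: Partner
    distance: float
    topology: Topology
    backbone_class: BackboneClass
    water_label: str | None = None

    def __post_init__(self) -> None:
        # canonical partner ordering makes edge lists order-independent
        if self.partner2.key() < self.partner1.key():
            self.partner1, self.partner2 = self.partner2, self.partner1

    @property
    def pair_key(self) -> tuple:
        return (self.partner1.key(), self.partner2.key())

    def to_row(self) -> str:
        p1, p2 = self.partner1, self.partner2
        return "\t".join(
            [
                self.kind,
                p1.chain, p1.res_label, p1.atom,
                p2.chain, p2.res_label, p2.atom,
                f"{self.distance:.3f}",
                self.topology,
                self.backbone_class,
                self.water_label or ".",
            ]
        )


TSV_HEADER = ("kind\tchain1\tres1\tatom1\tchain2\tres2\tatom2\t"
              "distance_angstrom\ttopology\tbackbone_class\twater_label")


def write_interactions_tsv(path, interactions: Iterable[Interaction]) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for ix in interactions:
            fh.write(ix.to_row() + "\n")


@dataclasses.dataclass
class InteractionNetwork:
    """Edges touching a focal loop plus a census broken down by class.

    ``summary`` keys:

    * ``n_intra_loop_strong`` / ``_weak`` / ``_salt``: both partners inside
      the loop, per class
    * ``n_intra_loop_hbonds``: strong H-bonds with both partners inside the
      loop (the intramolecular H-bond census)
    * ``n_intra_loop_mainchain_mainchain``: subset of those between
      mainchain atoms
    * ``n_inter_strong`` / ``_weak`` / ``_salt`` / ``_water``: partners in
      different chains, per class
    * ``n_intersubunit_bonds``: distinct atom pairs across chains carrying a
      strong H-bond or a salt bridge (a pair satisfying both counts once)
    * ``n_intersubunit_pairs_any``: distinct cross-chain atom pairs carrying
      any strong/weak/salt edge
    """

    focal_chain: str
    focal_range: tuple[int, int]
    edges: list[Interaction]
    summary: dict[str, int]
    thresholds: dict[str, float]


# ---------------------------------------------------------------------------
# atom gathering


def _polar_atoms(model: StructureModel):
    """All potential donor/acceptor heavy atoms of polymer residues.

    Returns a list of (partner, coords, is_donor, is_acceptor, chain_id,
    residue identity) tuples.
    """
    out = []
    for chain in model.chains:
        residues = chain.polymer_residues()
        for res in residues:
            don = DONORS.get(res.name, frozenset())
            acc = ACCEPTORS.get(res.name, frozenset())
            for atom in res.atoms:
                is_d = atom.name in don
                is_a = atom.name in acc
                if atom.name == MAINCHAIN_DONOR and res.name != "PRO":
                    is_d = True
                if atom.name in (MAINCHAIN_ACCEPTOR, "OXT"):
                    is_a = True
                if is_d or is_a:
                    out.append(
                        {
                            "partner": Partner(
                                chain=chain.chain_id,
                                res_label=res.label,
                                res_name=res.name,
                                atom=atom.name,
                                is_mainchain=atom.is_mainchain or atom.name == "OXT",
                            ),
                            "coords": atom.coords,
                            "donor": is_d,
                            "acceptor": is_a,
                            "res_key": (chain.chain_id, res.seq_num, res.icode),
                            "seq_num": res.seq_num,
                        }
                    )
    return out


def _backbone_class(p1: Partner, p2: Partner) -> BackboneClass:
    if p1.is_mainchain and p2.is_mainchain:
        return "mainchain-mainchain"
    if p1.is_mainchain or p2.is_mainchain:
        return "mainchain-sidechain"
    return "sidechain-sidechain"


def _topology(p1: Partner, p2: Partner) -> Topology:
    return "intra-chain" if p1.chain == p2.chain else "inter-chain"


# ---------------------------------------------------------------------------
# hydrogen bonds


def detect_hbonds(
    model: StructureModel,
    d_strong: float = 3.0,
    d_weak_max: float = 5.0,
    d_min: float = 2.2,
) -> list[Interaction]:
    """Enumerate donor–acceptor pairs, classed strong (< d_strong) or weak.

    Pairs within one residue are excluded; adjacent-residue mainchain N–O
    pairs below 2.6 Å (covalent peptide geometry) are excluded.  Each atom
    pair is emitted once even when both atoms are donor and acceptor.
    """
    if not (0 < d_min < d_strong <= d_weak_max):
        raise ConfigError(
            f"thresholds must satisfy 0 < d_min < d_strong <= d_weak_max; "
            f"got d_min={d_min}, d_strong={d_strong}, d_weak_max={d_weak_max}"
        )
    atoms = _polar_atoms(model)
    if not atoms:
        raise EmptyModelError("model has no polymer polar atoms")
    coords = np.array([a["coords"] for a in atoms])
    tree = cKDTree(coords)
    edges: dict[tuple, Interaction] = {}
    for i, j in tree.query_pairs(r=d_weak_max):
        ai, aj = atoms[i], atoms[j]
        if ai["res_key"] == aj["res_key"]:
            continue
        if not ((ai["donor"] and aj["acceptor"]) or (ai["acceptor"] and aj["donor"])):
            continue
        d = float(np.linalg.norm(ai["coords"] - aj["coords"]))
        if d < d_min or d > d_weak_max:
            continue
        p1, p2 = ai["partner"], aj["partner"]
        # covalently adjacent mainchain N-O at peptide-bond geometry
        if (
            p1.is_mainchain and p2.is_mainchain
            and p1.chain == p2.chain
            and abs(ai["seq_num"] - aj["seq_num"]) == 1
            and {p1.atom, p2.atom} == {"N", "O"}
            and d < 2.6
        ):
            continue
        kind: Kind = "strong-hbond" if d < d_strong else "weak-hbond"
        ix = Interaction(
            kind=kind,
            partner1=p1,
            partner2=p2,
            distance=d,
            topology=_topology(p1, p2),
            backbone_class=_backbone_class(p1, p2),
        )
        edges[ix.pair_key] = ix
    return sorted(edges.values(), key=lambda e: e.pair_key)


# ---------------------------------------------------------------------------
# salt bridges


def detect_salt_bridges(
    model: StructureModel,
    cutoff: float = 5.0,
    his_cationic: bool = True,
    include_cterm: bool = True,
) -> list[Interaction]:
    """Minimum cationic-group / anionic-group atom distance per residue pair.

    For each (cationic residue, anionic residue) pair the minimum distance
    over all group-atom combinations is taken; a salt bridge is emitted when
    it is <= ``cutoff``, with that minimum as its distance and the arg-min
    atom pair as partners.
    """
    if cutoff <= 0:
        raise ConfigError("salt-bridge cutoff must be positive")
    cat_groups = dict(CATIONIC_GROUPS)
    if not his_cationic:
        cat_groups.pop("HIS", None)

    def group_atoms(res: ResidueRecord, chain_id: str, table, cterm_ok: bool):
        names = table.get(res.name, frozenset())
        out = [(a, False) for a in res.atoms if a.name in names]
        if cterm_ok and res.atom("OXT") is not None:
            out.extend((a, True) for a in res.atoms if a.name in ("O", "OXT"))
        return out

    cations, anions = [], []
    for chain in model.chains:
        for res in chain.polymer_residues():
            cat = group_atoms(res, chain.chain_id, cat_groups, cterm_ok=False)
            if cat:
                cations.append((chain.chain_id, res, cat))
            ani = group_atoms(res, chain.chain_id, ANIONIC_GROUPS,
                              cterm_ok=include_cterm)
            if ani:
                anions.append((chain.chain_id, res, ani))

    edges = []
    for (c_chain, c_res, c_atoms) in cations:
        for (a_chain, a_res, a_atoms) in anions:
            if c_chain == a_chain and c_res.label == a_res.label:
                continue
            best = None
            for (ca, _), (aa, aa_mc) in itertools.product(c_atoms, a_atoms):
                d = float(np.linalg.norm(ca.coords - aa.coords))
                if best is None or d < best[0]:
                    best = (d, ca, aa, aa_mc)
            if best is not None and best[0] <= cutoff:
                d, ca, aa, aa_mc = best
                p1 = Partner(c_chain, c_res.label, c_res.name, ca.name, ca.is_mainchain)
                p2 = Partner(a_chain, a_res.label, a_res.name, aa.name, aa.is_mainchain)
                edges.append(
                    Interaction(
                        kind="salt-bridge",
                        partner1=p1,
                        partner2=p2,
                        distance=d,
                        topology=_topology(p1, p2),
                        backbone_class=_backbone_class(p1, p2),
                    )
                )
    return sorted(edges, key=lambda e: e.pair_key)


# ---------------------------------------------------------------------------
# water bridges


def detect_water_bridges(model: StructureModel, d_hb: float = 3.4) -> list[Interaction]:
    """Waters hydrogen-bonded to polar atoms of two distinct residues.

    One edge per (residue, residue, water) triple; the edge distance is the
    longer of the two water legs.  The default 3.4 Å leg is looser than the
    protein–protein strong class because structured-water geometry is looser.
    """
    if d_hb <= 0:
        raise ConfigError("water-bridge leg distance must be positive")
    waters = []
    for chain in model.chains:
        for res in chain.residues:
            if res.kind != "water":
                continue
            for atom in res.atoms:
                if atom.element == "O":
                    waters.append((chain.chain_id, res, atom))
    if not waters:
        return []
    polar = _polar_atoms(model)
    if not polar:
        return []
    coords = np.array([a["coords"] for a in polar])
    tree = cKDTree(coords)
    edges: dict[tuple, Interaction] = {}
    for w_chain, w_res, w_atom in waters:
        idx = tree.query_ball_point(w_atom.coords, r=d_hb)
        # per-residue closest polar contact for this water
        per_res: dict[tuple, tuple[float, dict]] = {}
        for i in idx:
            a = polar[i]
            d = float(np.linalg.norm(a["coords"] - w_atom.coords))
            key = a["res_key"]
            if key not in per_res or d < per_res[key][0]:
                per_res[key] = (d, a)
        water_label = f"{w_chain}/{w_res.label}"
        for (k1, (d1, a1)), (k2, (d2, a2)) in itertools.combinations(
            sorted(per_res.items()), 2
        ):
            p1, p2 = a1["partner"], a2["partner"]
            ix = Interaction(
                kind="water-bridge",
                partner1=p1,
                partner2=p2,
                distance=max(d1, d2),
                topology=_topology(p1, p2),
                backbone_class=_backbone_class(p1, p2),
                water_label=water_label,
            )
            edges[(ix.pair_key, water_label)] = ix
    return sorted(edges.values(), key=lambda e: (e.pair_key, e.water_label))


# ---------------------------------------------------------------------------
# loop census


def loop_interaction_summary(
    model: StructureModel,
    loop_chain: str,
    loop_range: tuple[int, int],
    d_strong: float = 3.0,
    d_weak_max: float = 5.0,
    d_min: float = 2.2,
    salt_cutoff: float = 5.0,
    water_d_hb: float = 3.4,
) -> InteractionNetwork:
    """Census of all interactions touching a focal loop.

    Edges with at least one partner in ``loop_chain`` residues
    ``loop_range[0]..loop_range[1]`` (inclusive) are collected.  The summary
    separates intramolecular-within-loop hydrogen bonds (with a
    mainchain–mainchain subcount) from intersubunit bonds; see
    :class:`InteractionNetwork` for the exact count definitions.
    """
    lo, hi = loop_range
    if hi < lo:
        raise ConfigError(f"empty loop range {loop_range}")
    model.chain(loop_chain)  # raises if missing

    def in_loop(p: Partner) -> bool:
        if p.chain != loop_chain:
            return False
        try:
            num = int("".join(ch for ch in p.res_label if ch.isdigit() or ch == "-"))
        except ValueError:
            return False
        return lo <= num <= hi

    hbonds = detect_hbonds(model, d_strong=d_strong, d_weak_max=d_weak_max, d_min=d_min)
    salts = detect_salt_bridges(model, cutoff=salt_cutoff)
    waters = detect_water_bridges(model, d_hb=water_d_hb)
    all_edges = hbonds + salts + waters
    edges = [
        e for e in all_edges if in_loop(e.partner1) or in_loop(e.partner2)
    ]

    def both_in_loop(e: Interaction) -> bool:
        return in_loop(e.partner1) and in_loop(e.partner2)

    intra_strong = [e for e in edges if e.kind == "strong-hbond" and both_in_loop(e)]
    intra_weak = [e for e in edges if e.kind == "weak-hbond" and both_in_loop(e)]
    intra_salt = [e for e in edges if e.kind == "salt-bridge" and both_in_loop(e)]
    inter = [e for e in edges if e.topology == "inter-chain"]
    inter_strong = {e.pair_key for e in inter if e.kind == "strong-hbond"}
    inter_weak = {e.pair_key for e in inter if e.kind == "weak-hbond"}
    inter_salt = {e.pair_key for e in inter if e.kind == "salt-bridge"}
    inter_water = {(e.pair_key, e.water_label) for e in inter if e.kind == "water-bridge"}

    summary = {
        "n_edges": len(edges),
        "n_intra_loop_strong": len(intra_strong),
        "n_intra_loop_weak": len(intra_weak),
        "n_intra_loop_salt": len(intra_salt),
        "n_intra_loop_hbonds": len(intra_strong),
        "n_intra_loop_mainchain_mainchain": sum(
            1 for e in intra_strong if e.backbone_class == "mainchain-mainchain"
        ),
        "n_inter_strong": len(inter_strong),
        "n_inter_weak": len(inter_weak),
        "n_inter_salt": len(inter_salt),
        "n_inter_water": len(inter_water),
        "n_intersubunit_bonds": len(inter_strong | inter_salt),
        "n_intersubunit_pairs_any": len(inter_strong | inter_weak | inter_salt),
    }
    return InteractionNetwork(
        focal_chain=loop_chain,
        focal_range=(lo, hi),
        edges=edges,
        summary=summary,
        thresholds={
            "d_strong": d_strong,
            "d_weak_max": d_weak_max,
            "d_min": d_min,
            "salt_cutoff": salt_cutoff,
            "water_d_hb": water_d_hb,
        },
    )


# ---------------------------------------------------------------------------
# active sites


def active_site_separation(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    site_atoms: dict[str, list[tuple[int, str]]] | None = None,
    element: str = "ZN",
) -> float:
    """Distance between per-chain active-site centroids (Å).

    By default the site of each chain is the centroid of its metal atoms of
    ``element`` (catalytic Zn for alkaline phosphatases); an explicit
    ``site_atoms`` mapping ``chain_id -> [(seq_num, atom_name), ...]``
    overrides this.
    """

    def centroid(chain_id: str) -> np.ndarray:
        chain = model.chain(chain_id)
        coords = []
        if site_atoms is not None:
            for seq_num, atom_name in site_atoms[chain_id]:
                res = chain.residue(seq_num)
                atom = res.atom(atom_name) if res is not None else None
                if atom is None:
                    raise ResidueLookupError(
                        f"chain {chain_id!r}: no atom {atom_name} in residue {seq_num}"
                    )
                coords.append(atom.coords)
        else:
            for res in chain.residues:
                for atom in res.atoms:
                    if atom.element.upper() == element.upper():
                        coords.append(atom.coords)
        if not coords:
            raise ResidueLookupError(
                f"chain {chain_id!r} has no site atoms (element {element})"
            )
        return np.mean(np.array(coords), axis=0)

    return float(np.linalg.norm(centroid(chain_a) - centroid(chain_b)))
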