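"""Synthetic homodimers and simulated datasets with planted ground truth.

Toy structures stand in for crystal structures so that every pipeline stage
(superposition traces, B-factor comparison, interaction census, stability
fits) can be verified offline against quantities known by construction:

* backbones are built in torsion space with ideal bond lengths and angles
  (natural-extension reference-frame construction), so helical hydrogen
  bonding is enumerable in closed form;
* chain B is the rigid image of chain A under a two-fold symmetry rotation,
  then planted displacements are applied to B — chain A stays the pristine
  reference;
* planted donor/acceptor or charged-group atoms are placed at their target
  distances exactly, pointing into (cross-chain pairs) or away from
  (intra-chain pairs) the dimer gap so they create no unintended contacts;
* B-factors follow a planted baseline + bump profile;
* every generator is a pure function of its spec + seed.

Ground truth is serialized as a JSON sidecar next to each written fixture so
tests never re-derive expectations implicitly.

The generators are not physically realistic conformer builders: planted
side-chain atoms may sit far from their residue's backbone.  Only the
distances, classes and labels matter to the analyses under test.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .stability import R_GAS, CELSIUS_OFFSET, InactivationSeries, MeltCurve
from .structure_io import AtomRecord, ChainModel, ResidueRecord, StructureModel

__all__ = [
    "PlantedInteraction",
    "ToyDimerSpec",
    "GroundTruth",
    "make_toy_dimer",
    "simulate_inactivation",
    "simulate_melt",
    "simulate_mm",
]

# ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5

HELIX_PHI, HELIX_PSI = -61.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -140.0, 135.0

#: residue type implied by a planted polar/charged atom name
_ATOM_RESIDUE = {
    "OG": "SER", "OG1": "THR", "OH": "TYR",
    "ND2": "ASN", "OD1": "ASN", "NE2": "GLN", "OE1": "GLN",
    "NZ": "LYS", "NH1": "ARG", "NH2": "ARG", "NE": "ARG",
    "OD2": "ASP", "OE2": "GLU", "NE1": "TRP", "SG": "CYS",
}
#: overrides when the intended class needs a charged group
_SALT_ANION_RESIDUE = {"OD1": "ASP", "OD2": "ASP", "OE1": "GLU", "OE2": "GLU"}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d from internal coordinates w.r.t. chain a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _build_backbone(torsions: Sequence[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N, CA, C, O for each residue from (phi, psi) per residue."""
    n_res = len(torsions)
    if n_res < 2:
        raise GenerationError("need at least 2 residues to build a backbone")
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANG_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(n_res - 1):
        prev = residues[i]
        _, psi = torsions[i]
        phi_next, _ = torsions[i + 1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"],
                             BOND_C_N, ANG_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next,
                              BOND_N_CA, ANG_C_N_CA, 180.0)
        c_next = _place_atom(prev["C"], n_next, ca_next,
                             BOND_CA_C, ANG_N_CA_C, phi_next)
        # carbonyl O of residue i: anti to the next N, in the carbonyl plane
        u1 = prev["CA"] - prev["C"]
        u1 /= np.linalg.norm(u1)
        u2 = n_next - prev["C"]
        u2 /= np.linalg.norm(u2)
        bis = -(u1 + u2)
        prev["O"] = prev["C"] + BOND_C_O * bis / np.linalg.norm(bis)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    last = residues[-1]
    _, psi_last = torsions[-1]
    last["O"] = _place_atom(last["N"], last["CA"], last["C"],
                            BOND_C_O, ANG_CA_C_O, psi_last + 180.0)
    return residues


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


@dataclasses.dataclass
class PlantedInteraction:
    """One planted atom pair at an exact target distance."""

    chain1: str
    res1: int
    atom1: str
    chain2: str
    res2: int
    atom2: str
    distance: float
    kind: str  # intended class: strong-hbond | weak-hbond | salt-bridge
    res1_name: str | None = None
    res2_name: str | None = None
    #: shift of the anchor along the local chain tangent (Å); lets several
    #: pairs hang off one residue without their atoms coinciding
    lateral_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.distance < 2.2:
            raise GenerationError(
                f"target distance {self.distance} below the 2.2 A contact floor"
            )


@dataclasses.dataclass
class ToyDimerSpec:
    """Recipe for a two-chain toy homodimer with planted features.

    ``chain B`` is chain A rotated by ``symmetry_angle_deg`` about
    ``symmetry_axis`` through ``symmetry_point``; displacements, planted
    atoms, metals and waters are applied afterwards.
    """

    n_residues: int = 60
    start_seq: int = 1
    geometry: str = "extended"  # ideal-helix | extended | coil-jitter
    jitter_sigma: float = 0.0  # Å, Cartesian, for coil-jitter
    helical_segments: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    symmetry_angle_deg: float = 180.0
    symmetry_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    symmetry_point: tuple[float, float, float] = (0.0, 0.0, 6.0)
    displacements: list[tuple[tuple[int, int], tuple[float, float, float]]] = (
        dataclasses.field(default_factory=list)
    )
    b_baseline: float = 20.0
    b_bumps: list[tuple[tuple[int, int], float]] = dataclasses.field(default_factory=list)
    planted_interactions: list[PlantedInteraction] = dataclasses.field(default_factory=list)
    metal_sites: dict[str, list[tuple[float, float, float]]] = dataclasses.field(
        default_factory=dict
    )
    waters: list[tuple[float, float, float]] = dataclasses.field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.start_seq, self.start_seq + self.n_residues - 1
        if self.n_residues < 5:
            raise GenerationError("need at least 5 residues per chain")
        if self.geometry not in ("ideal-helix", "extended", "coil-jitter"):
            raise GenerationError(f"unknown geometry {self.geometry!r}")
        for (a, b) in self.helical_segments:
            if not (lo <= a <= b <= hi):
                raise GenerationError(f"helical segment {(a, b)} outside chain {lo}-{hi}")
        for (a, b), _ in list(self.displacements) + list(self.b_bumps):
            if not (lo <= a <= b <= hi):
                raise GenerationError(f"interval {(a, b)} outside chain {lo}-{hi}")
        for p in self.planted_interactions:
            for ch, rs in ((p.chain1, p.res1), (p.chain2, p.res2)):
                if ch not in ("A", "B"):
                    raise GenerationError(f"planted interaction chain {ch!r} not A/B")
                if not (lo <= rs <= hi):
                    raise GenerationError(f"planted residue {rs} outside chain {lo}-{hi}")


@dataclasses.dataclass
class GroundTruth:
    """What the generated dimer is known to contain, by construction."""

    expected_trace: dict[str, float]  # residue label -> planted |offset| (Å)
    expected_b_regions: list[tuple[int, int, float]]  # start, end, amplitude (Å²)
    expected_interactions: list[dict]
    #: backbone mainchain-mainchain strong H-bonds in chain A (direct scan of
    #: the built coordinates; i->i+4 helical bonds plus any boundary bonds)
    expected_helix_mainchain_hbonds: int
    expected_site_separation: float | None
    b_baseline: float
    simulator_params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["expected_b_regions"] = [tuple(x) for x in raw["expected_b_regions"]]
        return cls(**raw)


def _torsion_profile(spec: ToyDimerSpec) -> list[tuple[float, float]]:
    base = (HELIX_PHI, HELIX_PSI) if spec.geometry == "ideal-helix" else (
        EXTENDED_PHI, EXTENDED_PSI
    )
    torsions = [base] * spec.n_residues
    for (a, b) in spec.helical_segments:
        for seq in range(a, b + 1):
            torsions[seq - spec.start_seq] = (HELIX_PHI, HELIX_PSI)
    return torsions


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[StructureModel, GroundTruth]:
    """Build the dimer described by ``spec`` plus its ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`GenerationError` when
    planted constraints conflict (one atom pinned twice inconsistently, or a
    planted atom landing within 2.2 Å of an unrelated atom).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    torsions = _torsion_profile(spec)
    backbone = _build_backbone(torsions)
    if spec.geometry == "coil-jitter" and spec.jitter_sigma > 0:
        for res in backbone:
            for name in res:
                res[name] = res[name] + rng.normal(0.0, spec.jitter_sigma, 3)

    def b_value(seq: int) -> float:
        b = spec.b_baseline
        for (a, bb), amp in spec.b_bumps:
            if a <= seq <= bb:
                b += amp
        return max(b, 0.0)

    def build_chain(chain_id: str, coords: list[dict[str, np.ndarray]]) -> ChainModel:
        chain = ChainModel(chain_id=chain_id)
        for i, res_coords in enumerate(coords):
            seq = spec.start_seq + i
            rec = ResidueRecord(name="ALA", seq_num=seq, kind="polymer")
            for name in ("N", "CA", "C", "O"):
                rec.atoms.append(
                    AtomRecord(
                        name=name,
                        element=name[0],
                        coords=res_coords[name].copy(),
                        bfactor=b_value(seq),
                        occupancy=1.0,
                        is_mainchain=True,
                    )
                )
            chain.residues.append(rec)
        return chain

    chain_a = build_chain("A", backbone)
    rot = _rotation_about_axis(np.array(spec.symmetry_axis), spec.symmetry_angle_deg)
    point = np.array(spec.symmetry_point, dtype=float)
    coords_b = [
        {name: rot @ (xyz - point) + point for name, xyz in res.items()}
        for res in backbone
    ]
    chain_b = build_chain("B", coords_b)

    # planted displacements: rigid offsets applied to chain-B intervals
    for (a, b), offset in spec.displacements:
        off = np.asarray(offset, dtype=float)
        for res in chain_b.residues:
            if a <= res.seq_num <= b:
                for atom in res.atoms:
                    atom.coords = atom.coords + off

    model = StructureModel(structure_id=f"toy-dimer-seed{spec.seed}",
                           chains=[chain_a, chain_b])

    # planted interactions; directions follow the local across-dimer axis
    # (from a residue's CA to the CA of its symmetry image), so planted atoms
    # point into the gap (cross-chain pairs) or away from it (intra pairs)
    chains = {"A": chain_a, "B": chain_b}

    def across_axis(chain_id: str, seq: int) -> tuple[np.ndarray, np.ndarray]:
        other = "B" if chain_id == "A" else "A"
        chain = chains[chain_id]
        here = chain.residue(seq).ca.coords
        image = chains[other].residue(seq).ca.coords
        v = image - here
        # remove the component along the local chain direction so planted
        # atoms leave the backbone perpendicularly even where it curves
        neighbours = [chain.residue(seq - 1), chain.residue(seq + 1)]
        pts = [r.ca.coords for r in neighbours if r is not None and r.ca is not None]
        if len(pts) == 2:
            tangent = pts[1] - pts[0]
        elif len(pts) == 1:
            tangent = pts[0] - here
        else:
            tangent = np.zeros(3)
        t_norm = np.linalg.norm(tangent)
        if t_norm > 1e-6:
            tangent = tangent / t_norm
            v = v - np.dot(v, tangent) * tangent
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            raise GenerationError(
                f"residue {chain_id}/{seq} lies on the symmetry axis; "
                "cannot orient a planted interaction there"
            )
        return v / norm, tangent
    placed: dict[tuple[str, int, str], np.ndarray] = {}
    truth_interactions: list[dict] = []

    def plant_atom(chain_id: str, seq: int, atom_name: str,
                   position: np.ndarray, res_name: str | None) -> None:
        key = (chain_id, seq, atom_name)
        if key in placed:
            if np.linalg.norm(placed[key] - position) > 1e-6:
                raise GenerationError(
                    f"atom {key} pinned by two conflicting planted constraints"
                )
            return
        res = chains[chain_id].residue(seq)
        want_name = res_name or _ATOM_RESIDUE.get(atom_name)
        if want_name:
            if res.name not in ("ALA", want_name):
                raise GenerationError(
                    f"residue {chain_id}/{seq} needed as both {res.name} and {want_name}"
                )
            res.name = want_name
        res.atoms.append(
            AtomRecord(
                name=atom_name,
                element=atom_name[0],
                coords=position,
                bfactor=b_value(seq),
                occupancy=1.0,
                is_mainchain=False,
            )
        )
        placed[key] = position

    anchor_offset = 4.5  # Å off the backbone, clear of the strong-bond class
    for p in spec.planted_interactions:
        ca1 = chains[p.chain1].residue(p.res1).ca.coords
        direction, tangent = across_axis(p.chain1, p.res1)
        if p.chain1 == p.chain2:
            direction = -direction
        anchor = ca1 + anchor_offset * direction + p.lateral_shift * tangent
        partner = anchor + p.distance * direction
        res1_name = p.res1_name
        res2_name = p.res2_name
        if p.kind == "salt-bridge":
            res1_name = res1_name or _ATOM_RESIDUE.get(p.atom1)
            res2_name = res2_name or _SALT_ANION_RESIDUE.get(p.atom2)
        plant_atom(p.chain1, p.res1, p.atom1, anchor, res1_name)
        plant_atom(p.chain2, p.res2, p.atom2, partner, res2_name)
        realized = float(np.linalg.norm(anchor - partner))
        if abs(realized - p.distance) > 1e-3:
            raise GenerationError(
                f"planted pair {p} realized at {realized:.4f} A, wanted {p.distance}"
            )
        truth_interactions.append(
            {
                "kind": p.kind,
                "chain1": p.chain1, "res1": p.res1, "atom1": p.atom1,
                "chain2": p.chain2, "res2": p.res2, "atom2": p.atom2,
                "distance": p.distance,
                "topology": "intra-chain" if p.chain1 == p.chain2 else "inter-chain",
            }
        )

    # planted atoms must not collide with anything else
    all_coords = []
    all_keys = []
    for c, r, a in model.atoms():
        all_coords.append(a.coords)
        all_keys.append((c.chain_id, r.seq_num, a.name))
    all_coords = np.array(all_coords)
    for key, pos in placed.items():
        d = np.linalg.norm(all_coords - pos, axis=1)
        for i in np.nonzero(d < 2.2)[0]:
            if all_keys[i] != key:
                raise GenerationError(
                    f"planted atom {key} within 2.2 A of {all_keys[i]}"
                )

    # metals and waters
    for chain_id, sites in spec.metal_sites.items():
        chain = chains[chain_id]
        for j, xyz in enumerate(sites):
            rec = ResidueRecord(name="ZN", seq_num=900 + j, kind="metal")
            rec.atoms.append(
                AtomRecord(name="ZN", element="ZN", coords=np.asarray(xyz, float),
                           bfactor=spec.b_baseline, occupancy=1.0)
            )
            chain.residues.append(rec)
    if spec.waters:
        w_chain = ChainModel(chain_id="W")
        for j, xyz in enumerate(spec.waters):
            rec = ResidueRecord(name="HOH", seq_num=j + 1, kind="water")
            rec.atoms.append(
                AtomRecord(name="O", element="O", coords=np.asarray(xyz, float),
                           bfactor=spec.b_baseline, occupancy=1.0)
            )
            w_chain.residues.append(rec)
        model.chains.append(w_chain)

    site_sep = None
    if "A" in spec.metal_sites and "B" in spec.metal_sites:
        ca_ = np.mean(np.array(spec.metal_sites["A"], dtype=float), axis=0)
        cb_ = np.mean(np.array(spec.metal_sites["B"], dtype=float), axis=0)
        site_sep = float(np.linalg.norm(ca_ - cb_))

    trace = {}
    for res in chain_a.residues:
        if res.kind != "polymer":
            continue
        off = np.zeros(3)
        for (a, b), offset in spec.displacements:
            if a <= res.seq_num <= b:
                off = off + np.asarray(offset, dtype=float)
        trace[res.label] = float(np.linalg.norm(off))

    # backbone mainchain-mainchain strong bonds of chain A, by direct scan
    # (helix boundaries can add bonds beyond the naive per-segment count)
    helix_hbonds = 0
    res_a = chain_a.polymer_residues()
    for i, ri in enumerate(res_a):
        for rj in res_a[i + 2:]:
            for x, y in ((ri.atom("O"), rj.atom("N")), (ri.atom("N"), rj.atom("O"))):
                if (x is not None and y is not None
                        and np.linalg.norm(x.coords - y.coords) < 3.0):
                    helix_hbonds += 1

    truth = GroundTruth(
        expected_trace=trace,
        expected_b_regions=[(a, b, amp) for (a, b), amp in spec.b_bumps],
        expected_interactions=truth_interactions,
        expected_helix_mainchain_hbonds=helix_hbonds,
        expected_site_separation=site_sep,
        b_baseline=spec.b_baseline,
        seed=spec.seed,
    )
    return model, truth


# ---------------------------------------------------------------------------
# dataset simulators


def simulate_inactivation(
    ea_kj_mol: float,
    ln_a: float,
    temperatures_c: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> InactivationSeries:
    """Arrhenius-law inactivation rate constants with lognormal noise.

    k(T) = exp(lnA − Ea·1000/(R·T)) · exp(σ·ε), ε ~ N(0, 1), deterministic
    for a given seed.
    """
    if ea_kj_mol <= 0:
        raise GenerationError("activation energy must be positive")
    temps = np.asarray(temperatures_c, dtype=float)
    if temps.size < 3:
        raise GenerationError("need at least 3 temperatures")
    t_k = temps + CELSIUS_OFFSET
    k = np.exp(ln_a - ea_kj_mol * 1000.0 / (R_GAS * t_k))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        k = k * np.exp(rng.normal(0.0, noise_sigma, size=k.shape))
    return InactivationSeries(temperature_k=t_k, k_per_s=k, label=label)


def simulate_melt(
    tm_c: float,
    steepness_per_c: float = 0.5,
    folded_baseline: tuple[float, float] = (-1.0, 0.0),
    unfolded_baseline: tuple[float, float] = (0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    temperature_grid: Sequence[float] | None = None,
) -> MeltCurve:
    """Two-state sigmoid melt trace with linear baselines and Gaussian noise.

    ``noise_sigma`` is a fraction of the transition amplitude.  The default
    grid is 20–90 °C in 0.5 °C steps (a 1 °C·min⁻¹ CD ramp sampled twice a
    degree).
    """
    t = (np.arange(20.0, 90.0 + 1e-9, 0.5) if temperature_grid is None
         else np.asarray(temperature_grid, dtype=float))
    if np.any(np.diff(t) <= 0):
        raise GenerationError("temperature grid must be strictly increasing")
    af, bf = folded_baseline
    au, bu = unfolded_baseline
    width = 1.0 / steepness_per_c
    f_u = 1.0 / (1.0 + np.exp(-(t - tm_c) / width))
    signal = (af + bf * t) * (1 - f_u) + (au + bu * t) * f_u
    amplitude = abs((au + bu * tm_c) - (af + bf * tm_c))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma * amplitude, size=t.shape)
    return MeltCurve(temperature_c=t, signal=signal)


def simulate_mm(
    kcat_per_s: float,
    km_mm: float,
    enzyme_conc: float = 1.0,
    substrate_grid_mm: Sequence[float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis–Menten rate table with relative Gaussian noise.

    The default substrate grid is a doubling series over 0.0125–1.0 mM,
    bracketing a KM of ~0.2 mM from both sides.  Returns a DataFrame with
    columns ``substrate_mM`` and ``rate``.
    """
    s = (np.array([0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0])
         if substrate_grid_mm is None else np.asarray(substrate_grid_mm, dtype=float))
    if np.any(s <= 0):
        raise GenerationError("substrate concentrations must be positive")
    vmax = kcat_per_s * enzyme_conc
    v = vmax * s / (km_mm + s)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_sigma, size=s.shape))
    return pd.DataFrame({"substrate_mM": s, "rate": v})
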