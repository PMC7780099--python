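"""Shared fixtures: small planted dimers and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dimerflex.interactions import ACCEPTORS, DONORS
from dimerflex.synthetic import PlantedInteraction, ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="session")
def symmetric_dimer():
    """A perfectly two-fold-symmetric extended dimer (no planted features)."""
    spec = ToyDimerSpec(n_residues=50, geometry="extended", seed=1)
    return make_toy_dimer(spec)


@pytest.fixture(scope="session")
def displaced_dimer():
    """Chain B carries a 1.0 Å rigid offset on residues 140-145.

    The chain is long (300 residues) and the displaced stretch sits
    mid-chain, so the rigid fit cannot absorb or tilt away a meaningful part
    of the planted offset and per-residue recovery is sharp.
    """
    spec = ToyDimerSpec(
        n_residues=300,
        geometry="extended",
        displacements=[((140, 145), (0.0, 1.0, 0.0))],
        seed=2,
    )
    return make_toy_dimer(spec)


@pytest.fixture(scope="session")
def helix_dimer():
    """An ideal-helix dimer: i->i+4 backbone H-bonds known in closed form."""
    spec = ToyDimerSpec(n_residues=20, geometry="ideal-helix", seed=3)
    return make_toy_dimer(spec)


@pytest.fixture(scope="session")
def planted_contacts_dimer():
    """Extended dimer with one intra strong, one cross strong, one cross weak
    H-bond and one cross salt bridge planted at exact distances."""
    spec = ToyDimerSpec(
        n_residues=40,
        geometry="extended",
        planted_interactions=[
            PlantedInteraction("A", 8, "OG", "A", 10, "OD1", 2.8, "strong-hbond"),
            PlantedInteraction("A", 16, "OG", "B", 20, "OD1", 2.8, "strong-hbond"),
            PlantedInteraction("A", 24, "OG", "B", 28, "OD1", 4.0, "weak-hbond"),
            PlantedInteraction("A", 32, "NH1", "B", 36, "OD1", 3.5, "salt-bridge"),
        ],
        metal_sites={"A": [(5.0, -20.0, 0.0)], "B": [(5.0, -20.0, 10.0)]},
        seed=4,
    )
    return make_toy_dimer(spec)


# ---------------------------------------------------------------------------
# independent oracles (plain all-pairs scans, no spatial indexing)


def _polar_atom_list(model):
    out = []
    for chain in model.chains:
        for res in chain.residues:
            if res.kind != "polymer":
                continue
            for atom in res.atoms:
                donor = (
                    atom.name in DONORS.get(res.name, ())
                    or (atom.name == "N" and res.name != "PRO")
                )
                acceptor = (
                    atom.name in ACCEPTORS.get(res.name, ())
                    or atom.name in ("O", "OXT")
                )
                if donor or acceptor:
                    out.append(
                        (chain.chain_id, res.seq_num, res.label, atom, donor, acceptor)
                    )
    return out


def brute_force_hbond_pairs(model, d_strong=3.0, d_weak_max=5.0, d_min=2.2):
    """Exhaustive all-pairs hydrogen-bond scan; returns {frozenset_key: (kind, d)}."""
    atoms = _polar_atom_list(model)
    found = {}
    for (c1, s1, l1, a1, don1, acc1), (c2, s2, l2, a2, don2, acc2) in (
        itertools.combinations(atoms, 2)
    ):
        if (c1, s1) == (c2, s2):
            continue
        if not ((don1 and acc2) or (acc1 and don2)):
            continue
        d = float(np.linalg.norm(a1.coords - a2.coords))
        if d < d_min or d > d_weak_max:
            continue
        if (
            a1.is_mainchain and a2.is_mainchain and c1 == c2
            and abs(s1 - s2) == 1 and {a1.name, a2.name} == {"N", "O"}
            and d < 2.6
        ):
            continue
        kind = "strong-hbond" if d < d_strong else "weak-hbond"
        key = frozenset([(c1, l1, a1.name), (c2, l2, a2.name)])
        found[key] = (kind, d)
    return found


def brute_force_min_group_distance(res_a_atoms, res_b_atoms):
    """Exhaustive minimum distance over two atom groups."""
    return min(
        float(np.linalg.norm(a.coords - b.coords))
        for a in res_a_atoms
        for b in res_b_atoms
    )


def brute_force_best_rotation_rmsd(coords_a, coords_b, n_grid=20, n_refine=40):
    """Minimum RMSD over rigid motions by direct search over rotations.

    Centers both sets, scans a coarse Euler-angle grid, then polishes the
    best candidates with Nelder-Mead.  Independent of the SVD solution.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        diff = a0 - b0 @ r.T
        return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    candidates = sorted(
        ((rmsd_of([z, y, x]), [z, y, x])
         for z in grid for y in grid[: n_grid // 2] for x in grid),
    )[:n_refine]
    best = np.inf
    for _, start in candidates:
        res = minimize(rmsd_of, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best
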