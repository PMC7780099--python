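"""Validation recipes for user-supplied crystal structures.

Given a homodimeric structure file (and optionally a second, variant
structure expanded to the same dimer or supplied as a monomer), these
recipes run the standard analysis battery and return a plain dict of
headline numbers.  They are intended for checking the pipeline against
deposited coordinates the user has downloaded; nothing in the offline test
suite depends on them.
"""

from __future__ import annotations

from pathlib import Path

from .bfactor import structure_mean_bfactor
from .interactions import (
    active_site_separation,
    detect_salt_bridges,
    loop_interaction_summary,
)
from .structure_io import read_structure
from .superposition import compare_structures, superpose_chains

__all__ = ["validate_dimer", "validate_pair"]


def validate_dimer(
    path: str | Path,
    chain_a: str = "A",
    chain_b: str = "B",
    loop_range: tuple[int, int] = (324, 354),
) -> dict:
    """Headline analysis of one homodimer structure file.

    Returns pooled/mean main-chain asymmetry of chain B on chain A, the
    loop interaction census, inter-chain salt bridges touching the loop, the
    metal-centroid separation, and the mean protein B-factor.
    """
    model = read_structure(path)
    result, trace = superpose_chains(model, chain_a, chain_b)
    network = loop_interaction_summary(model, chain_a, loop_range)
    lo, hi = loop_range
    loop_salts = [
        {
            "partner1": e.partner1.key(),
            "partner2": e.partner2.key(),
            "distance_angstrom": round(e.distance, 2),
        }
        for e in detect_salt_bridges(model)
        if e.topology == "inter-chain"
        and any(
            p.chain == chain_a and lo <= int(p.res_label) <= hi
            for p in (e.partner1, e.partner2)
        )
    ]
    out = {
        "deviation_rms_angstrom": trace.rms,
        "deviation_mean_angstrom": trace.mean,
        "fit_rmsd_angstrom": result.rmsd,
        "loop_summary": network.summary,
        "thresholds": network.thresholds,
        "interchain_loop_salt_bridges": loop_salts,
        "mean_protein_bfactor_A2": structure_mean_bfactor(model),
    }
    try:
        out["active_site_separation_angstrom"] = active_site_separation(
            model, chain_a, chain_b
        )
    except Exception:
        out["active_site_separation_angstrom"] = None
    return out


def validate_pair(
    path_reference: str | Path,
    path_other: str | Path,
    chain_reference: str = "A",
    chain_other: str = "A",
) -> dict:
    """Cross-structure main-chain comparison (e.g. variant onto wild-type)."""
    ref = read_structure(path_reference)
    other = read_structure(path_other)
    result, trace = compare_structures(ref, chain_reference, other, chain_other)
    return {
        "deviation_rms_angstrom": trace.rms,
        "deviation_mean_angstrom": trace.mean,
        "fit_rmsd_angstrom": result.rmsd,
        "n_atoms_fit": result.n_atoms,
        "mean_protein_bfactor_other_A2": structure_mean_bfactor(other),
    }
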