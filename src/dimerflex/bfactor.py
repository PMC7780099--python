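"""Per-residue B-factor profiles, normalization and flexibility comparison.

Crystallographic B-factors (Å²) report positional disorder; comparing them
between two structures requires normalization because overall B scales with
resolution, refinement protocol and crystal quality.  Here each per-residue
profile is divided by its own maximum, after which a localized increase in
relative mobility appears as a contiguous run of positive differences.

Worm scores map normalized B onto a tube radius for structure viewers:
values at or below the 5th percentile render at 0.3 Å, at or above the 95th
at 1.25 Å, with 0.80 Å at the midpoint of the percentile band and linear
interpolation on either side of it.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .errors import ConfigError, EmptyModelError
from .structure_io import MAINCHAIN_ATOMS, StructureModel

__all__ = [
    "BFactorProfile",
    "NormalizedProfile",
    "FlexibilityComparison",
    "WormScore",
    "residue_bfactor_profile",
    "normalize_profile",
    "compare_flexibility",
    "worm_scores",
    "smooth_profile",
]

Aggregation = Literal["mainchain-mean", "all-atom-mean", "CA-only"]

WORM_LO = 0.3  # Å, at/below the 5th percentile
WORM_MID = 0.80  # Å, at the midpoint of the percentile band
WORM_HI = 1.25  # Å, at/above the 95th percentile


@dataclasses.dataclass
class BFactorProfile:
    """Ordered (residue label, aggregated B / Å²) pairs for one chain."""

    entries: list[tuple[str, float]]
    aggregation: Aggregation
    n_skipped: int = 0  # residues lacking the aggregation atom set

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# aggregation\t{self.aggregation}\n")
            fh.write("residue_label\tbfactor_A2\n")
            for lab, v in self.entries:
                fh.write(f"{lab}\t{v:.4f}\n")


@dataclasses.dataclass
class NormalizedProfile:
    """Profile divided by its own maximum; max entry is exactly 1."""

    entries: list[tuple[str, float]]
    normalizer: float  # Å², the maximum that was divided out

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalizer_A2\t{self.normalizer:.4f}\n")
            fh.write("residue_label\tnormalized_b\n")
            for lab, v in self.entries:
                fh.write(f"{lab}\t{v:.6f}\n")


@dataclasses.dataclass
class FlexibilityComparison:
    """Pointwise normalized-B differences plus flagged differential regions.

    A flagged region is a maximal run of >= ``min_run`` consecutive common
    residues whose difference keeps one sign and magnitude >= ``threshold``.
    """

    entries: list[tuple[str, float, float, float]]  # label, bX, bY, bX - bY
    regions: list[tuple[str, str, float]]  # start label, end label, mean diff
    threshold: float
    min_run: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold\t{self.threshold}\n")
            fh.write(f"# min_run\t{self.min_run}\n")
            fh.write("residue_label\tnorm_b_x\tnorm_b_y\tdifference\n")
            for lab, bx, by, d in self.entries:
                fh.write(f"{lab}\t{bx:.6f}\t{by:.6f}\t{d:.6f}\n")

    def regions_to_bed(self, path) -> None:
        """BED-like 3 columns; residue numbers are 1-based and inclusive."""
        with open(path, "w") as fh:
            fh.write("# start_residue and end_residue are author residue "
                     "numbers, 1-based, inclusive\n")
            fh.write("start_residue\tend_residue\tmean_difference\n")
            for start, end, mean_d in self.regions:
                fh.write(f"{start}\t{end}\t{mean_d:.6f}\n")


@dataclasses.dataclass
class WormScore:
    """Tube radii (Å) derived from normalized B by percentile mapping."""

    entries: list[tuple[str, float]]
    lo: float = WORM_LO
    hi: float = WORM_HI

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])


def residue_bfactor_profile(
    model: StructureModel,
    chain_id: str,
    aggregation: Aggregation = "mainchain-mean",
) -> BFactorProfile:
    """Aggregate atomic B-factors per polymer residue of one chain.

    ``mainchain-mean`` averages N, CA, C, O; ``all-atom-mean`` averages every
    heavy atom; ``CA-only`` takes the CA value.  Residues lacking the atom
    set are skipped and counted.
    """
    if aggregation not in ("mainchain-mean", "all-atom-mean", "CA-only"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    chain = model.chain(chain_id)
    entries: list[tuple[str, float]] = []
    skipped = 0
    for res in chain.polymer_residues():
        if aggregation == "CA-only":
            atoms = [res.ca] if res.ca is not None else []
        elif aggregation == "mainchain-mean":
            atoms = [a for a in res.atoms if a.name in MAINCHAIN_ATOMS]
        else:
            atoms = list(res.atoms)
        if not atoms:
            skipped += 1
            continue
        entries.append((res.label, float(np.mean([a.bfactor for a in atoms]))))
    if not entries:
        raise EmptyModelError(
            f"chain {chain_id!r} has no residues with {aggregation} atoms"
        )
    return BFactorProfile(entries=entries, aggregation=aggregation, n_skipped=skipped)


def structure_mean_bfactor(model: StructureModel, kinds: tuple[str, ...] = ("polymer",)) -> float:
    """Mean B over all atoms of the given residue kinds (whole structure)."""
    values = [
        a.bfactor for _, r, a in model.atoms() if r.kind in kinds
    ]
    if not values:
        raise EmptyModelError(f"no atoms of kinds {kinds}")
    return float(np.mean(values))


def normalize_profile(profile: BFactorProfile | NormalizedProfile) -> NormalizedProfile:
    """Divide a profile by its maximum; idempotent on already-normalized input."""
    values = profile.values
    if values.size == 0:
        raise EmptyModelError("cannot normalize an empty profile")
    peak = float(values.max())
    if peak <= 0:
        raise ConfigError("profile maximum is zero; cannot normalize")
    labels = profile.labels
    return NormalizedProfile(
        entries=[(lab, float(v / peak)) for lab, v in zip(labels, values)],
        normalizer=peak,
    )


def smooth_profile(profile: BFactorProfile, window: int = 3) -> BFactorProfile:
    """Centered moving mean; window must be odd. Edges use a shrunk window."""
    if window < 1 or window % 2 == 0:
        raise ConfigError("smoothing window must be a positive odd integer")
    values = profile.values
    half = window // 2
    out = []
    for i, (lab, _) in enumerate(profile.entries):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out.append((lab, float(values[lo:hi].mean())))
    return BFactorProfile(entries=out, aggregation=profile.aggregation,
                          n_skipped=profile.n_skipped)


def compare_flexibility(
    prof_x: NormalizedProfile,
    prof_y: NormalizedProfile,
    threshold: float = 0.10,
    min_run: int = 5,
) -> FlexibilityComparison:
    """Pointwise difference of two normalized profiles with region calls.

    Differences are ``x - y`` on the residue labels common to both profiles
    (in X's order).  Maximal runs of >= ``min_run`` consecutive residues
    whose difference keeps one sign with magnitude >= ``threshold`` are
    flagged.
    """
    if threshold <= 0 or min_run < 1:
        raise ConfigError("threshold must be > 0 and min_run >= 1")
    y_map = dict(prof_y.entries)
    common = [(lab, bx, y_map[lab]) for lab, bx in prof_x.entries if lab in y_map]
    if len(common) < 10:
        raise ConfigError(
            f"profiles share only {len(common)} residues (need >= 10)"
        )
    entries = [(lab, bx, by, bx - by) for lab, bx, by in common]

    regions: list[tuple[str, str, float]] = []
    run: list[tuple[str, float]] = []
    run_sign = 0

    def flush() -> None:
        nonlocal run, run_sign
        if len(run) >= min_run:
            diffs = [d for _, d in run]
            regions.append((run[0][0], run[-1][0], float(np.mean(diffs))))
        run = []
        run_sign = 0

    for lab, _, _, d in entries:
        sign = 1 if d >= threshold else (-1 if d <= -threshold else 0)
        if sign != 0 and sign == run_sign:
            run.append((lab, d))
        else:
            flush()
            if sign != 0:
                run = [(lab, d)]
                run_sign = sign
    flush()
    return FlexibilityComparison(
        entries=entries, regions=regions, threshold=threshold, min_run=min_run
    )


def worm_scores(profile: NormalizedProfile) -> WormScore:
    """Map normalized B to worm radii via the 5th/95th percentile band.

    Values at/below the 5th percentile map to 0.3 Å, at/above the 95th to
    1.25 Å, the band midpoint to 0.80 Å, piecewise-linear in between.  A
    constant profile (degenerate band) maps everything to the 0.80 Å
    mid-score.
    """
    values = profile.values
    if values.size == 0:
        raise EmptyModelError("cannot score an empty profile")
    p5, p95 = np.percentile(values, [5.0, 95.0])
    if p95 - p5 <= 1e-12:
        radii = np.full_like(values, WORM_MID)
    else:
        mid = 0.5 * (p5 + p95)
        radii = np.where(
            values <= mid,
            WORM_LO + (values - p5) / (mid - p5) * (WORM_MID - WORM_LO),
            WORM_MID + (values - mid) / (p95 - mid) * (WORM_HI - WORM_MID),
        )
        radii = np.clip(radii, WORM_LO, WORM_HI)
    return WormScore(entries=[(lab, float(r)) for lab, r in zip(profile.labels, radii)])
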