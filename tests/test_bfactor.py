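"""B-factor profiles, normalization, differential regions and worm scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerflex import (
    compare_flexibility,
    normalize_profile,
    residue_bfactor_profile,
    worm_scores,
)
from dimerflex.bfactor import (
    BFactorProfile,
    NormalizedProfile,
    smooth_profile,
    structure_mean_bfactor,
)
from dimerflex.errors import ConfigError, EmptyModelError
from dimerflex.structure_io import AtomRecord, ChainModel, ResidueRecord, StructureModel
from dimerflex.synthetic import ToyDimerSpec, make_toy_dimer


def profile_from(values, labels=None):
    labels = labels or [str(i + 1) for i in range(len(values))]
    return BFactorProfile(
        entries=list(zip(labels, map(float, values))), aggregation="mainchain-mean"
    )


def norm_from(values, labels=None):
    labels = labels or [str(i + 1) for i in range(len(values))]
    peak = max(values)
    return NormalizedProfile(
        entries=[(l, v / peak) for l, v in zip(labels, values)], normalizer=peak
    )


def chain_with_bfactors(bmap):
    """One-chain structure; residue i gets 4 mainchain atoms at B = bmap[i]."""
    chain = ChainModel(chain_id="A")
    for seq, b in bmap.items():
        res = ResidueRecord(name="ALA", seq_num=seq)
        for j, name in enumerate(("N", "CA", "C", "O")):
            res.atoms.append(
                AtomRecord(name=name, element=name[0],
                           coords=np.array([seq * 4.0 + j, 0.0, 0.0]),
                           bfactor=float(b), is_mainchain=True)
            )
        chain.residues.append(res)
    return StructureModel("btest", [chain])


class TestProfiles:
    def test_constant_bfactors_constant_profile(self):
        model = chain_with_bfactors({i: 20.0 for i in range(1, 11)})
        prof = residue_bfactor_profile(model, "A")
        assert np.allclose(prof.values, 20.0)

    def test_mainchain_mean_arithmetic(self):
        model = chain_with_bfactors({1: 0.0, 2: 0.0})
        res = model.chain("A").residues[0]
        for atom, b in zip(res.atoms, (10.0, 20.0, 30.0, 40.0)):
            atom.bfactor = b
        prof = residue_bfactor_profile(model, "A", "mainchain-mean")
        assert prof.values[0] == pytest.approx(25.0)

    def test_all_atom_mean_matches_direct_average(self, planted_contacts_dimer):
        """Whole-structure polymer mean equals a direct average over atoms."""
        model, _ = planted_contacts_dimer
        direct = np.mean(
            [a.bfactor for _, r, a in model.atoms() if r.kind == "polymer"]
        )
        assert structure_mean_bfactor(model) == pytest.approx(direct, abs=1e-12)

    def test_empty_chain_errors(self):
        model = StructureModel("x", [ChainModel(chain_id="A")])
        with pytest.raises(EmptyModelError):
            residue_bfactor_profile(model, "A")


class TestNormalization:
    def test_simple_division(self):
        norm = normalize_profile(profile_from([10, 20, 40]))
        assert np.allclose(norm.values, [0.25, 0.5, 1.0])
        assert norm.normalizer == pytest.approx(40.0)

    def test_constant_profile_all_ones(self):
        norm = normalize_profile(profile_from([7.0] * 5))
        assert np.allclose(norm.values, 1.0)

    def test_scale_invariance(self):
        base = profile_from([3.0, 9.0, 27.0])
        scaled = profile_from([v * 13.7 for v in base.values])
        assert np.allclose(
            normalize_profile(base).values, normalize_profile(scaled).values
        )

    def test_idempotent(self):
        once = normalize_profile(profile_from([5, 10, 15]))
        twice = normalize_profile(once)
        assert np.array_equal(once.values, twice.values)

    def test_zero_max_errors(self):
        with pytest.raises(ConfigError):
            normalize_profile(profile_from([0.0, 0.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 200.0), min_size=1, max_size=60))
    def test_max_is_exactly_one(self, values):
        norm = normalize_profile(profile_from(values))
        assert norm.values.max() == 1.0
        assert norm.values.min() >= 0.0


class TestFlexibilityComparison:
    def test_identical_profiles_no_regions(self):
        p = norm_from(list(range(1, 31)))
        comp = compare_flexibility(p, p)
        assert comp.regions == []
        assert all(d == 0.0 for _, _, _, d in comp.entries)

    def test_planted_offset_region_exact(self):
        """+0.15 offset on residues 81-100 flags exactly that interval."""
        labels = [str(i) for i in range(50, 150)]
        base = [0.5] * 100
        bumped = [
            0.65 if 81 <= int(l) <= 100 else 0.5 for l in labels
        ]
        px = NormalizedProfile(entries=list(zip(labels, bumped)), normalizer=1.0)
        py = NormalizedProfile(entries=list(zip(labels, base)), normalizer=1.0)
        comp = compare_flexibility(px, py, threshold=0.1, min_run=5)
        assert len(comp.regions) == 1
        start, end, mean_d = comp.regions[0]
        assert (start, end) == ("81", "100")
        assert mean_d == pytest.approx(0.15)

    def test_subthreshold_offset_no_regions(self):
        labels = [str(i) for i in range(1, 41)]
        py = NormalizedProfile(entries=[(l, 0.5) for l in labels], normalizer=1.0)
        px = NormalizedProfile(entries=[(l, 0.55) for l in labels], normalizer=1.0)
        comp = compare_flexibility(px, py, threshold=0.1, min_run=5)
        assert comp.regions == []

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        labels = [str(i) for i in range(1, 61)]
        vx = rng.uniform(0.2, 1.0, 60)
        vy = rng.uniform(0.2, 1.0, 60)
        px = NormalizedProfile(entries=list(zip(labels, vx)), normalizer=1.0)
        py = NormalizedProfile(entries=list(zip(labels, vy)), normalizer=1.0)
        fwd = compare_flexibility(px, py, threshold=0.15, min_run=3)
        rev = compare_flexibility(py, px, threshold=0.15, min_run=3)
        assert [(l, -d) for l, _, _, d in fwd.entries] == [
            (l, d) for l, _, _, d in rev.entries
        ]
        assert [(s, e) for s, e, _ in fwd.regions] == [(s, e) for s, e, _ in rev.regions]
        for (_, _, d1), (_, _, d2) in zip(fwd.regions, rev.regions):
            assert d1 == pytest.approx(-d2)

    def test_flagged_region_mean_exceeds_threshold(self):
        rng = np.random.default_rng(7)
        labels = [str(i) for i in range(1, 101)]
        vx = rng.uniform(0.0, 1.0, 100)
        vy = rng.uniform(0.0, 1.0, 100)
        px = NormalizedProfile(entries=list(zip(labels, vx)), normalizer=1.0)
        py = NormalizedProfile(entries=list(zip(labels, vy)), normalizer=1.0)
        comp = compare_flexibility(px, py, threshold=0.2, min_run=2)
        for _, _, mean_d in comp.regions:
            assert abs(mean_d) >= comp.threshold

    def test_insufficient_overlap_errors(self):
        px = norm_from([1, 2, 3])
        py = norm_from([1, 2, 3])
        with pytest.raises(ConfigError):
            compare_flexibility(px, py)

    def test_planted_bump_on_structures_within_two_residues(self):
        """End-to-end: planted B bump recovered at threshold = amplitude/2."""
        flat = ToyDimerSpec(n_residues=80, b_baseline=20.0,
                            b_bumps=[((60, 70), 30.0)], seed=8)
        bumped = ToyDimerSpec(n_residues=80, b_baseline=20.0,
                              b_bumps=[((60, 70), 30.0), ((25, 40), 10.0)], seed=8)
        m_flat, _ = make_toy_dimer(flat)
        m_bump, truth = make_toy_dimer(bumped)
        pf = normalize_profile(residue_bfactor_profile(m_flat, "A"))
        pb = normalize_profile(residue_bfactor_profile(m_bump, "A"))
        amplitude = 10.0 / pb.normalizer  # planted amplitude, normalized
        comp = compare_flexibility(pb, pf, threshold=amplitude / 2, min_run=5)
        assert len(comp.regions) == 1
        start, end, _ = comp.regions[0]
        assert abs(int(start) - 25) <= 2 and abs(int(end) - 40) <= 2


class TestWormScores:
    def test_constant_profile_maps_to_midscore(self):
        ws = worm_scores(norm_from([5.0] * 10))
        assert np.allclose(ws.values, 0.80)

    def test_hundred_equally_spaced_values(self):
        values = np.linspace(1.0, 100.0, 100)
        ws = worm_scores(norm_from(list(values)))
        assert np.allclose(ws.values[:5], 0.3)
        assert np.allclose(ws.values[-5:], 1.25)
        assert 0.3 < ws.values[50] < 1.25

    def test_band_midpoint_maps_to_080(self):
        values = list(np.linspace(0.0, 1.0, 101))
        norm = NormalizedProfile(
            entries=[(str(i), v) for i, v in enumerate(values)], normalizer=1.0
        )
        ws = worm_scores(norm)
        p5, p95 = np.percentile(values, [5, 95])
        mid = 0.5 * (p5 + p95)
        idx = int(np.argmin(np.abs(np.asarray(values) - mid)))
        assert ws.values[idx] == pytest.approx(0.80, abs=0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=80))
    def test_clamped_and_monotone(self, values):
        norm = normalize_profile(profile_from(values))
        ws = worm_scores(norm)
        assert ws.values.min() >= 0.3 - 1e-12
        assert ws.values.max() <= 1.25 + 1e-12
        order = np.argsort(norm.values, kind="stable")
        radii_sorted = ws.values[order]
        assert np.all(np.diff(radii_sorted) >= -1e-12)


def test_smoothing_preserves_length_and_mean_locality():
    prof = profile_from([0, 0, 10, 0, 0])
    sm = smooth_profile(prof, window=3)
    assert len(sm.entries) == 5
    assert sm.values[2] == pytest.approx(10 / 3)
    with pytest.raises(ConfigError):
        smooth_profile(prof, window=2)
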