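# Methods

## Scope and model

The package analyses homodimeric enzyme crystal structures along four axes:
rigid-body asymmetry between chemically identical monomers, relative
crystallographic mobility (B-factors), the noncovalent network tying an
interface loop to the partner subunit, and solution-side thermal-stability /
kinetics fits. The in-memory model is a plain Atom → Residue → Chain →
Structure hierarchy; gemmi performs all PDB/mmCIF parsing and PDB writing,
so nothing downstream touches file formats. Author residue numbering is the
only numbering exposed (residue "336" in the file is residue 336 here);
alternate conformers are reduced to the highest-occupancy copy
(first-listed on ties); hydrogens are dropped and never used.

## Superposition

`kabsch_fit` is the SVD Kabsch solution with reflection correction: for
centered coordinate sets A, B the cross-covariance H = B₀ᵀA₀ is decomposed
H = UΣVᵀ and R = V·diag(1, 1, det(VUᵀ))·Uᵀ, which is the exact least-squares
optimum over proper rotations. Degenerate inputs (n < 3, rank < 2) raise.
Chain superposition fits on a selected atom set (default main-chain
N, CA, C, O; CA-only available) over residues paired by identical author
number + insertion code, requiring a CA on both sides; pairs with missing
atoms are dropped and counted, never imputed. The deviation trace always
reports post-fit Cα–Cα distances. Two scalar summaries are emitted — the
arithmetic mean of per-residue distances and their root mean square — and
the headline "average deviation" figure is the rms form; both appear in
every report so either convention can be read off. No outlier rejection or
iterative trimming is applied.

## B-factor flexibility

Profiles aggregate per residue (main-chain mean by default; all-atom mean
and CA-only available — all-atom serves whole-structure averages of the
kind reported in refinement tables). Normalization divides a profile by its
own maximum, taken over the per-residue aggregated values of the analysed
chain, not over all atoms including solvent; this makes profiles from
different crystals comparable on a 0–1 scale. Differential regions are
maximal runs of ≥ `min_run` consecutive common residues whose difference
keeps one sign with magnitude ≥ `threshold` (defaults 0.10 and 5; both are
study parameters exposed everywhere). Requiring a consistent sign is what
makes a flagged region's mean |difference| respect the threshold and
matches the intended semantics of a locally elevated profile. No smoothing
is applied by default; a centered moving mean of configurable odd window is
available.

Worm scores map normalized B to tube radii through the 5th/95th percentile
band (linear-interpolation percentiles): ≤ p5 → 0.30 Å, ≥ p95 → 1.25 Å, the
band midpoint → 0.80 Å, piecewise-linear between. Two linear segments are
used because a single segment from 0.30 to 1.25 would put the midpoint at
0.775, not the conventional 0.80 mid-score. A constant profile maps
everything to 0.80.

## Interaction detection

All criteria are distance-only. Structures at ~2 Å resolution carry no
hydrogens, so donors are inferred from heavy atoms and no donor–H–acceptor
angle term is meaningful; angle filtering is deliberately out of scope.

* Strong hydrogen bond: donor/acceptor heavy-atom pair, d_min ≤ d < 3.0 Å.
* Weak hydrogen bond: 3.0 ≤ d ≤ 5.0 Å.
* d_min = 2.2 Å floor excludes covalent/clash artifacts; additionally an
  adjacent-residue mainchain N–O pair below 2.6 Å is excluded, because the
  peptide bond itself places O(i)···N(i+1) ≈ 2.25 Å.
* Salt bridge: for each (cationic, anionic) residue pair, the minimum
  distance over cationic-group atoms (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2)
  × anionic-group atoms (Asp OD1/OD2, Glu OE1/OE2, C-terminal O/OXT);
  emitted if ≤ 5.0 Å. His counts as cationic by default (protonation is
  unknown at mildly basic pH) and can be switched off.
* Water bridge: a water oxygen within 3.4 Å (looser than the strong class,
  reflecting structured-water geometry) of polar atoms of two distinct
  residues; one edge per (residue, residue, water), distance = the longer
  leg.

Candidate pairs come from a scipy cKDTree; the tree is an implementation
detail whose correctness the test suite defines against an exhaustive
all-pairs scan with identical rules. Each atom pair appears once (canonical
partner ordering), even when both atoms are donor and acceptor.

The loop census collects edges with ≥ 1 partner in the focal range. The
intramolecular count is strong H-bonds with both partners inside the loop
(with a mainchain–mainchain subcount); the intersubunit bond count is the
number of distinct cross-chain atom pairs carrying a strong H-bond or salt
bridge — a salt bridge whose distance also satisfies the weak-H-bond class
is one bond, not two. Because the literature rarely states which classes
enter such printed counts, the summary always carries per-class counts
(strong/weak/salt/water, intra and inter) and the thresholds used, so any
alternative reading can be checked from the same report. Active-site
separation is the distance between per-chain metal-atom centroids (Zn by
default), overridable by an explicit atom selection.

## Stability and kinetics

Constants: R = 8.314 J·mol⁻¹·K⁻¹; temperatures are °C at the interface and
Kelvin internally; Eₐ is kJ·mol⁻¹ at the interface.

* Arrhenius: ordinary least squares of ln k on 1/T; Eₐ = −slope·R,
  ln A = intercept, with standard errors from the regression. T₅₀% inverts
  the fitted law at the 30-min half-loss rate constant
  k½ = ln 2/1800 s ≈ 3.851 × 10⁻⁴ s⁻¹:
  T₅₀% = Eₐ·1000/(R·(ln A − ln k½)); the precondition ln A > ln k½ is
  checked and its violation reported as "no solution".
* Two-state melt: signal(T) = (a_f + b_f·T)(1 − F_U) + (a_u + b_u·T)·F_U
  with logistic F_U(T) = 1/(1 + exp(−(T − Tm)/w)), fitted by
  Levenberg–Marquardt with baselines initialised from the first/last 10% of
  points and Tm from the mid-signal crossing. F_U per point is recovered
  from the fitted baselines and clipped to [0, 1]; Tm is the logistic
  midpoint, so F_U(Tm) = 0.5 by construction. Baselines are linear by
  default (constant optional). Flat signals and fits that place Tm far
  outside the measured range fail explicitly. The recovered Tm is invariant
  to linear rescaling of the signal axis (tested).
* Michaelis–Menten: nonlinear least squares of v = V_max·S/(K_M + S) with
  non-negativity bounds; k_cat = V_max/[E] when the enzyme concentration is
  given. Standard errors come from the asymptotic covariance, so one-sided
  designs (all S ≪ K_M) report honestly wide errors instead of silently
  succeeding.

Plain least squares is used throughout — no robust losses — matching how
such measurements are conventionally fitted.

## Synthetic data

Backbones are built in torsion space by the natural-extension reference
frame (NeRF) construction with ideal bond lengths/angles (N–CA 1.458,
CA–C 1.525, C–N 1.329, C=O 1.231 Å). Geometries: `ideal-helix`
(φ, ψ = −61°, −47°), `extended` (−140°, 135°), `coil-jitter` (extended plus
seeded Cartesian noise). The helix torsions were fixed so the built helix
realizes i→i+4 O···N at 2.90 Å — safely inside the strong class — and
i→i+3 at 3.39 Å (weak); textbook torsions put i→i+4 at 3.045 Å, straddling
the 3.0 Å class boundary, which would make planted bond counts fragile.
Where a helical segment is embedded in an extended chain, boundary residues
can gain extra backbone bonds, so the ground truth enumerates backbone
bonds by a direct scan of the built coordinates rather than a per-segment
formula.

Chain B is the rigid image of chain A under a configurable two-fold
rotation; planted displacements (rigid offsets on residue intervals) are
applied to B afterwards, so chain A remains the pristine reference.
Planted interactions place the named atoms at their target distances
exactly (verified to 10⁻³ Å), anchored 4.5 Å off the backbone along the
local across-dimer axis (orthogonalised against the chain tangent), pointing
into the gap for cross-chain pairs and away from it for intra-chain pairs;
several pairs can hang off one residue via a lateral shift along the chain.
The generator raises if an atom is pinned by conflicting constraints or a
planted atom lands within 2.2 Å of an unrelated atom. Residue types follow
the planted atom names (OG → Ser, NH1 → Arg, ...). B-factors follow a
baseline + interval-bump profile; metals and waters are placed at explicit
coordinates. Every generator is a pure function of its spec + seed, and
ground truth is serialized as a JSON sidecar next to written fixtures.

The generator is explicitly not a physically realistic conformer builder:
planted side-chain atoms may sit far from their residue's backbone, there
are no rotamers, no solvation, no crystal packing. Consequently, passing
tests demonstrate that the *measurement machinery* — superposition,
normalization, detection, fitting — recovers known truth; they do not
certify behaviour on pathologies real crystals show (disorder, missing
loops, alternate conformations beyond two, TLS-refined B-factors).

## Emulated reference dimers

`dimerflex.emulation` builds two 310-residue (author numbering 50–359)
reference scenarios at the geometry scales reported for cold-active
alkaline-phosphatase dimers: the intact-interface dimer plants a loop
(324–354) census of exactly 12 intramolecular strong H-bonds (6
mainchain–mainchain from a helical stretch at 324–332), 10 intersubunit
strong H-bonds plus a 4.9 Å Arg336(A)–Asp59(B) salt bridge, metal sites
60 Å apart, and sub-Å chain-B displacements sized so the pooled post-fit
deviation lands near 0.30 Å; the broken-interface variant removes the
network, raises B-factors on residues 81–100 (+15 Å²) and 115–150 (+12 Å²)
on a 27.662 Å² baseline (all-atom mean 30.91 Å²), and carries displacements
sized for ≈ 0.35 Å against the intact chain A. Displacement magnitudes are
quoted post-fit because the rigid fit absorbs part of any planted offset;
the planted offsets themselves (0.8, 0.94/0.94/0.49 Å) are recorded in the
specs. The stability simulators use Tm = 50.8 °C, k_cat = 302 s⁻¹,
K_M = 0.19 mM, and an Arrhenius pair (Eₐ = 300 kJ·mol⁻¹,
ln A = 112.8394) whose derived T₅₀% is 25.8 °C.

Problem sizes throughout (310-residue chains, ≤ 500-atom oracle windows,
8-point rate series, 141-point melts, 300-replicate bias checks) keep every
analysis in seconds while leaving the statistics meaningful.

## Known limitations

* Residue correspondence is by author numbering only — suitable for point
  mutants and isomorphous pairs, not for homologs needing sequence
  alignment.
* Interaction detection has no π-stacking, cation-π or hydrophobic classes,
  and no geometric (angular) hydrogen-bond criteria.
* No symmetry expansion: a biological dimer deposited as a monomeric
  asymmetric unit must be expanded by the user before analysis.
* Melt fitting assumes a two-state transition; intermediates bias Tm.
* Per-residue normalization uses per-residue maxima; a per-atom variant is
  not implemented.
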