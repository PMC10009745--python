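# Methods

`monofilm` analyses Langmuir monolayer experiments on bipolar amphiphiles —
prototypically the side-chain-oxidised cholesterols (25-OH, 27-OH), whose
second hydroxyl lets a film pass from a monolayer to bilayer-like
structures through a pseudo-plateau in the π–A isotherm. This note records
the models, conventions, numerical choices and limitations behind each
stage.

## Units and constants

Internal units follow the monolayer literature: area per molecule in
Å²/molecule, surface pressure π and compressional modulus in mN/m, surface
potential ΔV in mV, temperature in K; molar energies in kJ/mol and molar
entropies in J/(mol·K). The single conversion used throughout is
1 Å²·mN/m = 10⁻²³ J per molecule, so N_A·∫A dπ in these units maps to
kJ/mol through a factor 6.02214076 × 10⁻³. The temperature coefficient of
the surface tension of water is fixed at dγ/dT = −0.153 mN m⁻¹ K⁻¹
(valid 10–35 °C) and is overridable everywhere it is used. Printed-table
comparisons round half away from zero, because that is how the reference
tables are typeset (π_t = 36.585 → 36.59).

## Isotherm features

Records are canonicalised (compression: decreasing area; expansion:
increasing; duplicate areas averaged) before analysis. Derivatives are
taken on a Savitzky–Golay-smoothed pressure curve (default window 7,
order 2, configurable); a window of 3 degenerates to plain central
differences and is what exact synthetic tests use. For noisy records a
window spanning roughly 1–2 Å² of area (e.g. 31 samples on a 0.05 Å²
grid) gives slope noise well below the flatness threshold; this is the
setting used in the statistical recovery tests.

* **Compressional modulus** C_s⁻¹ = −A·(dπ/dA). Phase labels follow the
  classical compressibility scheme: < 25 mN/m low-density liquid, 25–50
  liquid-expanded, 100–250 liquid-condensed, > 500 solid. The two unnamed
  gaps (50–100, 250–500) are reported as `intermediate` rather than
  given invented names.
* **Lift-off**: largest area where π exceeds a threshold (default
  0.5 mN/m) for k = 5 consecutive samples; the persistence guard exists
  because a single noisy sample must not define an onset.
* **Collapse**: local slopes are fitted on 8-sample windows on either side
  of each point; a collapse candidate is a softening jump (slope magnitude
  dropping toward zero on compression) exceeding half the 90th percentile
  of local slope magnitudes. The 90th percentile — not the median — is the
  scale because the shallow post-collapse tail can dominate the sample
  count. Among candidates the one at the highest pressure is reported,
  which separates collapse from the (lower-lying) plateau edges.
* **Pseudo-plateau**: there is no universal numeric criterion for a
  plateau; this package uses a slope-flatness fraction (default 0.15) in
  two passes. A coarse pass thresholds |dπ/dA| against 0.15 × the 90th
  percentile of slopes and keeps the longest flat run flanked by steep
  regions on both sides; the final threshold is 0.15 × the median slope of
  the rise *before* that run (the condensed ascent), and the run is
  regrown around its centre, tolerating isolated noise spikes (two
  consecutive above-threshold samples end it). Each boundary is then
  snapped to the sample nearest the intersection of the plateau line with
  a line fitted to the flanking segment — the intersection localises the
  edge below the grid spacing even under noise, while the reported
  boundary stays a point of the record. The midpoint pressure is exactly
  π_t = (π_b + π_e)/2.

## Electrical analysis

The Helmholtz relation ΔV = μ_⊥/(A·ε·ε₀) with unknown film permittivity ε
motivates the apparent dipole moment μ_a = ε₀·ΔV·A, reported in debye with
the SI value kept alongside. The critical area uses the same persistent
onset logic as lift-off with a 15 mV default threshold (typical Kelvin
probe reproducibility) and is symmetric in the sign of ΔV. A sustained
fall of μ_a while π still rises is reported as the depolarisation onset —
the signature of a second molecular layer whose dipoles partly compensate
the first. Estimating ε or the true μ_⊥ is out of scope.

## Hysteresis thermodynamics

Each branch contributes ΔG = N_A·∫A dπ over a fixed pressure window
(default 1.2 → 39.8 mN/m, spanning pre-lift to post-plateau pressures of
these films), integrated trapezoidally with endpoint areas interpolated.
Points that break π-monotonicity near the barrier turnaround are clipped
to the monotone envelope and logged. The hysteresis free energy is the
difference of the branch integrals; since a lossy film's expansion branch
lies at smaller areas, the literal difference is positive, and the
retained energy is reported with a negative sign (ΔG^hys = −|ΔG^comp −
ΔG^exp|), matching how these tables are conventionally printed. The
entropy follows from the temperature dependence, ΔS^hys =
−d(ΔG^hys)/dT by ordinary least squares over ≥ 2 temperatures, and the
enthalpy from the Gibbs relation ΔH^hys = ΔG^hys + T·ΔS^hys. When only a
single temperature is available ΔS^hys must be supplied and only the
Gibbs relation is applied. The Gibbs closure reproduces every published
per-cycle (ΔG, ΔS, ΔH) triple for the 25-OH/27-OH films to the printed
two decimals at 293.15 K (20 °C experiments are taken as 293.15 K).

## Plateau-transition thermodynamics

Per temperature, the plateau midpoint π_t is extracted and fitted linearly
against T; the transition enthalpy follows from the adapted
Clausius–Clapeyron relation for a film on water,

    ΔH_t = N_A · T · (A_e − A_b) · (dπ_t/dT − dγ/dT),

and ΔS_t = ΔH_t/T, always computed from the unrounded enthalpy (rounding
ΔH_t first visibly corrupts ΔS_t in the third digit). ΔH_t > 0 exactly
when (A_e − A_b) and the driving term share a sign: a plateau that
shrinks on heating while π_t falls faster than γ marks an endothermic,
entropically driven transition.

A `slope` override lets a tabulated slope replace the fitted one in the
enthalpy step. This matters when dπ_t/dT nearly cancels dγ/dT: for the
27-OH data the fit gives −0.1495 mN m⁻¹ K⁻¹ versus the tabulated −0.150,
and that third decimal shifts ΔH_t by ~20% through the small difference
(−0.1495 + 0.153 vs −0.150 + 0.153). The published 27-OH enthalpies are
reproduced with the tabulated slope; the fitted value is always reported
alongside. One published cell (27-OH, 303 K) prints −0.07 kJ/mol where
the relation yields −0.0754 (→ −0.08 at two decimals); the recomputed
value is reported as computed.

## Snapshot geometry

Hydrogen bonds use the geometric criterion: donor–acceptor heavy-atom
distance strictly below 3.0 Å and donor–hydrogen–acceptor angle (vertex
at the hydrogen — the only reading under which a 135° threshold makes
chemical sense) of at least 135°, read literally: the distance bound is
strict, the angle bound inclusive. Distances use the minimum-image
convention; slab geometry is periodic in x, y only by default.
Intramolecular pairs are excluded by default since the census targets
bonds between amphiphiles. Persistence filters bond identities — (donor
heavy atom, acceptor heavy atom), ignoring which hydroxyl hydrogen —
present in at least a fraction (default 0.8, inclusive) of frames, so a
rotating hydroxyl does not break a bond's identity.

The molecular tilt is the angle between the dominant principal axis of
the unweighted coordinate second-moment tensor and the interface normal,
folded into [0°, 90°]; the principal-axis definition is parameter-free
and rotation-equivariant. Area per lipid is Lx·Ly/n per leaflet.
Anchoring of a bipolar sterol is classified per molecule by which tagged
hydroxyl oxygen (head C(3)-OH vs chain OH) lies closer to the water-slab
midplane; exact ties count as head-anchored. Density profiles are
weight-conserving histograms (count or mass); electron-density weighting
is not implemented (mass weighting approximates it). RDFs normalise pair
distances against the ideal-gas expectation at the system's density and
require r_max ≤ half the smallest periodic edge.

## Synthetic data

The generators plant known ground truth rather than solve an equation of
state. Isotherms are piecewise linear in area: zero pressure above the
lift-off area, a condensed rise, an optional pseudo-plateau whose
midpoint obeys π_t(T) = π_p0 + (dπ_t/dT)(T − T0), a lesser post-plateau
rise, and a slope break at collapse, plus seeded Gaussian noise. Defaults
sketch a 27-OH-like film: lift-off 44 Å², condensed slope 3.3 mN/m per
Å², plateau at 20 mN/m of width 15 Å² with a 0.6 mN/m residual rise (real
plateaus are never perfectly flat, and a residual keeps the midpoint
non-trivial), dπ_t/dT = −0.15 mN m⁻¹ K⁻¹, collapse at 40 mN/m, grid
0.05 Å². Hysteresis cycles shift the expansion branch rigidly (or per-π)
toward smaller areas and return the enclosed ∫(A_comp − A_exp)dπ as
analytic truth. Snapshots build two leaflets of rod-like bipolar
pseudo-sterols (hydroxyl O + H at each end, six backbone beads) on a
jittered lattice (default spacing 6.05 Å ⇒ ~36.6 Å² per lipid) flanking a
geometric water slab, with a collective planted tilt per leaflet, an
exactly planted head-anchored count, and an exact number of cross-leaflet
hydrogen-bonded pairs placed at O···O = 2.8 Å and 160°, all other
hydroxyl pairs ≥ 3.5 Å apart.

What the generators do *not* emulate: equation-of-state curvature,
plateau kinetics and nucleation, multi-plateau films, explicit water,
conformational disorder, or thermal libration of bonds. Passing the
closed-loop tests therefore demonstrates the correctness of the
extraction operators, not the physics of real films; on experimental data
the smoothing window and flatness fraction remain the user's
responsibility.

## Problem sizes and determinism

The statistical suites use 50-seed isotherm families (six temperatures,
noise σ = 0.05 mN/m) for transition recovery, 100-seed plateau recovery
at σ = 0.1 mN/m on a 0.25 Å² grid, and 100 random 80-atom snapshots for
the hydrogen-bond brute-force oracle — sizes at which every suite is
exhaustive yet runs in seconds. All randomness flows through
`numpy.random.default_rng` seeds; per-temperature noise streams within a
family derive from a `SeedSequence` spawn of the family seed, so families
are reproducible and mutually independent.

## Known limitations

* Collapse detection assumes collapse is the highest-pressure softening
  kink; exotic isotherms whose collapse stiffens the film would be
  missed.
* The plateau detector reports sampled boundary points; sub-grid edge
  positions are used only to pick the nearest sample.
* Hysteresis ΔS from per-cycle temperature series assumes ΔG^hys varies
  linearly over the measured range.
* PDB coordinates round to 10⁻³ Å; planted bond geometries survive this,
  but exact-equality tests should compare topology, not coordinates.
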