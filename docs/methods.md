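# Methods

This note records the models implemented in `hydradyn`, the estimator
conventions, the defaults and why they were chosen, and what the synthetic
validation does and does not demonstrate about real data.

## Units and constants

Internal units are Å, ps, K, Da; neutron energies in μeV, activation
energies in kJ/mol.  ħ = 658.2119569 μeV·ps converts between the energy
and time domains; R = 8.3145 J mol⁻¹ K⁻¹.  Radial profiles are reported in
nm.  Hydration levels *h* are grams of D₂O per gram of protein; the D₂O
molar mass (20.028 g/mol) is the default in composition bookkeeping even
when the simulation water model is H₂O, because *h* is defined
gravimetrically against the heavy-water mass used to hydrate real samples.

## Containers and ingestion

A `Trajectory` is a dense `(n_frames, n_atoms, 3)` float64 array with a
timestep and a temperature label; an `AtomTable` carries per-atom element,
mass, names, residue/subunit assignment, role (protein/water/ion) and the
classification flags.  PDB and trajectory files are read through
MDAnalysis.  No centre-of-mass removal, wrapping or unwrapping is applied
on load: silent COM correction changes long-lag MSDs, and silent
unwrapping corrupts them, so trajectories carry an `unwrapped` flag and
the MSD estimators refuse wrapped input.  Biological assemblies are built
by applying the structure's BIOMT operators, each copy becoming its own
subunit.

Methyl groups are the CH₃ carbons of Ala (Cβ), Val (Cγ1/Cγ2), Leu
(Cδ1/Cδ2), Ile (Cγ2/Cδ1), Thr (Cγ2) and Met (Cε); terminal caps are
excluded.  When no bond records exist, a hydrogen is bonded to the nearest
heavy atom within 1.25 Å — robust for idealised hydrogen placement; a
candidate methyl carbon without exactly three bonded hydrogens is skipped
with a warning rather than guessed.  Exchangeable hydrogens are those
bonded to N, O or S.  For structures without explicit hydrogens (crystal
structures), per-residue template counts (standard amino-acid topology,
Asp/Glu⁻, Lys/Arg⁺, neutral His, charged termini, disulfides subtracting
their thiol hydrogen) provide the hydrogen bookkeeping; these may differ
marginally from any particular force field's topology.

## MSD estimators

`compute_msd` averages |r(t₀+t) − r(t₀)|² over selected atoms and all time
origins.  The default path uses the FFT autocorrelation decomposition
(running sums of |r|² minus twice the positional autocorrelation), which
is algebraically identical to the O(N²) double loop; the direct estimator
is kept both as the in-suite oracle and for strided-origin use.  MSD(0) is
exactly zero and tiny negative FFT round-off is clipped.

The scalar MSD_t(T) is defined here as the arithmetic mean of MSD(t) over
the lag window (default 6–8 ns, configurable).  The window mean is a
deliberate design choice — the estimator is stated at window level only in
the workflow this package follows — and its error is a
Flyvbjerg–Petersen blocking estimate: the series is pair-averaged
repeatedly, the error at each level is √(var/(n−1)), and the reported
value is the first plateau (successive levels agreeing within their own
uncertainty), falling back to the maximum when no plateau forms.

Mobility change between hydrated and dry states is
(MSD_h − MSD_d)/MSD_d · 100 per residue, with **strict** thresholds:
hindered iff change < −10 %, enhanced iff change > +60 %.  Values exactly
on a threshold are neutral; a numerical guard keeps floating-point noise
from flipping boundary cases.

Sub-diffusion exponents come from least squares of log MSD on log t over a
5 ps–1 ns window.

## Methyl decomposition

At a fixed lag (default exactly 1 ns) the methyl-hydrogen displacement is
split as Δr_H = Δ(r_H − r_C) + Δr_C.  "Rotational" is operationalised as
the carbon-relative hydrogen displacement: coordinate-frame free, exactly
complementary to the carbon MSD, and saturating at the three-site chord
average 2r² under fast exchange.  This definition includes any C3-axis
reorientation in the rotational part; a convention that first removes
local backbone reorientation would differ by the axis-libration
contribution.  Both conventions coincide for the fixed-axis rotors used in
validation; the choice is documented rather than hidden.  All three
estimators share one origin set, so
total = rotational + non-rotational + cross holds to round-off, with the
cross term reported, never assumed zero.

## Neutron observables

The incoherent self ISF uses the closed-form powder average
⟨exp(iQ·d)⟩ = sinc(Q|d|), exact for the isotropic self term — no explicit
Q-vector sampling.  The default scattering selection is protein hydrogens
with uniform weight: D₂O hydration water contributes negligibly and is
excluded; options include all hydrogens and a "deuterate exchangeable"
mode that zero-weights exchangeable protein hydrogens to emulate H/D
exchange.  Excluding zero-weighted atoms changes nothing by construction,
and the suite asserts it.

Resolution enters as R(t), the unit-normalised Fourier transform of the
energy profile: Gaussian FWHM Γ → exp(−σ_E²t²/2ħ²); Lorentzian →
exp(−Γ|t|/2ħ); pseudo-Voigt → η-weighted sum (η default 0.5; instrument
presets OSIRIS Γ = 24.5 μeV / window ±12.5 μeV and IRIS 17.5 / ±8.5).
Elastic intensity is ∫I(Q,t)R(t)dt for peak-height mode (the ω = 0 cosine
transform of the symmetric extension) or ∫I·R·sinc(wt/ħ)dt for the
±w-integrated mode; the two agree within 2 % for purely elastic toy
systems.  Simulated scans use peak height, tabulated experimental scans
the integrated mode.  A warning fires when R(t_max) > 0.01 (t-grid too
short for the resolution).

The Debye–Waller fit is per-temperature linear least squares of
ln[I(Q,T)/I(Q,T_base)] on Q² with floating intercept over 0.4–1.8 Å⁻¹
(≥3 points, positive intensities required); ⟨u²⟩ = −3 × slope, and the
Gaussian-approximation flag reports max(Q²⟨u²⟩)/3.  Scans are normalised
per Q at the base (lowest) temperature.

**Timescale caveat.**  For Gaussian dynamics of per-axis variance σ², the
fitted ⟨u²⟩ equals 3σ² (half the direct-space plateau 6σ²) only when the
motion relaxes much faster than the resolution's observation window.  The
validation ladder therefore uses a 2 ps relaxation against a 5 μeV
Gaussian resolution (observation ≈ hundreds of ps), where the identity
holds to ~1 %.  With a 24.5 μeV resolution and 50 ps relaxation the
elastic scan genuinely under-reads ⟨u²⟩ — that is instrument physics, not
an estimator defect, and it mirrors the limited temporal window of real
backscattering measurements.

## Radial profiles

"RDF" here is the shell-volume-normalised radial number density
n(r) = count/(4πr²Δr) about the mass-weighted COM of a reference selection
(whole protein by default), frame averaged, with 0.05 nm bins.  A
vacuum-suspended assembly has no bulk density, so no g(r) normalisation is
attempted; conclusions rest on peak positions and shapes.  Profiles are
count-based (mass-weighting the selection would only rescale a
single-element selection).  The cavity radius is the innermost radius
where density first exceeds 5 % of the profile maximum, linearly
interpolated between bin centres; the threshold fraction is this package's
convention (sensitivity at 0.02/0.10 shifts the uniform-shell result by
less than a bin).  Whole residues are assigned to methyl / non-methyl
subsets.  Overlap between unit-normalised profiles is Σ min(n̂₁, n̂₂) over
per-bin probability masses.

## Hydration-water kinetics

Water–water hydrogen bonds use the community-standard geometric criterion
O···O ≤ 3.5 Å and H–donor-O–acceptor-O angle ≤ 30°, both donor directions
tested; the criterion is configurable and recorded in outputs.  C_H(t) is
the **intermittent** correlation ⟨h(0)h(t)⟩/⟨h⟩ over all pairs ever
bonded — the standard estimator for relaxation-time and Arrhenius
analysis, since the decay of interest is bond *switching*, not first
breakage; a continuous variant can be obtained by pre-processing the
indicator.  τ_H is the 1/e crossing, interpolated linearly in ln C_H, and
flagged undefined when C_H never reaches 1/e in the analysed lag range.
E_a is R times the slope of ln τ_H against 1/T (default fit range
200–290 K, ≥3 points), with errors from the regression covariance.
Replica statistics are mean ± sample SD over independent seeds.

## Synthetic generators

- **Harmonic**: stationary Ornstein–Uhlenbeck motion about fixed centres.
  OU (rather than frame-iid noise) gives MSD(t) a resolvable rise to its
  6σ² plateau; relaxation time default 50 ps.
- **Methyl rotors**: three hydrogens on a circle of radius 1.03 Å about a
  fixed random C3 axis through the carbon; site jumps are Poisson with
  total rate k(T) = k₀·exp(−E/RT) and ±120° direction by unbiased
  thinning.  Axis libration is off by default so the rotational plateau is
  exactly 2r².
- **Water**: pair centres follow fractional Brownian motion (Davies–Harte
  circulant embedding, Hurst = β/2) scaled so the 3D MSD is A·t^β; the
  per-pair bond indicator is a two-state Markov chain with rates k_on(T),
  k_off(T), and the O/H geometry toggles between a bonded (2.8 Å, aligned
  donor H) and unbonded (5.0 Å) arrangement so geometric detection
  reproduces the indicator exactly.  The closed form
  C_H(t) = p + (1−p)e^{−(k_on+k_off)t}, p = k_on/(k_on+k_off), is the
  oracle.
- **Temperature series**: 16 temperatures from 10 to 290 K, two scenarios.
  120 confined hydrogens plus 12 rotors give a 23 % methyl-hydrogen
  fraction, matching the protein systems this emulates.  σ²(T) is linear
  (6σ²(290 K) = 0.6 Ų); the rotor barrier (5 kJ/mol, k₀ = 0.6 ps⁻¹) was
  calibrated on the generator's closed-form windowed-MSD curve so the
  piecewise-linear knee of methyl activation sits at 100 K for the 6–8 ns
  window; the hydrated scenario adds variance linearly above 220 K, scaled
  so the 290 K hydrated/dry MSD ratio equals the configured enhancement
  (default 1.6), and can attenuate hydrated amplitudes below 175 K to
  produce the low-temperature inversion seen in some weakly hydrated
  proteins (off by default, 0.85 when enabled).  Hydrated series include
  Markov-bonded water pairs (k_off Arrhenius with 20 kJ/mol).  Identical
  seeds give bit-identical trajectories; scenarios share per-temperature
  base seeds so they differ only by the configured physics.

Trajectories default to 1700 frames × 5 ps (8.5 ns), so the 6–8 ns lag
window applies unchanged; these sizes keep the full two-scenario scan with
all analysis stages under a minute on one core.

**What the synthetic validation shows and does not show.**  Passing tests
demonstrate that each estimator recovers known ground truth under its own
assumptions (Gaussian confinement, ideal rigid rotors, Markov bonds,
exact fractional noise) at desk-scale statistics.  They do not demonstrate
force-field realism, conformational heterogeneity, water-protein coupling,
anisotropic or multi-well landscapes, or the ~200 ns statistics of
production trajectories; printed experimental activation energies and
MSD curves for real proteins are reproducible only from such trajectories,
which this package analyses but does not generate.

## Transition-temperature estimation

Scenario comparison fits a continuous piecewise-linear model
{1, T, (T−b)₊ …} to MSD_t(T) by exhaustive search over breakpoint
candidates (5 K grid, segments ≥30 K apart) and reports the
minimum-SSE breakpoints.  On the 16-point grid with default statistics the
knee of a smooth Arrhenius-activated sigmoid is located with roughly
±10–15 K scatter across seeds; the detected knee sits at the top of the
activation rise, which is why the generator calibration targets the knee
rather than the rate's midpoint.

## Numerical choices and degenerate inputs

Strictly positive timesteps and temperatures are enforced at construction;
empty selections, residues without hydrogens, all-zero profiles,
never-bonded systems, τ ≤ 0 and sub-3-point fits raise informative errors
rather than propagating NaNs.  Lag-0 values are set exactly (MSD 0,
I(Q,0) = 1, C_H(0) = 1).  Blocking needs ≥8 samples.  fGn eigenvalues are
clipped at zero against round-off.  XYZ output carries three decimals
(1e-3 Å round trip); manifests record seeds and ground truth; every
pipeline TSV carries the package version, config hash and seed.

## Known limitations

No pair g(r); no full S(Q,ω) lineshape fitting, coherent scattering or
multiple-scattering corrections; no whole-body rotation/translation
separation (none is applied upstream either); water model realism limited
to what hydrogen-bond detection needs; the piecewise-linear breakpoint
estimator is grid-quantised; the elastic-scan route inherits the
observation-window bias discussed above.
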