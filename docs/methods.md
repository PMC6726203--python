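# Methods

This note documents the models, numerical choices and limitations behind
`ircmech`. Units throughout: Ångström for distances, kcal/mol for
energies, elementary charge (a.u.) for charges; bond orders and the
reaction coordinate ξ are dimensionless unless an IRC arc length is
supplied.

## Data model

A reaction path is an ordered list of frames (geometries) with an
optional energy per frame and a strictly increasing scalar reaction
coordinate ξ. By default ξ is the frame index 0..n−1; a sidecar CSV can
override it with IRC arc length. Both conventions are supported because
published reaction-coordinate axes are frequently left undefined;
differentiation and event positions are always taken with respect to
whichever ξ is active, and no claim is made that either matches a
particular publication's axis. Atom indices are 1-based in every public
interface (XYZ/PDB convention) and converted at the boundary only.

Energies are kcal/mol internally, always. Hartree inputs must be
converted on read (×627.5095, exposed as `HARTREE_TO_KCAL`); a single
internal unit avoids silent mixed-unit bugs.

## Stationary-point detection

Interior local maxima of the energy profile with topographic prominence
≥ `prominence_tol` become transition states; the interior minimum between
two consecutive TSs is an intermediate; the first and last frames are
reactant and product by definition. Detection uses
`scipy.signal.find_peaks`; relative energies are always reported from the
raw profile even when an odd moving-average window (`smooth_window`) is
applied for detection, so smoothing can never bias reported barriers.

The default prominence is 0.5 kcal/mol: stepwise pathways can hide behind
sub-kcal features — a first TS barely 1 kcal/mol above its intermediate
is mechanistically meaningful — so the detector must keep them, while
still rejecting profile noise below half a kcal/mol. Adjacent maxima of
exactly equal height are both kept and flagged as a "shoulder pair"
rather than merged: on potential-energy (as opposed to free-energy)
surfaces the concerted/stepwise distinction near such features is not
robust, and the flag makes that visible instead of deciding silently.

## Pauling associativity

At a TS the breaking and forming P–O distances are averaged and Pauling's
relation D(n) = D(1) − 0.60·log₁₀(n) is inverted for the fractional bond
number n; D(1) defaults to 1.73 Å (single P–O bond) and is overridable
for other transferred groups. The logarithm is base 10: with the 0.60 Å
coefficient, that is the only base under which the standard worked values
for loose phosphoryl-transfer TSs come out, and the package validates
this in its tests.

Reporting convention: n is truncated (rounded toward zero) to 3 decimals
and the percentages are derived from the truncated value at 1 decimal,
with full precision retained in `n_exact`. Truncation rather than
rounding is deliberate — it is the convention under which the canonical
worked examples (n = 0.039 from distances 3.04/2.10 Å; n = 0.048 from
2.57/2.47 Å) are internally consistent with their quoted percentages
(96.1 % and 95.2 % dissociative).

A metaphosphate-like intermediate is flagged when both P–O bond orders
are < 0.5. Without bond orders, the geometric surrogate is both P–O
distances > D(1) + 0.60 Å — one full Pauling decade looser than a single
bond, i.e. n < 0.1 on each side. The surrogate is intentionally stricter
than the bond-order criterion: distances inflate slowly as bond order
decays, and a weaker geometric cutoff would flag ordinary late-TS
geometries.

## Bond-order derivatives and events

dB/dξ uses the three-point central formula on the (possibly non-uniform)
ξ grid (`numpy.gradient`), one-sided at the endpoints; it is exact for
linear data. Optional pre-smoothing is a moving-window polynomial
(Savitzky–Golay) fit, default off, offered as window 5 / degree 2 because
real IRC bond orders carry numerical noise; it is a deviation knob, not a
default behavior.

Events are local extrema of |dB/dξ| that clear both a height and a
prominence threshold of `min_peak_frac` (default 0.2) of that pair's own
global |dB/dξ| maximum. Per-pair normalization lets one default serve
pairs with very different net changes; the full-prominence requirement
rejects noise wiggles riding on the flank of a genuine peak. The event
window is the contiguous region where |dB/dξ| stays above half the peak
height — this defines the event width and its net change (trapezoidal
integral of the derivative over the window) without any curve fitting.
Events whose |net change| reaches `min_net_change` (default 0.1) are
forming/breaking; smaller ones are strengthening/weakening. The reported
peak position is the centroid of |dB/dξ| over the event window, which is
exact for symmetric peaks and localizes to sub-grid precision under
noise; peaks at the very ends of the path are not reported.

Crossings of two bond-order curves are sign changes of their difference,
located by linear interpolation between the bracketing frames. The
synchronicity span of an event group is (max ξ_peak − min ξ_peak)
normalized by the full ξ range; 0 means perfectly synchronous.

## Fragment charges

Fragment charges are exact per-frame sums — no smoothing, no
interpolation; published charge curves are, as far as stated, plotted
raw, and the module follows suit. The module is agnostic to the
population scheme (NPA by convention; the scheme name is metadata).
Overlapping fragments must be explicitly flagged, so partition-based
conservation checks stay meaningful. Per-frame totals drifting more than
`charge_sum_tol` (default 0.01 a.u.) from the first frame are recorded as
warnings, not errors: population-analysis output legitimately wobbles in
the last printed digit.

`charge_profile_report` tabulates fragment charges at the stationary
points supplied by the mechanism stage, reports global extrema with their
ξ, reactant→extremum and reactant→product deltas, and monotone segments.
`charge_event_correlation` differences each fragment across a ξ window
(default 0.1) centred on each bond event; windows reaching past the path
ends are clipped with a warning.

## Geometry

Distances and angles are plain Euclidean measurements, property-tested
for invariance under rigid motions. Metal coordination counts ligands
within a cutoff, default 2.6 Å for Mg–O: first-shell Mg–O contacts in
phosphoryl-transfer active sites sit at 1.9–2.4 Å and a departing ligand
moves past 2.9 Å, so 2.6 Å separates the two populations cleanly;
distances are reported for every candidate regardless of the cutoff.
Hydrogen bonds use the common geometric criteria d(D,A) ≤ 3.5 Å and
∠(D–H···A) ≥ 120°, both configurable since conventions differ between
studies; donor pairs whose D–H distance exceeds 1.3 Å are not covalently
bonded and are skipped with a warning. Distance tables are printed at
2 decimals (the conventional precision for such tables) with full
precision retained internally.

## Synthetic paths

The generator emulates the statistical structure of QM/MM reaction-path
output so every stage can be tested with known ground truth:

* **Bond orders** are sums of logistic transitions
  B(ξ) = B_start + ΔB·σ((ξ−μ)/s) per pair, plus Gaussian noise clipped
  at 0.
* **Energies** interpolate prescribed stationary targets with a cubic
  Hermite spline having zero slope at every target, so extrema land
  exactly on the targets and nowhere else.
* **Geometry** places the reactive triad (donor O, P, acceptor O)
  collinearly along z with P–O distances obtained by inverting Pauling's
  relation from the clean bond orders, clamped to the configured
  (d at B=1, d at B=0) range; spectator atoms sit on a static lattice.
  Collinear-triad emission is sufficient for every implemented
  measurement (distances, the 180° in-line angle, planted coordination
  distances); full 3-D realism is a non-goal.
* **Charges** follow per-fragment PCHIP trends through optional planted
  interior extrema; atoms outside any trend share the remainder so that
  per-frame totals equal the system charge exactly before noise.
* **Noise** is i.i.d. Gaussian per channel — the simplest model that
  exercises the smoothing and prominence logic. Randomness is
  `numpy.random.default_rng(seed)` (PCG64), reproducible across
  platforms; a fixed spec + seed yields bit-identical bundles.

Default preset conditions: a 61-atom QM region, 121 frames over ξ∈[0,1],
energy noise 0.05 kcal/mol, bond-order noise 0.002 and charge noise
1×10⁻⁴ a.u. per atom. The last two are small by design: bond orders and
population charges are deterministic wavefunction outputs whose only
"noise" is numerical/printing precision, unlike sampled energies.

The two mechanistic presets encode the canonical phosphoryl-transfer
scenarios. `base_assisted_like` is stepwise and dissociative: barrier
14.3 kcal/mol, first TS 1.1 kcal/mol above a metaphosphate-like
intermediate (forming bond order ≈ 0.46 there), second TS 7.2 kcal/mol
above it, reaction energy 2.5 kcal/mol, and two late proton transfers
(Lys→phosphate at ξ=0.70, Ser→Asp at 0.75) planting a 0.05 synchronicity
offset. `substrate_assisted_like` is concerted with a single high TS
(50.5 kcal/mol) at which both P–O distances are long (TS ≈ 96 %
dissociative), the bridging bond having broken early and the proton
shuttling to a non-bridging oxygen at the TS. `associative_toy`
exercises the opposite branch (both partial bonds ≈ 0.78 at the TS,
n > 0.5, with the negative-charge buildup an associative TS implies), and
`barrierless_toy` the degenerate no-TS case.

What passing tests on these paths do *not* show: that real QM/MM
energies, bond orders or charges behave this way. The generator has no
force field and no wavefunction; its energy shapes, noise model and
event shapes are stylized. What the tests do show is that *given* data
with the assumed structure, the analysis recovers the planted mechanism:
labels, stationary points (±1 frame noise-free, ±2 at σ=0.1 kcal/mol
with smoothing), event midpoints (±1 grid step at bond-order noise
σ ≤ 0.01), and associativity within 2 percentage points of the value the
planted geometry implies.

## Numerical choices and degenerate inputs

* Derivative scheme exact for linear data; trapezoidal integral of dB/dξ
  closes to within 2 % of ΔB on logistic fixtures.
* Curves whose global |dB/dξ| maximum is ≤ 1e−8 are treated as flat (no
  events) rather than normalized into noise.
* Paths need ≥ 2 frames; stationary-point detection and derivatives need
  ≥ 3. Fewer is an explicit `InsufficientDataError`, never a silent
  empty result; an energy profile with no interior maximum yields
  pathway class `"none"` with an empty TS list, without error.
* i == j distances are permitted (0.0) and flagged at the reporting
  layer; coincident points make an angle undefined and raise.
* Bond-order tables must cover every (pair, frame) cell — missing cells
  are an error, never interpolated. Duplicate rows and negative orders
  are rejected.
* Report JSON is sorted-key and timestamp-free, so identical inputs give
  byte-identical reports.

## Problem sizes

The synthetic presets use 61 atoms and 61–121 frames; the dedicated
event-recovery fixtures use 201 frames. These sizes keep the full test
suite and the acceptance script in the seconds-to-minutes range on a
single CPU while leaving every detector threshold exercised at realistic
path resolution (IRC paths are conventionally resampled to order 10²
points).

## Known limitations

* The stepwise/concerted call is made on potential energies; free-energy
  effects can flip it for sub-kcal features (hence the shoulder flag and
  the configurable prominence).
* Event direction for pairs with multiple overlapping transitions
  depends on the half-height window; strongly overlapping events of the
  same sign on one pair merge into the stronger one.
* The Wiberg text-block parser targets the standard NBO column-chunked
  dialect only (frozen example in `tests/data/wiberg_block.txt`); full
  quantum-chemistry logs (route sections, SCF traces) are out of scope.
* PDB support is read-only and keeps naming fields only; MD-engine
  trajectory formats are out of scope.
* The generator's observation-noise model is i.i.d. Gaussian; correlated
  noise along the path (e.g. from SCF convergence drift) is not
  emulated.
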