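# Methods

`kpermeate` post-processes molecular-dynamics trajectories of a
voltage-gated K⁺ channel (Kv1.2-like, tetrameric, T-V-G-Y-G selectivity
filter) to quantify ion permeation: where ions sit, how fast they move
through, in which knock-on mode they exit, and how the surrounding
water behaves.  This note records the models, conventions, and design
choices behind each stage, and what the synthetic ground-truth
generators do and do not emulate.

## Coordinate and unit conventions

All quantities are in Å / ps / THz (1 THz = 1/ps); readers for
nm-based formats convert on ingest.  The pore axis is a unit vector,
by default +z, with the **extracellular side at larger z**.  Frames are
0-based and uniformly spaced; "the previous frame" of frame *f* is
*f − 1*.  The axial sign convention is a package convention, not a
property of the input: any trajectory can be rotated into it on load.

## Binding sites

The filter is framed by six oxygen rings of the conserved T-V-G-Y-G
sequence: the 374THR side-chain hydroxyl oxygen, then the backbone
carbonyl oxygens of 374THR, 375VAL, 376GLY, 377TYR, 378GLY.  Each ring
position is the *mean axial coordinate over the four chains*, giving a
single boundary per ring; site S4 lies between the hydroxyl and THR
carbonyl rings, S3…S0 between successive carbonyl rings, and the cavity
site S_cav extends 3 Å (0.3 nm) below the hydroxyl ring.  Intervals are
half-open `[lower, upper)`; an ion exactly on a boundary belongs to the
upper site (ties are measure-zero; the convention guarantees a
partition).  The site map is built from the first frame by default
(fixed dotted-line site positions); a per-frame mode re-derives the
boundaries each frame for a flexing filter.

Pore diameters are carbonyl-oxygen cross distances of one residue: the
tetramer has two diagonal (opposite-chain) pairs, paired by first-frame
geometry, and the reported diameter is the mean of the two diagonals.

## Permeation counting and residence times

A completed outward transit is counted with a two-plane hysteresis
rule: +1 when an ion reaches `OUTSIDE_ABOVE` having previously been on
the intracellular side (`OUTSIDE_BELOW` or `S_cav`) without an
intervening `OUTSIDE_ABOVE`; inward transits mirror this and count −1.
Recrossings of the S0 boundary that never reach the cavity side are
thermal noise, not transits.  The rule is exactly antisymmetric under
time reversal (property-tested on arbitrary label paths).

Currents follow `I = n·e/T` with `e = 1.602176634 × 10⁻¹⁹ C`; fluxes
are normalised to a 400 ns window.  Conductance `G = I/V` requires a
user-supplied transmembrane voltage — the analysis has no way to infer
it from a trajectory, so none is assumed.

The mean residence time of a site is the total time K⁺ ions spent in it
(each frame contributes one sampling interval `dt`) divided by the
number of ions that completed an outward permeation.  By default *all*
ions contribute dwell time; the `only_permeating` option restricts the
numerator to permeating ions, which is the right comparison against a
per-ion dwell model (trajectory-edge-censored and never-permeating ions
otherwise inflate the mean by roughly 1/n_events).

## Loading states and knock-on modes

The loading state is the occupancy string of S4→S0 (entry to exit):
`K` ion, `W` water oxygen, `O` vacancy; the condensed form drops
vacancies.  When both an ion and a water fall in one site the ion wins
(the ion defines the electrostatic state of the site).  At each
completed outward exit the state of the preceding frame is recorded and
classified:

| condensed state | mode |
|---|---|
| `KKK` | direct knock-on |
| `KWKWK` | soft knock-on |
| `KWKK`, `KKWK` | mixed knock-on |
| anything else | OTHER |

OTHER is reported separately and never merged into a named mode, so
literal-vocabulary proportions remain reconstructible.  A generalised
rule (count waters strictly between the first and last ion: 0 → direct,
1 → mixed, ≥2 → soft; ≥2 ions required) is available as an option for
states outside the literal vocabulary.  String orientation (S4→S0) is
recorded in output metadata.

## PMF and occupancy

The potential of mean force is Boltzmann inversion of the axial ion
density: `W(z) = −ln[n(z)/max n]` in kT, so the global minimum is
exactly 0 at the density maximum (any additive constant of a PMF is
arbitrary; pinning the minimum is a reproducible convention; multiply
by kT at 310 K for absolute energies).  Default bin width 0.2 Å
resolves the ~3 Å ring spacing with adequate counts.  Unsampled bins
report +∞ and are flagged, never interpolated.  A PMF is only
meaningful where sampling is adequate; validation profiles are
evaluated on the region within 2 kT of the well minimum (the analog of
profiling inside the filter), where every bin holds hundreds of counts
at n = 10⁵.  Site occupancy is the fraction of frames in which a site
holds ≥1 K⁺.

## VACF and vibrational spectra

`C(t) = ⟨v(t₀)·v(t₀+t)⟩ / ⟨v(t₀)²⟩`, averaged over atoms, Cartesian
components and all sliding origins (per-lag unbiased normalisation), so
`C(0) = 1` exactly.  The vibrational power spectrum is the one-sided
cosine transform `I(ω) = (2/π)∫₀^∞ C(t)cos(ωt)dt`, discretised with
trapezoid endpoint weights and evaluated as a type-I DCT
(even-extension FFT); a brute-force direct sum with identical
quadrature is kept as an oracle and agrees to ~10⁻¹⁵.  Default
velocity sampling is 4 fs (Nyquist 125 THz, comfortably above carbonyl
stretch bands); a half-Hann taper over the lags is on by default
(bias/variance compromise — the window choice is echoed in the
result); `max_lag` defaults to half the series.  Peak extraction uses
prominence-filtered local maxima (5 % of the dynamic range by default),
sorted by intensity.  Spectra operate on per-atom velocities; a
bond-projection helper isolates the stretch component of a bond (e.g.
C=O) from rigid-body motion when that is wanted.

## Hydrogen bonds

A donor–H–acceptor triplet is bonded when the donor–acceptor distance
is < 3.5 Å and the bond angle < 30°.  Geometric-criterion phrasings are
ambiguous about the angle vertex, so both conventions are implemented:
the angle at the donor between D→H and D→A (default, the common
trajectory-analysis convention), or the deviation of D–H⋯A from
linearity.  The *continuous* lifetime is the mean length of
uninterrupted bonded intervals — any unbonded frame breaks the bond
(gap tolerance 0); intervals touching either trajectory end are
censored and excluded by default (an always-on trace falls back to its
censored span, flagged).  The *survival* lifetime integrates the
normalised continuous-survival function, `ΣL²/(2ΣL)`, which equals the
dwell constant for exponential dwells.

## Synthetic ground truth

The generators emulate the statistical structure each stage assumes —
not channel physics:

* **Loading-state Markov chain** (`gen_sf_markov`): a continuous-time
  Markov chain over loading-state strings, simulated exactly
  (Gillespie) and rendered as particles.  Occupants sit at their site
  center plus Gaussian axial jitter (default σ = 0.15 Å, ≫10σ from any
  boundary at the default 3 Å ring spacing); entrants are parked below
  the cavity before entry and exited particles above S0, so the
  hysteresis counter observes complete transits.  Transitions the
  designer declares as *exits* (origin state must hold K in S0) move
  the topmost ion out; all other transitions are order-preserving
  in-filter rearrangements with entries/returns on the cavity side.
  Transitions are serialised onto distinct frame boundaries, so the
  frame before an exit shows exactly the pre-transition state — the
  mode classifier can therefore be validated to 100 % at any rate/dt.
  Whole-configuration moves, not per-ion Langevin dynamics: events and
  modes are known by construction, which is the point; kinetics beyond
  exponential holding times, field-dependent rates, and cavity
  hydration are *not* modelled, so passing tests validate the analysis
  code, not any claim about real channel kinetics.  Waters are
  represented by their oxygen only.
* **Boltzmann sampler**: inverse-CDF sampling of `exp(−U(z))` on a
  dense grid (4001 points) — an exact equilibrium-density oracle with
  no dynamics.
* **Telegraph H-bond process**: alternating exponential bonded/unbonded
  dwells rendered as triplet geometry (2.9 Å/15° bonded, 5.0 Å
  unbonded).  Frame sampling merges unbonded gaps shorter than `dt`
  and hides bonded intervals shorter than `dt`, biasing the continuous
  lifetime upward by ~+3 % at dt = τ/50 and ~+1 % at dt = τ/150;
  validation runs use the finer sampling.
* **Scheduled crossings**: linear transits at chosen times — a
  counting oracle.

Statistical validations aggregate independent replica trajectories
(different child seeds) rather than one long run, mirroring how
replicate production runs are analysed; memory per trajectory scales
with event count because every particle keeps a row in every frame.

## Problem sizes used in validation

Classifier and mode fractions: 12 replicas of a 170 ps hub-and-spoke
chain (~600 exits).  Residence times: a five-site single-file ladder
(rate 0.2/ps), 24–300 replicas (1 200–14 500 exits).  Occupancy: an
exit-free two-ion chain, 5 × 10⁴ ps at dt = 0.25 ps, compared with the
analytic stationary law.  PMF: 10⁵ samples, κ ∈ {0.5, 2} kT/Å².
Spectra: 4 fs sampling, 100 ps series, f₀ ∈ {5…30} THz.  H-bond:
τ ∈ {5, 20, 50} ps, ≥5 000 dwells.

## Known limitations

* No PBC unwrapping beyond axial projection; inputs are assumed whole.
* The transit counter needs the trajectory to *show* an ion on both
  sides; sampling intervals long enough to skip the whole filter in
  one frame still count (below → above), but the recorded pre-exit
  loading state then lags the true one.
* Conductance requires an externally known voltage.
* Zero-count PMF bins are honest +∞; no smoothing or reweighting.
* H-bond lifetimes are the continuous (uninterrupted) definition;
  intermittent/recrossing kinetics (Luzar–Chandler) are out of scope.
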