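# Methods

This note documents the models implemented in `chromodyn`, the numerical
and design choices made where the published record leaves the procedure
open, what the synthetic-data generators do and do not emulate, and the
known limitations.

## 1. Polymer model of a domain

A chromatin domain is a fiber of contour length *L* [nm] and persistence
length *l_p* [nm] folded into one of four conformations. The squared
gyration radius is

| conformation            | R_g²                                          |
|-------------------------|-----------------------------------------------|
| loop rosette, theta     | (L·l_p/6)·(2f−1)/f²                           |
| loop rosette, good      | (L^{6/5}·l_p^{4/5}/9.59)·(1.92f−0.92)/f^{11/5}|
| globule                 | L^{2/3}·l_p^{4/3}/1.76                        |
| blob                    | L·l_p/3                                       |

with *f* ≥ 1 the number of loops sharing the rosette center (ignored by
globule and blob). Internal dynamics follow a Zimm-type mode picture:
mode *p* relaxes with time τ_p = τ_1/p^x and mean-squared amplitude
a_p = c_a·R_g²/p^y, where

| conformation        | c_τ (τ_1·k_BT/η_s R_g³) | x     | c_a   | y    |
|---------------------|--------------------------|-------|-------|------|
| theta rosette       | 6.111                    | 3/2   | 0.152 | 2    |
| good-solvent rosette| 4.114                    | 17/20 | 0.172 | 9/4  |
| globule             | 7.151                    | 1     | 0.236 | 5/3  |
| blob                | 5.849                    | 3/2   | 0.152 | 2    |

**Viscosity calibration.** The effective nucleoplasmic viscosity is not a
first-principles number; the default η_s = 4.306·10⁻³ Pa·s at
T = 310.15 K is calibrated once so that the theta-rosette law maps
τ_1 = 161 ms onto R_g = 297 nm (the euchromatin reference pair). With
this single calibration all other printed (τ_1, R_g) pairs across
conformations follow from the closed forms to better than 1 %, which is
the package's internal consistency check. Both constants are
configurable (`PhysicalEnvironment`).

**Mode truncation.** Spectra are truncated at the smallest p with
a_p/a_1 < 10⁻³, capped at 50 (p_max = 32 for theta rosettes). Fits
repeated at twice the truncation change τ_1 by well under 2 %.

**Genomic content.** The effective domain volume is
V = χ_V·(4/3)πR_g³ with χ_V = 0.724, calibrated so that the
heterochromatin (245 nm, 1.56× mean density → 0.80–1.12 Mb) and
euchromatin (297 nm, 0.91× → 0.83–1.16 Mb) rows are mutually consistent;
the genomic content is then
gc = ρ_rel · c_nuc · N_A · V · NRL evaluated at both ends of the mean
nucleosome concentration interval (default 100–140 µM, NRL = 191 bp).
χ_V, concentrations, NRL and relative densities are all configurable
(`ChromatinCalibration`).

**Segment MSD.** The mean-squared displacement of a chain segment about
the domain centroid is taken as msd(t) = 2·Σ_p a_p(1 − e^{−t/τ_p}), whose
plateau 2Σa_p equals the stationary variance of the equivalent
Ornstein–Uhlenbeck mode ensemble — the convention that makes generator
and analysis exactly consistent. For the theta rosette the full series
gives a plateau of 2·0.152·ζ(2)·R_g² ≈ 0.500·R_g².

**Parameter surfaces.** For fixed (R_g, gc), each candidate linear mass
density d [nucleosomes/11 nm] fixes L = gc/(d·NRL/11 nm) and the
conformational branch is inverted for l_p; rows inside the plausibility
box (0.5–6 nuc/11 nm, l_p 10–200 nm, f ≤ 20) are flagged. Note that the
closed-form inversion for (gc = 1 Mb, d = 4.5, f = 9, R_g = 297 nm)
gives l_p ≈ 197 nm; combinations quoted elsewhere from graphical
analyses need not coincide with this inversion and no agreement is
forced.

## 2. Lattice Monte Carlo

Chains are beads on a cubic lattice (grid constant a = 30 nm, one bond =
2500 bp); consecutive beads occupy one of the 26 surrounding sites, so
bond lengths are {a, √2a, √3a} with mean ≈ 42 nm (an emergent property,
not a constraint). Self-avoidance = no double site occupancy.

* **Topology as hard constraints.** Loops are closed (first/last bead
  adjacent) and consecutive loop bases of a rosette are mutually
  adjacent, forming the rosette center. Both are enforced as adjacency
  constraints on every proposed move, so they hold exactly throughout.
* **Move set.** Single-bead displacement to one of the 26 neighbor sites,
  accepted iff the target is free (when self-avoiding), every constraint
  partner remains adjacent, and any confinement holds. Proposals are
  symmetric and the target distribution uniform over valid conformations,
  so detailed balance holds; the phantom-chain ideal-gyration test
  (⟨R_g²⟩ = N⟨b²⟩/6 with ⟨b²⟩ = (54/26)a², 3.8 % above the nominal 2a²)
  verifies this.
* **Initial construction** is deterministic: linear stretches run along
  +x, rosette loops are hairpins in the y–z plane of their base (bases on
  consecutive x sites), globular stretches are compact serpentine blocks
  whose beads are confined to a sphere sized for a volume fraction
  φ = 0.1 during equilibration. The published record does not specify a
  globule algorithm or an MC schedule; these are this package's choices.
* **Equilibration.** Defaults are 20·N sweeps of burn-in and 4·N sweeps
  between samples (N beads; one sweep = N attempted moves), several times
  the single-loop Rouse time that governs rosette shape relaxation.
  For free linear chains, which relax globally in ~N² sweeps, sampling
  starts from exact equilibrium (independent uniform bonds) instead.
* **Loop-length variants** in a configuration (`loop(100/125/150/...)`)
  are cycled across ensemble members and the resulting maps averaged,
  emulating positional noise of loop anchors.

The declared size of a `dom(y)` element is validated against the sum of
its contents with a configurable tolerance; published configuration
listings are internally inconsistent at the several-percent level, so
presets parse with the check relaxed and the realized content is
authoritative for bead counts.

## 3. Contact maps and loop calling

Contact maps are ensemble proximity frequencies: P(i,j) is the fraction
of conformations in which any bead pair of bins i, j lies within the
capture radius (default √3·a = 52 nm, the maximal bonded-neighbor
distance, so chain neighbors are in contact by construction). Bins are
0-based half-open genomic intervals, 2.5 kb by default.

The loop-calling pipeline operates on a hand-selected square domain:

1. mask the diagonal ± 30 kb (low end of the published ±30–75 kb range);
2. global profile = per column, (max + mean)/2 over unmasked entries;
3. peak detection by sliding 12-point (30 kb) parabolic fits: a concave
   fit whose vertex lies inside the stretch is a candidate; candidates
   must exceed 0.8× the profile average (the published threshold,
   interpreted as 0.8× the arithmetic mean of unmasked values) **and**
   be locally prominent: the fitted vertex-to-window-edge drop must
   exceed 4× the profile's robust point-noise (1.4826·MAD of second
   differences/√6). The prominence gate is this package's addition; the
   80 % rule alone accepts essentially any fluctuation of a flat noisy
   profile and fires on the smooth dome of a globular domain, while the
   gate reduces false high-confidence calls on structure-free noise maps
   to ≈0 per map and yields zero calls on globular domains, at full
   (11/11) recovery of planted rosette anchors;
4. candidates closer than one fit window merge (highest fitted vertex
   wins, leftmost on ties);
5. for every global peak (anchor), a local projection (row-band mean over
   ±27.5 kb) is peak-searched for partner sites; a pair recovered
   reciprocally from both of its anchors (within one fit window) is a
   high-confidence loop base, a one-directional pair low confidence.

## 4. FCS: correlator, models, window scan

**Windowed correlator.** The trace is tiled into non-overlapping windows
of length Θ; in each, G(τ) = ⟨δF_k δF_l⟩/(⟨F_k⟩⟨F_l⟩) with window-local
means, and G is averaged over windows (k = l: ACF; k ≠ l: CCF). Lags are
quasi-logarithmic (8/octave) up to Θ/5. Windows with vanishing mean are
skipped and counted. Local averaging suppresses processes slower than Θ
(bulk photobleaching, cell movement), at the cost of a predictable
downward bias.

**Estimator-bias transform.** Subtracting window-local means shifts the
estimate by the variance of the window mean plus two cross terms. For a
model ACF g evaluated on the window's sample grid, the exact expectation

    E[Ĝ(k)] = g(k) − 2·A(k) + V

(A and V from cumulative sums of g) is cheap to compute, and all fits
evaluate their model through this transform. Without it the fitted
relaxation time depends strongly on the window (2× low at Θ = 1 s for
τ_1 = 161 ms); with it the window dependence disappears, which is what
makes the window-size scan a meaningful quality check. A small residual
(−5 % on τ_1 at the default conditions) remains from the covariance of
the estimator's numerator and its window-mean normalization, a property
shared by any instrument using this normalization.

**Free diffusion.** The standard anomalous-diffusion ACF with optional
fluorescent-protein blinking:
G = (1/N)[1−Θ_T+Θ_T e^{−τ/τ_T}]·[1+(τ/τ_D)^α]^{−1}[1+(τ/τ_D)^α/κ²]^{−1/2},
κ = z_0/w_0, D = w_0²/(4τ_D).

**Polymer relaxation.** A single OU mode with per-axis variance a_p/3 and
time τ_p seen through the Gaussian focus has the correlator

    g_p(τ) ∝ (1 + u_p/υ_p)^{−1}(1 + u_p/(κ²υ_p))^{−1/2} − (const at τ→∞),
    u_p = 1 − e^{−τ/τ_p},   υ_p = 3w_0²/(4a_p),

where υ_p follows from the mode's own diffusivity D_p = a_p/(3τ_p) with
no free parameter. For a segment moving as the **sum** of its modes —
which is what a chromatin locus does and what the generator simulates —
the exact ACF compounds the displacement variances *inside* the
correlator: u(τ) = Σ_p u_p/υ_p replaces u_p/υ_p. The literal sum of
single-mode terms weighted by a_p agrees with this only in the
weak-fluctuation limit a_1 ≪ w_0²; at chromatin-domain amplitudes
(a_1 ≈ 1.3·10⁴ nm² vs w_0² = 4·10⁴ nm²) the mode-sum shape fitted to the
exact curve underestimates τ_1 about twofold. Both forms are implemented
(`relaxation_acf(form="exact"|"mode_sum")`); the exact composition is the
default fitting model, and the fitted τ_1 fixes R_g and the full
spectrum through the conformation's laws, leaving only amplitudes free.
The composite model adds a fast free-diffusion term (α = 1) when a free
fraction is present.

**Window scan.** The model is refitted across a grid of window sizes
(≥ 4 sizes spanning a decade); the plateau is the longest run of
consecutive sizes whose fitted time constants change pairwise by < 10 %,
and the smallest window of that run is selected. Traces without any
plateau are flagged invalid and excluded.

**Pooling.** A single 60-s trace determines τ_1 only to ~20 % (the
information limit of ~370 relaxation times per trace, matching the large
per-cell scatter behind published means over dozens of cells). Headline
numbers therefore pool several independent traces by averaging their
correlation functions per window before fitting; the acceptance run uses
12 × 60 s.

## 5. FRAP / CP binding kinetics

The binding scheme is strictly sequential: free →(k_on)→ short-lived
→(k_switch)→ long-lived →(k_off2)→ free, with direct release k_off1 from
the short-lived state. Closed forms, shared exactly between generators
and fitters so recovery tests are well-posed:

* **Strip-profile broadening**: Gaussian depletion of width σ with
  σ²(t) = σ_0² + 2·D_app·t; D_app is half the regression slope with its
  CI from the t-distribution of the slope.
* **Integrated strip recovery**:
  F(t) = 1 − f_slow·e^{−k_off2 t} − f_mobile·erf(h/√(2σ_0²+4D_app t)),
  complete bleaching assumed inside the strip so the free fraction
  f_free = 1 − f_slow − f_mobile is identified by the instantaneous
  recovery at t = 0⁺. The slow-exponential and slow-diffusion terms are
  partially degenerate; the fitter multi-starts over the slow share and
  k_off2 decades and keeps the best χ².
* **Continuous photobleaching**: bound state i bleaches while bound and
  exchanges with the unbleached pool, giving
  F/F₀ = f_free + Σᵢ fᵢ[k_off,i/(k_off,i+k_b) +
  (k_b/(k_off,i+k_b))e^{−(k_off,i+k_b)t}]. Rates far above k_b are
  weakly identifiable; the data must sample the fast decay (≲ 1 s) densely.
* **Point FRAP**: global two-exponential recovery with rates shared
  across bleach-duration series, amplitudes per curve.
* **Rate algebra**: stationarity of the scheme gives
  k_switch = f_long·k_off2/f_short and
  k_on = f_short·(k_off1+k_switch)/f_free; residence times are
  t_short = 1/k_off1, t_long = 1/k_off2 and the mean absorption time
  t_mean = 1/(k_off1+k_switch) + [k_switch/(k_off1+k_switch)]/k_off2.
  The closure is verified against direct ODE integration and the
  absorption time against a jump-process Monte Carlo.

## 6. Accessibility

The fiber (diameter d_f = 14 nm by default) threading a domain of volume
V excludes a probe of radius r_p from the dilated cylinder around it:
A(r_p) = max(0, 1 − L·π(d_f/2+r_p)²/V_mode). Scarce molecules see the
static volume (V); abundant molecules are adiabatically replenished into
the fluctuation-expanded volume V_dyn (default 2V, reflecting volume
fluctuations of the order of the volume itself). The 50 % accessibility
radius is r_50 = √(V_mode/(2πL)) − d_f/2. Cross-state comparisons
(heterochromatin < euchromatin < hyperacetylated) are made at fixed
genomic content — the same 1 Mb of chromatin packed at the measured
radii — because at fixed linear density the ratio V/L, not V alone,
sets r_50. This is a geometric stand-in; only orderings and orders of
magnitude are asserted, not exact limits.

## 7. Synthetic data: what is and is not emulated

Generators store every ground-truth parameter next to their output.

* **Bound emitters**: anchors uniform in a box around the focus
  (±2w_0 laterally, ±1.5z_0 axially); each emitter's displacement is the
  sum of the spectrum's OU modes, synthesized *exactly* via circulant
  embedding of the summed covariance Σ_p (a_p/3)e^{−kΔt/τ_p} (identical
  in law to stepping each mode with its exact discretization, at a
  fraction of the cost). Detection is a 3-D Gaussian; shot noise is
  Poisson per bin; optional two-state blinking (telegraph) and
  multiplicative bleaching envelope. Defaults: 250 emitters (focal
  occupancy ≈ 10), peak rate 30 kHz, Δt = 0.2 ms, 60 s — a realistic
  confocal FCS setting; the acceptance chain uses 100 emitters per trace
  and pools traces instead.
* **Free diffusion**: Gaussian steps in a periodic box, same detection.
* **FRAP/CP/point-FRAP**: the closed forms of §5 plus Gaussian noise.
* **Contact maps**: lattice-MC ensembles (§2) with binomial sampling
  noise at a finite read depth; planted loop-base coordinates emitted as
  truth.

Not emulated: detector afterpulsing and dead time, microscope drift,
spectral cross-talk, chromatin density heterogeneity within the focus,
exchange of bound emitters (anchors are fixed for the whole trace), and
experimental 5C/T2C ligation/mapping biases. Passing recovery tests
therefore demonstrates correctness of the analysis chain for the model
class it assumes, not robustness to every instrumental artifact.

## 8. Problem sizes

Default test and acceptance runs use: 50–80 conformation ensembles of the
ten-loop 1,300-kb rosette (516 beads); 12 × 60-s traces at Δt = 0.2 ms
for the relaxation-time chain; 100 seeded strip-FRAP series for CI
coverage; 20 noise-only maps for the false-positive control. These sizes
put Monte Carlo standard errors comfortably inside the stated tolerances
while keeping a full run in minutes on one core.

## 9. Known limitations

* The ACF mode-composition convention, the contact-probability estimator,
  the FRAP/CP closed forms, the volume↔genomic-content conversion, the
  MSD convention and the accessibility formulas are documented stand-ins
  chosen for internal consistency; they are not claimed to equal any
  specific unpublished derivation.
* The loop-calling prominence gate is a specificity addition beyond the
  published 80 %-threshold description (§3).
* The lattice MC has no hydrodynamics and its dynamics are not physical
  time; all dynamic quantities come from the analytic mode picture.
* Accessibility ignores probe–fiber interactions and fiber flexibility on
  the probe scale.
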