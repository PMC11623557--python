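# Methods

## The frequency-modulation cell model

`fmcell` emulates excitable-cell action potentials (APs) with a single
constant-amplitude sine generator whose frequency is modulated in time.  A
uniformly sampled trace `V(t)` (time in ms, voltage in mV) is re-expressed
as

    V(t) = C sin((ω + Δw(t)) t + φ) + offset,        t in seconds,

where `C` and `offset` are the half-range and midrange of the trace, `ω`
is a fixed carrier frequency (rad/s), `φ` a constant phase, and `Δw(t)`
(rad/s) the frequency-modulating factor.  The analysis chain is

1. **Normalization** — affine map onto [−1, 1]; exactly invertible.
2. **Phase extraction** — per-sample arcsine with branch correction gives a
   continuous total phase `θ(t)` with `sin θ = y` exactly; the varying
   phase is `φ_t = θ − ωt − φ`.
3. **Modulation** — `Δw(t) = φ_t(t)/t`, with the `t = 0` sample filled
   from its one-sided limit.
4. **Synthesis** — the displayed product form, evaluated literally.  Note
   this is *not* the integral of an instantaneous frequency; steps 2–3 are
   constructed so the product form is self-consistent, and composing the
   four steps reproduces any finite trace to floating-point accuracy
   (tested at RMSE < 1e−8 mV).

### Conventions and numerical choices

- **Units**: files and containers carry ms/mV; radians and seconds appear
  only inside the trigonometric core, through one tested conversion
  helper.
- **Carrier** `ω` defaults to one period per trace, `2π/duration`; any
  value may be passed.
- **Constant phase** `φ` defaults to `arcsin(y(0))`.  In the product form
  the modulating term vanishes at `t = 0`, so the carrier phase alone must
  reproduce the first sample; any other default breaks exactness of the
  round trip at the first sample.
- **Branch correction**: the arcsine inverse is two-valued.  The unwrapper
  tracks the signal's direction and keeps `θ` on the ascending branch
  while the signal rises and the descending branch while it falls,
  switching only after the signal retreats more than a hysteresis
  (default 0.02 of the normalized range) from its running extremum, and
  retroactively reassigning the post-extremum lag samples when a turn is
  confirmed.  A greedy nearest-candidate rule is degenerate exactly at
  |y| = 1, where the two branches coincide and floating-point accidents
  decide the global phase path; that instability is invisible to a single
  round trip (both branches satisfy the sine identity exactly) but breaks
  the comparability of profiles extracted from families of similar
  traces.  The hysteresis also keeps sub-noise ripple from winding the
  phase.
- **Conditioning**: `Δw = φ_t/t` amplifies trace noise by roughly
  `1/(t·cos θ)`.  Two practical consequences: profiles extracted near
  `t → 0` inherit any early-sample noise magnified by `1/t`, and traces
  that *start* at a voltage extremum (|y(0)| = 1) are ill-conditioned
  because `cos θ ≈ 0` there.  Families intended for coefficient
  parameterization should therefore start away from their extrema — the
  synthetic pacemaker generator starts mid-diastole, with the maximum
  diastolic potential reached after repolarization, as in a real
  sinoatrial cycle.

## Reference models

Two small ODE models provide ground-truth traces without any external
data, both integrated with fixed-step classical RK4 for determinism:

- **FitzHugh–Nagumo** (`a = 0.7`, `b = 0.8`, `ε = 0.08`, stimulus pulse
  amplitude 1.0 for 1 ms), with the dimensionless time unit read as one
  millisecond: a single suprathreshold pulse lasting a few tens of ms,
  sampled at `dt = 0.01` ms over 38.6 ms (3861 points).
- **Fenton–Karma** three-variable ventricular model with the widely used
  Beeler–Reuter-derived constants (`τ_d = 0.25`, `τ_r = 33.33`,
  `τ_si = 29`, `τ_0 = 12.5`, `τ_v⁺ = 3.33`, `τ_v1⁻ = 1250`,
  `τ_v2⁻ = 19.6`, `τ_w⁺ = 870`, `τ_w⁻ = 41`, `u_c = 0.13`, `u_v = 0.04`,
  `u_csi = 0.85`, `k = 10`), sampled at `dt = 0.01` ms over 300 ms
  (30001 points); the AP repolarizes within the window (APD90 ≈ 268 ms).

All constants are plain dataclass fields and overridable.  Rest is not an
exact fixed point of the FK equations (the tanh tail of the slow inward
current leaves a ~1e−10/ms drift); tests treat sub-microvolt excursions
as rest.  External traces enter as two-column delimited text with a
uniformity check (relative jitter < 1e−9).

## Piecewise-linear compression

`Δw` profiles are compressed into `n` continuous linear segments

    f(t) = A_k t + B_k  on  (T_{k−1}, T_k],   B_{k+1} = (A_k − A_{k+1}) T_k + B_k,

with the first segment through the origin by default (`B_1 = 0`) and an
opt-in free intercept for profiles with `Δw(0) ≠ 0` (most extracted
profiles; the flag is used wherever a profile is fitted).  Fitting
minimizes the sum of squared errors on the full sample grid:

- for fixed breakpoints the slopes are a linear least-squares solve over
  hinge basis functions (continuity holds by construction);
- the interior breakpoints are optimized by multi-start SLSQP under
  strict-ordering constraints with an analytic envelope-theorem gradient,
  `dSSE/dT_j = −2 (A_j − A_{j+1}) Σ_{t_i > T_j} r_i`;
- starts: equally spaced, curvature-weighted (knots at quantiles of the
  absolute second difference), seeded jitters (`restarts` = 8, seed 0 by
  default), an exhaustive sample-grid seed for small problems
  (≤ 150 samples, ≤ 3 segments), and optionally a split refinement of a
  coarser solution, which makes SSE non-increasing in `n` when fits are
  chained;
- ties within 1e−12 in SSE resolve to the lexicographically smaller
  breakpoint vector; everything is deterministic given the seed.

Goodness of fit: SSE, `RMSE = sqrt(SSE/K)`, `R²`, and for periodic
targets the total harmonic distortion — RMS harmonic content over the
fundamental magnitude, computed by an FFT on a window covering an integer
number of fundamental periods (non-integer windows are rejected rather
than leaked).  The square-root (RMS-ratio) THD convention is used; it is
the standard definition and reproduces the worked examples' magnitude
regime.  On the published worked-example sines (e.g. amplitude
42.5175 mV at 2.0102 rad/s, 23 segments) this fitter lands *below* the
published THD/RMSE values — the published numbers act as upper bounds for
an SSE-optimal fit.

## Blockade parameterization

A family of APs indexed by a blockade fraction `b ∈ [0, 1]` (e.g.
fractional block of the sinoatrial funny current) is compressed by fitting
free breakpoints once on the `b = 0` profile, freezing them across the
family, and re-solving only slopes and intercept per level.  Freezing
makes each coefficient a single-valued trajectory `A_i(b)`; since the
per-level solve is linear in the data, trajectories inherit the
smoothness of the family.  Each trajectory — plus `ω(b)` and `B_1(b)` —
is then summarized by a continuous piecewise-linear function of `b` with
3, 4 or 5 pieces (PL3/PL4/PL5) and free interior knots, reusing the same
segmented-least-squares engine on the blockade axis.  Lower piece counts
warm-start higher ones, so SSE is non-increasing from PL3 to PL5.
PL5 needs at least 11 levels (the fitter requires more than two samples
per segment).  Evaluating the model at an arbitrary blockade reassembles
the profile and synthesizes the AP.

The synthetic pacemaker family (`make_synthetic_ap_family`) emulates the
statistical structure this machinery assumes — AP duration varying
smoothly (by default linearly, 200 + 100·b ms) with blockade, fixed
amplitude, a diastolic pedestal — not the biophysics of any detailed
sinoatrial model.  Its default is noiseless because it stands in for
deterministic ODE solutions; the noise-robustness fixtures state their σ
explicitly (0.001 mV, solver-scale — see the conditioning note above for
why trace noise is a first-class study condition here).  What passing
tests show is that the compression/parameterization machinery recovers
smooth blockade laws and interpolates held-out levels on such families;
they do not show robustness to recording-level noise or to families whose
morphology changes non-smoothly.

## State controller and tissue

Each reconstructed cell is a two-state automaton: resting (emits
`V_rest`) until the sensed voltage reaches `V_th`, then playback of the
stored waveform table for its full `k` samples (further stimuli ignored —
absolute refractoriness by construction), then rest.  `V_th` defaults to
`V_rest` + 10 % of the waveform range; `V_rest` to the first waveform
sample.  Playback reads a precomputed table resampled to the simulation
step; reconstruction at run time would repeat identical arithmetic.

Tissue couples cells on a chain or square lattice with unit spacing
through the discrete Laplacian (3-point in 1-D, 5-point in 2-D) with
no-flux boundaries:

    V_in[c] = V[c] + D · L(V)[c].

The diffusion term only *triggers* the controller; a playing cell's
emitted voltage is the stored waveform unchanged.  This trigger-only
semantics keeps the playback shape invariant under coupling, which is
what makes the adjacent-cell conduction lag `T_adj` independent of tissue
size — the model's headline tissue invariant.  Whether diffusion should
also deform the waveform (monodomain-style) is a genuine modeling fork;
the deformation variant would couple amplitude to `D` and break the
size-invariance this model is designed around, so it is out of scope
here.

Wavefront metrics: per-cell peak time = time of the first sample
attaining that cell's maximum (first-sample tie-break); `Tp1`, `Tpmid`,
`TpNN` at the top-left corner, center `(N²+1)/2` and bottom-right corner
of the row-major 1-based lattice; `T_mc1 = |Tp1 − Tpmid|`,
`T_mNN = |TpNN − Tpmid|`; `T_adj` = lag between a stimulated cell and its
orthogonal neighbors, which must agree to within half a step (asserted,
not assumed).  Cells that never fire yield absent (`None`) metrics rather
than fabricated times.  `D_min`, the smallest coupling that lets a
2-cell test propagate, is found by bisection on the (monotone)
propagation predicate; because triggering is linear in `D`, the threshold
is sharp at `(V_th − V_rest)/(max waveform − V_rest)`.

Dysfunctional ("lesioned") regions are clamped 5 mV below rest (configurable),
never fire, and repel the wavefront through their sub-resting contribution
to neighbors' Laplacians; stimulated cells cannot be lesioned.  Lesion
strips that block all monotone lattice paths to a corner delay that
corner's peak while leaving the stimulated cell's own peak and `T_adj`
unchanged.

Default tissue study conditions in the tests: the FHN waveform resampled
to `dt = 0.1` ms, `D = 0.15` (≈ 1.2 × the 2-cell `D_min` ≈ 0.128 for that
waveform's dimensionless amplitude), grids 7×7 / 15×15 / 31×31, lesion
experiments on 17×17.  Because the published tissue timings depend on an
unpublished ventricular parameterization and stimulus amplitude, the
tests assert the structural invariants (size-invariant `T_adj`, mirror
symmetry, distance doubling, lesion delays) rather than absolute
milliseconds.

## Known limitations

- The product-form synthesis ties `Δw`'s meaning to the time origin;
  profiles are not translation-invariant, and segment slopes near `t = 0`
  are the most noise-sensitive quantities in the pipeline.
- No rate dependence: playback is an exact replay, so AP-duration
  restitution and S1–S2 pacing behavior are absent by design.
- Re-excitation is possible once playback ends if a neighbor is still
  suprathreshold; with AP-like waveforms that end near rest this does not
  occur in the shipped configurations.
- Single-component model: morphologies whose arcsine phase path winds
  many times per sample interval (relative to the carrier) compress
  poorly compared to multi-sinusoid approaches.
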