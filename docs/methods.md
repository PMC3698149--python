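# Methods

This note documents the models behind `gelrange`, the defaults and why
they were chosen, and what the synthetic generators do and do not emulate.

## Range measurement and WEPL

A depth scan records the ionisation-chamber charge ratio versus
water-column thickness in 0.1 mm steps; the Bragg-peak position on that
axis is the residual range behind the sample in mmH₂O. The sample WEPL
follows from the peak shift between the water-filled and gel-filled vial,
`WEPL = 1 + (vial_w − vial_g)/d` with `d = 32 mm`; every term common to
the two configurations (caps, holder, beam energy) cancels.

**Peak localisation.** A parabola is fitted to the 5–9 samples around the
curve maximum; the vertex is the sub-step peak estimate. The vertex
standard error is propagated from the fit residual variance by the delta
method (`v = −c₁/2c₂`, gradient-based covariance propagation). A maximum
on the scan edge, or a non-concave fit window, raises a "peak not
bracketed" error rather than returning an extrapolated vertex.

**Session normalisation.** Day-to-day beam/positioning drift is absorbed
by one additive offset per session, fixed so the no-absorber scan matches
its beam-model range. The offset shifts every measurement uniformly, so it
verifies data quality without influencing the WEPL, which depends only on
differences. The operation is idempotent.

**Uncertainty budget.** Components are combined in quadrature and reported
at 2σ. The stepping (`u_step = 0.1 mm`), peak-fit (`u_fit`, of order the
step) and vial-manufacture (`u_vial = 0.05 mm` PMMA → ×1.165 mmH₂O) terms
are treated as 2σ-level bounds and enter unchanged; the scatter over
rotated-vial repeats enters as the 2σ standard error of the mean,
`2·sd/√n`. With the quoted component bounds this combines to ≈0.2 mmH₂O,
matching the quoted single-position uncertainty at its printed precision.
On the WEPL scale, position-level components affect both peak positions
independently (factor √2/d); the sample term affects only the gel mean
(factor 1/d). The calibration of the fit term is verified by a
500-replicate coverage test: the empirical 2σ spread of recovered peak
positions under scan noise must match the propagated prediction within a
third.

**Air entrapment.** Imperfect polymerisation leaves bubbles; a volume
fraction `f` of air shifts the peak by `f·d·WEPL_material` and lowers the
apparent WEPL by `f·WEPL_material`. The operation implements this
arithmetic exactly (3 % air over 32 mm of gel ≈ 0.97 mmH₂O, ΔWEPL ≈ 0.03);
quoted rounded figures for this effect are presentation, not separate
physics.

## CT, HLUT and planning impact

ROI statistics use voxel-centre inclusion in a circle repeated over
slices; positions follow the voxel-centre convention `(i + 0.5)·spacing`
with 0-based indices. The spread is reported at 2σ (sample SD).

The default HLUT is piecewise linear, anchored at air (−1000 → 0.001) and
water (0 → 1.000), with the soft-tissue segment calibrated so 28.9 HU maps
to 1.027 — the planning-system pair in clinical use for this material; the
bone-side breakpoints (1500 → 1.80, 3071 → 2.50) are generic conventions,
since the clinical table itself is not public. Lookups outside the domain
raise instead of clamping so fixture bugs surface. No stoichiometric
calibration from elemental compositions is attempted.

The planning impact of a WEPL discrepancy is linear: `shift = ΔWEPL · L`
with `L = 40 mm` a typical gel path. Treated as an independent random
error it extends a PTV margin by `√(m² + s²) − m`, which for m = 5–7 mm
and s ≈ 0.65 mm is 0.03–0.04 mm — negligible against the margins
themselves. These operations implement the stated formulas; rounded
headline figures derived from them are not separately modelled.

## Dose conversion

With a constant RBE the absorbed dose is the RBE-weighted prescription
divided by RBE (100 Gy (RBE) → 33.3 Gy at RBE 3 for carbon, 90.9 Gy at
RBE 1.1 for protons). The exact quotient is kept; integer-Gy rounding is a
reporting rule only, applied by `report_integer_gy`.

## PET activity model

Per depth bin and isotope, with decay constant λ = ln2/T½:

- build-up over beam-on `T`: `A(T) = R(1 − e^{−λT})` for a constant
  production rate `R`;
- transport delay `Δ`: `A₀ = A(T)·e^{−λΔ}`;
- frame `[t₁, t₂]` of the acquisition:
  `⟨A⟩ = A₀(e^{−λt₁} − e^{−λt₂})/(λ(t₂−t₁))`, evaluated via `expm1` for
  numerical stability on short frames.

Activity volumes are laterally integrated (sum over both transverse axes)
before fitting to maximise counting statistics, and profiles are compared
area-normalised (`Σ value·bin_width = 1`).

**Decomposition.** Because the candidate half-lives are fixed and known
(¹¹C 1222 s, ¹⁵O 120 s, ¹³N 598 s; ³⁸K 458 s exists in the registry but is
excluded from phantom fits — PMMA, hydrogel and gelatin contain no
potassium), the dynamic frames are linear in the per-isotope A₀. Each
depth bin is solved by non-negative least squares against the
frame-average basis. The basis condition number is checked first;
indistinguishable half-lives raise an error instead of returning an
arbitrary split. Fits are unweighted: at the count levels of interest the
per-frame variances are within a small factor of each other and the
simplicity is worth more than the marginal efficiency gain.

**Framing.** The acquisition framing is free in the measurement protocol;
the default is ten contiguous 180 s frames over the 1800 s acquisition —
early frames short enough to resolve ¹⁵O, late frames long enough to pin
¹¹C. The default timeline (215 s beam-on, 176 s delay, 1800 s acquisition)
reflects the phantom irradiation it emulates. With it, the ¹⁵O share of
the frame-averaged signal is strictly below its share of A₀ — the
measured image is ¹¹C-dominated even where ¹⁵O dominates production.

**Washout.** In perfused tissue, physiological clearance adds a rate to
the decay constant (`λ → λ + r`); in the confined gel implant it does not.
`washout_apply` returns the unchanged A₀ profile together with an
effective isotope carrying the modified half-life, leaving downstream
closed forms unchanged.

## Synthetic generators

The generators emulate the statistical structure the analysis assumes;
each is exactly invertible in its noiseless mode, which is the basis of
the round-trip tests.

- **Depth scans.** A piecewise analytic Bragg model: constant entrance
  plateau, monotone C¹ Hermite rise, an *exactly parabolic* cap of
  half-width 0.8 mm around the peak, monotone Hermite fall-off, constant
  fragmentation tail. The exactly quadratic cap makes the parabolic peak
  interpolation bias-free at any sampling phase, so noiseless scans invert
  to machine precision and the WEPL round-trip is exact to < 1e-6 by
  construction rather than by tolerance tuning. Shape constants
  (peak/plateau 3.5, fall-off over ~3 mm) mimic a 200 MeV/u carbon curve;
  only the peak position carries information, so any realistic unimodal
  shape would serve. Noise is additive Gaussian per point (default
  0.01 charge-ratio units in fixtures, giving a peak-position scatter of
  the same order as the quoted measurement uncertainty).
- **CT phantom.** A 16 cm PMMA sphere (HU 120, a fixture convention —
  the phantom HU and CT noise level are not published) containing the gel
  cylinder at Normal(28.9, 3.05) HU (2σ = 6.1), optional Bernoulli air
  bubbles at −1000 HU, air background; default grid 3 mm slices,
  0.6055 mm pixels.
- **Yield profiles.** A deterministic parametric stand-in for Monte-Carlo
  transport: per-material total production per primary per mm (PMMA
  4.0e−4, gel 3.2e−4, gelatin 3.4e−4) split by fixed per-material isotope
  mixes (PMMA: 75 % ¹¹C / 20 % ¹⁵O / 5 % ¹³N; gel: 25/65/10;
  gelatin: 30/60/10 — carbon-rich PMMA ¹¹C-dominated, water-dominated
  media ¹⁵O-dominated), modulated by a plateau with a mild rise and a
  smoothstep distal fall-off that is exactly zero beyond
  `beam_range + falloff_width`. Magnitudes are order-of-magnitude
  realistic for ~2×10¹¹ protons, not cross-section-derived.
- **Activity frames.** Expected decays per bin per frame from the closed
  forms above, Poisson-sampled and converted to Bq/ml by frame length and
  bin volume (default 10 ml per 1 mm lateral-integrated bin).

Randomness discipline: one seed per invocation; each generator draws from
a named substream (`SeedSequence([seed, crc32(name)])`), so fixtures are
mutually independent and reproducible.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: tomographic reconstruction and its resolution/
scatter/randoms effects, scanner sensitivity and dose calibration
(including absolute activity levels), lateral beam scattering and detector
response in the water column, CT beam-hardening and partial-volume
effects, and any cross-section physics. Absolute PET activity values are
therefore arbitrary-scale; only relative structure (shares, positions,
time constants) is meaningful.

## Problem sizes

Default study sizes: 500 replicates for the peak-scatter coverage test,
200 replicates for the Poisson decomposition study (gel-only phantom,
30 bins, ten 180 s frames, ≥10⁴ expected counts per frame and bin in the
beam path — a deliberate high-statistics regime; the recovery criterion is
the absolute deviation of each isotope's activity share, ≤ 0.05), and a
44 mm sphere at coarser spacing for CT unit tests with the full-size
phantom reserved for fixture generation.

## Known limitations

- The HLUT is a calibrated stand-in anchored at one soft-tissue point; it
  is not the clinical table.
- The uncertainty budget treats quoted component bounds as 2σ-level
  values; other conventions (uniform-distribution reduction) would lower
  the combined figure by ~15 %.
- Yield magnitudes and the 10 ml bin volume set the simulated count scale;
  conclusions about absolute detectability of the gel signal are outside
  scope.
- The NNLS decomposition assumes the isotope set is known; an unmodelled
  emitter biases the recovered shares.
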