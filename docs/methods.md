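# Methods

## The turnover model

Sedimentary hydrolysable aspartic acid is treated as two pools. Living
cells hold their D:L-Asp at `dl_live` = 0.014 (D fraction
f = 0.014/1.014 ≈ 0.0138) by repairing or replacing racemized residues;
racemization inside living biomass is not modeled. Necromass racemizes
freely and is degraded while fresh biomass dies into it. With quasi-steady
cell numbers the necromass throughput flux is F = A/T_NM (A the necromass
Asp pool), giving

    dD/dt = k·L − (k/K)·D − D/T_NM + F·f
    dL/dt = (k/K)·D − k·L − L/T_NM + F·(1 − f)

where k is the forward racemization rate constant and K the equilibrium
D:L (1.0 for Asp by symmetry; exposed in the calibration for generality).
Degradation is isomer-nonselective — it removes D and L in proportion —
which is the minimal assumption under which a single Arrhenius law
reproduces both published anchor pairs (below). The steady state inverts in
closed form:

    T_NM = (d − f) / (k·(1 − d·(1 + 1/K)))        d = D/(D+L) of necromass

and the biomass turnover time follows from flux balance,
T_b = T_NM · Asp_bio/Asp_necro. `forward_necromass` integrates the ODEs
directly (Radau, rtol 1e-10) and is used throughout the tests as the
independent oracle for the analytic inversion; the two agree to better
than 0.1 % over four decades of T_NM and five of k.

Inversion of a measured horizon proceeds: hydrolysis correction of the bulk
D fraction (unless the measurement is flagged as already corrected), in-situ
temperature from the thermal model, k from the Arrhenius law, subtraction of
the living-biomass D and L contribution (at f) from the bulk pool to obtain
the necromass D fraction, the closed-form T_NM, then T_b. Because biomass
is <1 % of the pool, the bulk ≈ necromass approximation changes T_NM only in
the third digit; the subtraction is kept for exactness of synthetic round
trips. Horizons whose corrected fraction falls at or below f are flagged
`below_live_ratio` (the data imply zero-age necromass — usually noise);
fractions at or above equilibrium are flagged `near_equilibrium` with
T_NM = ∞. Failures never abort a station.

## Racemization kinetics and calibration

k(T) = exp(ln A − Ea/(R·T_K)). No numerical Arrhenius parameters are
published for this system, so the default calibration is fit through the two
printed anchor pairs the steady-state inversion fixes: (D:L 0.481,
T_NM 4 yr, 65.51 °C) and (D:L 0.101, T_NM 1731 yr, 7.855 °C). Back-solving
k from each pair and fitting the two-point Arrhenius line gives

    Ea = 113907 J/mol,   ln A = 38.9474   (source_tag "anchor-fit-v1")

frozen at six significant digits in `default_calibration()`. The anchors
are reproduced to <0.01 % by construction; every other number the package
produces with this calibration is a genuine prediction of the one-law
model. Literature calibrations can be substituted via the config file; the
active `source_tag` is recorded in every run log. Printed D:L anchors are
taken as already hydrolysis-corrected.

The hydrolysis correction inverts the forward map d_m = d_t + h(1 − d_t)
with h = 0.044, so a racemization-free standard reading exactly 4.4 % D
corrects to zero; plain subtraction of 0.044 is available as a config
alternative (`hydrolysis_correction: subtract`). Readings below h clamp to
zero with a `below_blank` flag, never negative.

## Chronology and temperature

Age is linear in depth, age = depth/rate, with one constant sedimentation
rate per station and no compaction correction — consistent with a single
published rate per site. Temperature is linear in depth and anchored at the
deepest sample (the only printed anchor): T(z) = T_deep − G·(z_max − z)/100.
Depths beyond core recovery extrapolate the same line and are flagged.
Sedimentation rates from excess Pb-210 use the CF-CS model: excess = total
Pb-210 minus Pb-214-indexed supported activity (non-positive excess becomes
absent, flagged, never zero), then OLS of ln(excess) on interval-midpoint
depth in mm; rate = λ/|slope| with λ = 0.03114 /yr. Which regression
variant produced the published rates is not stated; the fit diagnostics
(R², n, slope) are returned so users can judge.

## Pools and unit bridges

qPCR copies become cells with 4.0 (Bacteria) and 1.6 (Archaea) copies per
cell. Total cell counts (flow cytometry, per cm³ wet sediment) set the
biomass size; qPCR sets only the Bacteria/Archaea split (50/50 when
absent). The per-mass bridge divides by (1 − φ)·ρ with porosity φ = 0.8 and
grain density ρ = 2.5 g/cm³ — the source data leave this conversion
implicit, so both are plain config constants. Per-cell Asp content defaults
to 3 × 10⁻¹⁷ mol for both domains (order-of-magnitude: ~30 fg C per
deep-biosphere cell, ~55 % of it amino-acid carbon, Asp ~8 mol% of
protein); T_NM is independent of this constant to first order (it only
enters through the <1 % biomass subtraction), T_b is directly proportional
to it, and it is fully exposed in the config. Amino-sugar concentrations
are corrected for hydrolysis losses of 25.5 % (GlcN) and 21.6 % (GalN) by
dividing by (1 − loss).

## Indicator suite

%TAA-C and %TAA-N use a built-in immutable atom-count table (Asp 4 C/1 N,
Gly 2/1, Lys 6/2, His 6/3, Arg 6/4, ...). Amino sugars are excluded from
both indices and from the protein-THAA sum; β-Ala and γ-Aba are excluded
from THAA but their C and N do count toward the indices (they are
amino-acid-derived). Values above 100 % are flagged as inconsistent, not
clipped. Ratios are molar; a zero denominator yields an absent (NaN)
value with a flag, never infinity. The cells-vs-%TAA-C power law is OLS on
(ln x, ln y); the correlation is reported as r, not r².

## Synthetic stations

The generator emulates the statistical structure the analysis assumes:
THAA decays exponentially with depth; a fixed Asp mole fraction (7.5 % of
THAA) enforces the observed tight Asp–THAA linearity; D- and L-Asp are
produced by running the forward necromass ODE at a configured true T_NM(z)
plus the biomass contribution at f, then pushed through the forward
hydrolysis map; cells follow cells = 8.94 × 10⁶ · (%TAA-C)^1.44; qPCR
copies come from a linear archaeal-fraction ramp (50→90 % at the hot
templates); excess Pb-210 decays exponentially at the configured rate over
the multi-core interval grid (1-cm steps to 4 cm, 2-cm to 20 cm, 4-cm to
40 cm); VFAs are constant-low (0.3–3 μM uniform) QC columns with no depth
trend. Noise is multiplicative lognormal, applied last and independently
per measured quantity from a single seed — D and L are noised separately so
ratio noise emerges naturally — and σ = 0 yields a deterministic function
of the configuration.

Three templates carry the published site-table metadata exactly
(2.10/0.79/0.79 mm/yr; 8.83/74.27/65.51 °C deepest-sample temperatures;
0.13/11.44/9.86 °C/m gradients; 10 horizons from 250/37/48 cmbsf every
100/50/50 cm). Their true T_NM(z) profiles are log-linear in depth between
the published top/bottom turnover times (1731→2572, 182→8, 63→4 yr).
These profiles are illustrative: at the real sites T_NM is an output, not
an input, and the generator makes no attempt to reproduce the measured
per-horizon profiles point for point. The alternative rule
T_NM(z) = c/k(T(z)) is supported in the config but is not the template
default, because a constant k·T_NM makes the steady-state D:L
depth-invariant, losing the depth-increasing structure real profiles show.
What passing round-trip tests demonstrate is internal consistency of
forward model and inversion under the assumed noise structure — not that
real sediments satisfy the steady-state or single-pool assumptions.

## Numerical choices

- Steady-state ODE integration runs to 60 relaxation times
  τ = 1/(k(1+1/K) + 1/T_NM) and verifies the residual drift; this adapts to
  both the stiff fast-turnover limit and the slow racemization limit.
- The closed-system solution uses the `expm1` form, exact at t = 0 and
  saturating cleanly at equilibrium.
- The hydrolysis clamp uses a 1e-9 relative guard so a reading exactly at
  the blank is a correction to zero, not a flagged clamp.
- Results CSVs round-trip at 12 significant digits; unbounded T_NM is the
  sentinel string `inf`, impossible inversions are empty cells.
- Problem sizes follow the emulated study design: 10 horizons per station,
  17 radionuclide intervals, 100 random triples for oracle equivalence,
  n = 30 for power-law recovery.

## Known limitations

- Single necromass Asp pool, no reactivity spectrum; non-steady-state
  (transient) inversion is deliberately refused rather than approximated.
- Instantaneous in-situ temperatures; no burial-history integration of the
  thermal path.
- The anchor-fit calibration inherits any bias of the two printed anchors;
  it is a two-point fit, not an independent kinetic study.
- Compaction, salt correction and CRS-style variable-flux chronologies are
  out of scope.
- T_b scales linearly with the per-cell Asp content, which is known only to
  order of magnitude.
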