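# dlamino

Microbial necromass and biomass turnover times from aspartic-acid
racemization in marine sediment depth profiles — with the full
organic-matter source/diagenesis indicator suite, Pb-210 excess chronology,
and a synthetic-station generator so the entire pipeline is testable without
any field data.

## The problem

Most of the microbial biosphere lives buried in seabed sediment, where
activity is too slow to measure by incubation. Aspartic acid provides a
built-in clock: chemical racemization converts its L-form to the D-form at a
strongly temperature-dependent rate, living cells repair or replace
racemized residues and hold a low D:L ratio (~0.014), while dead biomass
(necromass) racemizes freely toward equilibrium (D:L → 1). The measured
D:L-Asp of bulk sediment therefore encodes how fast necromass is being
degraded and replaced by fresh biomass.

## The model

Sedimentary hydrolysable Asp is split into a living pool pinned at the
living-cell D fraction *f* = 0.014/1.014 and a necromass pool that
racemizes (rate constant *k*, Arrhenius in temperature) while being turned
over with time constant *T*<sub>NM</sub>. At quasi-steady state (necromass
degraded = biomass produced) the necromass D fraction
*d* = D/(D+L) inverts in closed form:

```
T_NM = (d − f) / (k · (1 − 2d))          (equilibrium D:L = 1)
T_b  = T_NM · Asp_bio / Asp_necro
```

with *T*<sub>b</sub> the living-biomass turnover time, scaled by the pool
ratio (biomass Asp from cell counts, necromass Asp as the remainder —
typically >99 % of the pool). A forward ODE simulator of the same
production/degradation/racemization balance serves as an independent oracle
for the analytic inversion. Measured D fractions are first corrected for
the 4.4 % D induced by acid hydrolysis via d<sub>true</sub> =
(d<sub>meas</sub> − 0.044)/(1 − 0.044).

Around the core model the package computes the standard context variables:
%TAA-C and %TAA-N (share of TOC/TN still present as amino acids),
Asp:β-Ala, Glu:γ-Aba, Gly:Ser and GlcN:GalN ratios, cells-vs-%TAA-C power
laws, and CF-CS sedimentation rates from excess Pb-210.

## Worked example

Invert the warmest published anchor — D:L-Asp = 0.481 at the 65.51 °C base
of a hydrothermally heated core — and recover its turnover time:

```python
from dlamino import ModelConstants, default_calibration
from dlamino.racemization import k_asp
from dlamino.turnover import tnm_steady_state, tb_from_tnm

constants = ModelConstants()
calib = default_calibration()

d = 0.481 / (1 + 0.481)            # measured ratio -> D fraction
k = k_asp(65.51, calib)            # 0.2219 /yr at the core base
t_nm = tnm_steady_state(d, k, constants.dl_live)
print(f"k = {k:.4f} /yr, T_NM = {t_nm:.2f} yr")
print(f"T_b = {tb_from_tnm(t_nm, 6.85e-4, 1.0) * 365.25:.1f} d")
```

prints

```
k = 0.2219 /yr, T_NM = 4.00 yr
T_b = 1.0 d
```

i.e. necromass at the hot core base turns over in about 4 years, and with a
biomass:necromass Asp pool ratio of ~7 × 10⁻⁴ the living community replaces
itself in about a day. The same inversion at a cold-station horizon
(D:L = 0.101, 7.86 °C) gives T_NM ≈ 1731 yr — a three-orders-of-magnitude
temperature effect.

An end-to-end run on synthetic data:

```sh
dlamino generate --template SO241-58 --seed 1 --out-dir station
dlamino run --in station --out outputs
dlamino selftest
```

The `analysis/` scripts chain the same steps over all three station
templates (generation, Pb-210 chronology, indicator suite, turnover
inversion, temperature dependence) and write their tables under `results/`.

## Layout

- `src/dlamino/` — the library: `profiles_io` (types + CSV schemas),
  `chronology`, `racemization`, `turnover`, `pools`, `indicators`,
  `synthetic`, `config`, `cli`
- `analysis/` — numbered drivers over the library
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — model assumptions, calibration, numerical choices,
  limitations
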