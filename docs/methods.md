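# Methods

## Model

`gaspbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model for inhaled inert gases (xenon, argon) in mouse, rat, pig and
human. The gas is not metabolised and is not excreted by any route other
than exhalation, so the whole ADME description reduces to reversible,
flow-limited transport:

**Lung.** Alveolar gas and pulmonary capillary blood equilibrate
instantaneously according to the blood:gas partition coefficient. With a
pulmonary shunt fraction *s* (default 0.10) and a ventilatory mixing factor
*m* (default 0.90) multiplying alveolar ventilation *AV*, blood leaving the
lung carries

```
C_lung_out = (1 − s) · (m·AV·C_inh + CO·C_ven) / (CO + m·AV / PC_b:g) + s·C_ven
```

where *CO* is cardiac output and `C_inh = P_total/(R·T) · %gas/100` is the
ideal-gas molar concentration of the inhaled mixture (defaults 1 atm,
298 K). At the fixed point `C_ven = PC_b:g·C_inh` the lung returns
`PC_b:g·C_inh` for any shunt, so saturation concentrations are
shunt-independent. Dead space (32.5 % of minute ventilation) is only used
to derive *AV* when a species table does not list it; the shipped tables
list *AV* directly. The 90 %/10 % alveolar/inhaled composition of exhaled
gas is exposed as a derived output (`exhaled_concentration`) and does not
feed back into uptake.

**Blood.** Arterial and venous blood are dynamic well-mixed pools.
The arterial pool (volume = arterial + lung-blood fractions × body weight)
is fed at *CO* with lung effluent; the venous pool is fed at *CO* with the
mixed venous return `Σ Q_i·C_i/PC_i + (CO − Σ Q_i)·C_art`. The residual
cardiac output `(1 − Σ f_i)·CO` (1.67 % in the human table, whose printed
perfusion fractions sum to 0.9833) is routed as an arteriovenous bypass
carrying arterial blood unchanged — flow is conserved without renormalising
printed fractions. A finite arterial volume is required to give blood a
finite washout half-time; the reference study left the blood dynamics
unstated and this choice is the main formulation freedom in the model (see
Limitations).

**Tissues.** Every tissue is perfusion-limited: effluent venous blood is in
equilibrium with the tissue, `C_ven,i = C_i / PC_i`, giving

```
dC_i/dt = Q_i · (C_art − C_i / PC_i) / V_i
```

with `Q_i = f_perf,i·CO` and `V_i = f_vol,i·BW/ρ_i` (density 1 kg/L by
default, overridable per compartment; the shipped volume fractions are
taken as final). Each tissue's intrinsic time constant is
`τ_i = PC_i·V_i/Q_i` — from ~0.04 min (rat brain) to ~975 min (human poorly
perfused fat), which is what makes the system stiff and what makes fat a
long-lived reservoir under repeated dosing.

The resulting ODE system is linear and time-invariant between dose
transitions. A cumulative-uptake state `dU/dt = CO·(C_lung_out − C_ven)`
is integrated alongside the concentrations so mass balance can be audited
against `Σ V_i·C_i` at solver accuracy rather than quadrature accuracy.

## Parameters

The parameter library (YAML, one file per species and per gas) carries the
reference physiology and partition coefficients verbatim: body weight,
minute/alveolar ventilation, cardiac output, per-compartment perfusion and
volume fractions, blood-pool fractions, blood:gas and tissue:blood Ostwald
partition coefficients, and each gas' atmospheric abundance (8.7×10⁻⁶ %
Xe, 1 % Ar). Species differ in compartment structure: only the human
splits fat into richly/poorly perfused pools; mouse and rat have no
separate poorly perfused tissue; the pig lung-blood volume is unavailable
and defaults to zero. The mouse column prints minute ventilation
0.385 L/min against alveolar ventilation 0.025 L/min — mutually
inconsistent with the 32.5 % dead-space rule; both are stored as printed
and the alveolar value is what the lung equation consumes.

Argon's fat:blood coefficient 4.162 is the ratio of Ostwald solubilities
(olive oil 0.154 / blood 0.037), olive oil standing in for fat; the
`partition` module generalises this and fits OLS tissue-vs-fat
correlations for extending the library to new gases. It is an estimator
for new entries, not a build-time generator of the shipped tables, because
the correlations behind the published tables are not recoverable.

Intersubject scaling (`scale_subject`) sets the total fat volume fraction
to the gender mean (13.5 % male / 26.5 % female, or an explicit value),
splits it in the base model's fat ratio, and rescales the other tissue
fractions by a common factor so their mutual ratios and the total tissue
fraction are preserved. Cardiac output and ventilation scale as
`(W/W₀)^0.75` by default and blood-volume fractions are kept (absolute
volumes ∝ W); all three are user-pluggable hooks because the external
correlations the reference work cites are not reproduced in it. The
exponent 0.75 is the standard allometric choice for flows; with identity
hooks the base model is an exact fixed point.

## Numerics

- Integrator: LSODA (`scipy.integrate.odeint`) with the constant system
  Jacobian supplied; its stiff mode (BDF) is the scipy analogue of the
  MATLAB `ode15s` family used in the reference study.
- Maximum step 0.5 s (1/120 min), `rtol 1e-8`, `atol 1e-12`. The venous
  AUC computed with a 0.5-s cap agrees with a 0.1-s cap to ~1e-8 %.
- Integration restarts at every episode boundary so the stiff solver
  never steps across a dosing discontinuity.
- Output sampling: 0.1 min, refined to 0.01 min for 5 min after every
  dose transition to resolve arterial half-times down to ~0.05 min.
- Tiny negative excursions (within solver tolerance of zero) are clipped.
- Initial condition is zero body burden: ambient pre-exposure is
  neglected (it can be emulated with a low-percent pre-equilibration
  episode).

## PK metric conventions

- **AUC** is trapezoidal. Two windows are supported: the full simulated
  window (default; exposure + 1440 min post-dose) and the
  *administration window* (up to the end of the last episode). The
  published reference table that `reference_report` compares against was
  computed with the administration-window convention — reproducing all
  26 consistent rows within 1.6 % — so the comparison harness and the
  acceptance script use it. For slow fat stores the two differ by ~10×:
  most fat exposure accrues after dosing ends.
- **Cmax / observed tmax**: global maximum, earliest-time tie-break.
- **t½**: measured directly on the curve — time from Cmax until the
  concentration first falls to Cmax/2, searched from the end of
  administration, linearly interpolated between samples.
- **Reported tmax**: `t½ × 8/ln 2 ≈ 11.54 × t½`. This constant is the one
  that reproduces every published tmax from its t½; a stated "four times
  the time constant" rule would give 4/ln 2 ≈ 5.77 and matches none of
  them. Both observed and reported tmax are carried in summaries.
- **Residual dose**: concentration sampled one output step before each
  episode start; cycle 1 of a gas-naive subject is 0 by construction.
- **Equivalent inhaled percent**: inverse of the saturation relation,
  `100·C_blood/(PC_b:g · P/(RT))`.

## What the reference comparison does and does not show

`reference_report` reproduces published Cmax for every species and AUC for
human (Xe and Ar) and pig within a few percent, which validates the lung
equation, the parameter resolution and the integrator. Three families of
published entries are *not* reproducible from the shipped parameter
tables, by internal inconsistency of the published values rather than by
model choice, and the comparison shows them honestly:

1. **Rat AUC/Cmax.** The published rat venous AUC (0.984 mol·min/L)
   exceeds the theoretical upper bound for a 0.25-kg body under any
   perfusion-limited model with these coefficients (saturation × 60 min +
   whole-body capacity/CO ≈ 0.33 mol·min/L), and the published rat muscle
   Cmax (0.37× saturation after 60 min) contradicts the published rat t½
   values, which are consistent with the parameter table and with this
   implementation.
2. **Slow-compartment t½.** Fat and poorly-perfused t½ entries of ~29–30
   min are incompatible with those compartments' intrinsic time constants
   (244–975 min): no compartment obeying the flow-limited equation can
   halve from Cmax in 30 min. The estimator behind those entries is not
   recoverable; this package reports the directly measured value.
3. **One decimal typo.** The human-Xe poorly-perfused AUC prints 1.58E-03
   where the administration-window integral gives 1.578E-02 — the same
   mantissa, ten times the magnitude.

Measured blood and muscle t½ also run 16–35 % above the published values;
they are sensitive to the blood-pool formulation (arterial volume, lung
blood placement) that the reference study does not specify. Similarly,
the plateau pre-dose residual after ten daily xenon doses converts to an
equivalent constant inhalation of 0.004 % using arterial blood and
0.016 % using venous blood; the published "0.01 %" lies between the two,
inside this formulation ambiguity.

## Limitations

- Steady-state ventilation only: no intra-breath dynamics, no ventilatory
  heterogeneity, no diffusion-limited exchange, no metabolism.
- The arterial pool is a single well-mixed volume; blood washout
  half-times inherit its uncertainty (see above).
- Ostwald coefficients are used without temperature correction, and
  hematocrit or protein-binding effects on blood solubility are ignored.
- Delivery-device wash-in (ventilator circuits, animal boxes) is not
  modelled; the schedule is applied as a perfect step in inhaled
  concentration.
- The intersubject scaling hooks are deliberately simple defaults;
  population work should supply hooks fitted to its own cohort data.
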