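# hifcycle

Evolutionary fitness of HIF-α regulation strategies under cycling hypoxia.

Tumor microenvironments flicker between oxygenated and oxygen-depleted
states on timescales from minutes to hours. Cancer cells answer with the
hypoxia-inducible transcription factor HIF-α, and they face a classic
inducible-versus-constitutive dilemma from optimal defense theory: keep the
stress response switched on at a fixed level (*constitutive* expression —
pseudohypoxia, the regulatory face of the Warburg effect), or induce and
degrade it as oxygen comes and goes (*facultative* expression). `hifcycle`
is a small modeling toolkit, aimed at mathematical oncologists and
evolutionary biologists, for asking when each answer wins.

## The model

A cell's fitness is its net proliferation rate (payoff, min⁻¹) as a
function of its normalized HIF-α level *u* ∈ [0, 1]:

- normoxia (*Y* = 1): G_N(u) = r − c·u
- hypoxia (*Y* = 0): G_H(u) = r − c·u − m/(k + b·u)

with baseline proliferation rate *r*, expression cost *c*, hypoxic death
rate *m*, intrinsic tolerance *k*, and protection benefit *b*. Averaged over
an environment that is normoxic a fraction *q* of the time,
G(u; q) = r − c·u − (1−q)·m/(k + b·u).

Three strategies are compared:

- **perfect** — instantaneous, cost-free tracking:
  G = r − (1−q)(c + m/(k+b));
- **constitutive** — fixed *u*, with closed-form optimum
  u\* = √(m(1−q)/(b·c)) − k/b, clamped to [0, 1]. The cost is calibrated as
  c = m·b/(k+b)² so that a permanently hypoxic environment selects u\* = 1;
- **facultative** — *u*(t) relaxes exponentially toward u_max in hypoxia
  (rate α0) and toward u_min in normoxia (rate α1):
  du/dt = α0(u_max − u) if Y=0, −α1(u − u_min) if Y=1.

Over a periodic schedule (T_N minutes normoxia, T_H hypoxia) the dynamics
settle on a periodic orbit and the cycle-averaged payoff has an exact closed
form, which a multi-start COBYLA search maximizes over
0 ≤ u_min ≤ u_max ≤ 1. In stochastic (telegraph-style) environments the
payoff is averaged along simulated traces over a grid of (u_min, u_max)
candidates, with replicate traces giving a mean and standard error. The
fitness edge of induction is the selection coefficient
SC = (G_F − G_C)/G_C. Relaxation rates themselves can be estimated from
stabilization/destabilization experiments via threshold rules
(α0 = −ln(1−f)/t_rise, α1 = −ln f/t_decay) or least-squares fits of full
time courses.

## Worked example

```python
import hifcycle as h

params = h.ModelParameters()           # r=0.00048, c=0.0001328, m=0.00083, k=1, b=4
print(h.optimal_constitutive_u(0.5, params))

for half_period in (10, 120):
    schedule = h.PeriodicSchedule(half_period, half_period)
    best = h.optimize_fixed(schedule, params)
    g_const = h.optimal_constitutive_payoff(schedule.q, params)
    sc = h.selection_coefficient(best.payoff, g_const)
    print(half_period, round(best.u_min_star, 3), round(best.u_max_star, 3),
          f"{best.payoff:.6g}", f"SC={sc:.4f}")
```

prints

```
0.6338834764831844
10 0.54 1.0 0.000278553 SC=0.0004
120 0.305 1.0 0.000289555 SC=0.0399
```

Read: with equal time in each state the best fixed HIF-α level is
u\* ≈ 0.634. A facultative cell cycling every 10 minutes cannot track the
environment (α0 ≈ 0.012 min⁻¹ is slow), so its optimal baseline stays high
(u\*_min = 0.540) and its advantage over the constitutive strategy is
negligible (SC ≈ 0.0004). With 120-minute intervals the response has time to
swing, the optimal baseline drops to 0.305, and induction earns a ~4%
fitness edge — slower cycling selects for facultative regulation,
faster cycling for constitutive HIF-α stabilization.

The same computations are available from the shell:

```
hifcycle constitutive-scan --outdir out/scan
hifcycle fixed-interval    --outdir out/fixed
hifcycle stochastic        --outdir out/stoch --seed 1
hifcycle kinetics          --outdir out/kinetics
hifcycle surface           --outdir out/surface
```

Each command writes CSV tables plus a `run.json` sidecar with the fully
resolved configuration and seeds, so stochastic runs replay exactly.

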