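# pulsereduce

Nonlinear one-dimensional (1D) simulation of arterial pulse waves on
branched elastic vessel networks, together with a model-order-reduction
method that lumps peripheral 1D branches into equivalent windkessel (0D)
models while preserving the network's net resistance and total
compliance.

**Who it is for.** Researchers in computational hemodynamics who want to
know how many arterial segments a distributed 1D model actually needs to
reproduce central and peripheral pressure/flow waveforms — and hence how
many input parameters must be estimated for patient-specific modelling —
and anyone needing a compact, well-tested 1D pulse-wave solver with
three-element windkessel outlets.

## The model

Each vessel is a tapered elastic tube governed by the 1D mass and
momentum balances

```
A_t + (AU)_x = 0,      U_t + U U_x = −P_x/ρ + f/(ρA),
f = −2(ξ+2)πμU,
```

closed by the tube law `P = P_d + (β/A_d)(√A − √A_d)` with pulse wave
velocity `c = √(β/2ρA_d)·A^{1/4}`. The inflow is a prescribed periodic
flow at the aortic root (reflective flow source); junctions conserve
mass and total pressure `P + ρU²/2`; every terminal vessel ends in an
R1–C–R2 windkessel with `R1` equal to the outlet characteristic
impedance `Z₀ = ρc/A_d`.

The reduction collapses a terminal vessel plus its windkessel into a
two-element windkessel

```
R_new = R2 + R1 + R_v,
C_new = (C_v R2 + C_v R1 + C R2 + R_v C_v)/(R2 + R1 + R_v),
R_v = 2(ξ+2)πμ ∫ A_d⁻² dx,   C_v = (1/ρ) ∫ A_d/c_d² dx,
```

then merges sibling lumps in parallel into a new three-element
windkessel on their parent (`R1 = Z₀` of the parent to minimise
reflections, compliances add). Applied leaf-to-root this trims whole
generations of bifurcations — or the entire tree, recovering Frank's
classical two-element windkessel of the systemic circulation. The
approximation is valid when vessel transit times are small against the
cardiac period; `reduction_validity` quantifies this per branch. See
`docs/methods.md` for the full account.

## Worked example

Trim a representative tree of the 55 larger systemic arteries,
generation by generation, down to the aorta plus its first-generation
branches (`examples/03_trim_generations.py`):

```
 segments  terminals  parameters  net R (Pa s/m^3)  total C (m^3/Pa)
       55         28         227      1.400000e+08      1.000000e-08
       53         27         219      1.400000e+08      1.000000e-08
       45         23         187      1.400000e+08      1.000000e-08
       33         17         139      1.400000e+08      1.000000e-08
       21         11          91      1.400000e+08      1.000000e-08
```

Each row is one generation-trimming step: the 227-parameter model shrinks
to 91 parameters while the net resistance and total effective compliance
— the quantities the reduction is built to preserve — are unchanged to
machine precision. Simulating the 55- and 21-segment models and
comparing waveforms (`examples/05_reduction_study.py` shows the
machinery on a smaller tree) gives average aortic-root pressure errors
of ≈ 1.2% on this representative tree.

A single heartbeat in one vessel (`examples/01_single_vessel_pulse.py`):

```
converged after 10 cycles (residual 3.9e-04)
inlet pressure: systolic 109.0 mmHg, diastolic 51.0 mmHg, mean 73.4 mmHg
net resistance 1.400e+08 Pa s/m^3 x mean inflow 70.0 mL/s = 73.5 mmHg expected mean
```

The mean pressure equals net resistance × mean inflow (the periodic-state
identity); the pulse around it comes from wave propagation and the
outlet reflection.

The other scripts in `examples/` cover lumping a single terminal branch
(with the K1/K2/K3 profile integrals printed), Frank's whole-system
windkessel and its diastolic time constant, and a complete
reduce-and-compare study. A thin CLI mirrors the library:
`pulsereduce fixtures | simulate | reduce | wk | compare | run`.

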