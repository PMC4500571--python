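# bswitch

Analysis toolkit for the gene regulatory network that commits human
lymphoid-primed multipotent progenitors (LMPPs) to the B-lymphoid lineage.

Early B-cell development is controlled by two cytokine receptors (FLT3,
IL-7R) and seven transcription factors (PU.1, IKAROS, GFI1, E2A, EBF1, PAX5,
ZNF521).  The committed pro-B state (high EBF1/PAX5, surface CD19) and the
multipotent state (high FLT3/ZNF521) behave like two attractors of a
bistable switch: once EBF1 activity crosses a threshold, commitment is
essentially one-way.  `bswitch` implements a 10-species ODE model of this
network, in which each factor `x_i` follows saturating heterodimeric
kinetics

```
dx_i/dt = N_i(x) / D_i(x) - mu_i * x_i
```

with `N_i` a basal rate plus pairwise activation products, `D_i = 1 + N_i`
terms plus repression products, and two dimensionless environmental inputs
`T_EBF1` and `T_ZNF521` that promote transcription of EBF1 and ZNF521.  The
central element is a putative direct repression of *ZNF521* by PAX5
(strength `b4`): it closes a double-negative loop
EBF1 → PAX5 ⊣ ZNF521 ⊣ EBF1 that turns the network into an *irreversible*
bistable switch — the lower saddle-node (limit point) of the
EBF1-activation diagram sits at negative, physically inaccessible, `T_EBF1`.

The package provides, behind one uniform model interface (the full network,
seven core feedback sub-modules, and the alternative hypotheses in which the
ZNF521 repression runs through E2A or IKAROS instead of PAX5):

- stiff time integration, multi-start equilibrium search, linear stability,
  and 2-D nullclines (`bswitch.dynamics`);
- pseudo-arclength continuation with fold detection/refinement, bifurcation
  diagrams, and monostable / reversible / irreversible switch
  classification (`bswitch.continuation`);
- one-at-a-time bistability sensitivity sweeps and a seeded
  genetic-algorithm search for bistable parameter sets
  (`bswitch.bistability`);
- the hypothesis screen, the feedback-module ladder, and in-silico
  reprogramming of committed cells by scheduled `T_ZNF521` / `T_EBF1`
  modulation (`bswitch.screening`);
- attractor-versus-expression concordance and a generic fold-change /
  p-value differential filter (`bswitch.expression`), with synthetic
  two-condition fixtures (`bswitch.synthetic`).

The packaged nominal parameter set (`src/bswitch/data/nominal_params.txt`)
was calibrated with the package's own search machinery to reproduce the
qualitative two-attractor expression program and the irreversible switch;
see `docs/methods.md` for what that calibration does and does not pin down.

## Worked example

```python
import numpy as np
import bswitch as bw

params = bw.nominal_parameters()

# the two attractors at rest (no environmental activation)
eqs = bw.find_equilibria("full_A", params, (0.0, 0.0), n_starts=150, seed=0)
attractors = bw.label_attractors("full_A", eqs)
for name, state in attractors.items():
    levels = dict(zip(bw.get_model("full_A").states, np.round(state, 3)))
    print(f"{name}: FLT3={levels['FLT3']} ZNF521={levels['ZNF521']} "
          f"EBF1={levels['EBF1']} PAX5={levels['PAX5']} CD19={levels['CD19']}")

# the commitment switch: continuation in T_EBF1
diagram = bw.build_diagram("full_A", params, (0.0, 0.0), "T_EBF1",
                           (-1.5, 3.0), seed=0)
print("switch class:", diagram.switch_class)
print("bistable T_EBF1 interval:",
      [tuple(round(v, 3) for v in iv) for iv in diagram.bistable_intervals])
print("limit points at T_EBF1 =",
      sorted(round(f.param, 3) for f in diagram.visible_folds))
```

prints

```
proB: FLT3=0.17 ZNF521=0.004 EBF1=0.868 PAX5=0.675 CD19=0.415
LMPP: FLT3=0.54 ZNF521=0.825 EBF1=0.036 PAX5=0.069 CD19=0.083
switch class: irreversible_bistable
bistable T_EBF1 interval: [(0.0, 0.625)]
limit points at T_EBF1 = [-0.733, 0.625]
```

Reading: the multipotent attractor (LMPP) keeps FLT3/ZNF521 high and
EBF1/PAX5/CD19 low; the committed attractor (proB) is the mirror image.
Both coexist for `T_EBF1` between 0 and 0.625.  Raising `T_EBF1` past the
right limit point commits the cell; the left limit point at −0.733 is
inaccessible (the activation level cannot be negative), so lowering
`T_EBF1` alone can never undo commitment — the switch is irreversible.
Raising `T_ZNF521` to 0.12 moves the left fold to positive `T_EBF1`
(`bw.reversibility_map`), which is the model's reprogramming lever.

A CLI mirrors the library (`bswitch diagram`, `equilibria`, `sweep`,
`search`, `screen`, `ladder`, `reprogram`, `compare`, `fixtures`,
`validate`); each subcommand writes TSV artifacts plus a `manifest.json`
that makes the run exactly repeatable.

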