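# retrodyn

Stochastic and deterministic predator–prey models of retrotransposon
dynamics under competition for cellular resources.

Roughly half of the human genome consists of mobile genetic elements.
Autonomous retrotransposons (LINE-1, "L1") encode the protein machinery —
an endonuclease/reverse-transcriptase complex, `R_L` — that copies them
into new genomic locations; non-autonomous elements (Alu, SVA) hijack that
same machinery.  Because both element types consume a shared resource, the
copy numbers of active L1 (`L`) and active Alu (`S`) behave like prey and
predator: `retrodyn` simulates that interaction per cell and across cell
populations, and analyzes how it collapses as the cell's ribosomes and
energy budget become limiting — conditions plausibly reached in stressed
or malignant cells.

The package is aimed at systems-biology modelers: the library API is the
primary interface (see `examples/`), with a thin `retrodyn` CLI for
reproducible batch runs.

## The model

A cell is a continuous-time Markov jump process on integers `(L, S, R_L)`
with six reaction channels (rates per cell generation, volume `V`):

| reaction              | rate            |
|-----------------------|-----------------|
| ∅ → R_L (translation) | `V·v_R(L/V)`    |
| R_L → L (insertion)   | `b_L·R_L`       |
| R_L + S → 2S          | `(b_S/V)·R_L·S` |
| R_L → ∅               | `d_R·R_L`       |
| L → ∅ (silencing)     | `d_L·L`         |
| S → ∅ (silencing)     | `d_S·S`         |

The mean-field concentrations `L̄, S̄, R̄` obey the matching ODEs.  Four
modifications of the production law `v_R` encode resource competition:

- **basic**: `v_R(ℓ) = b_R·ℓ` (mass action);
- **ribosome**: `v_R(ℓ) = v_max·ℓ/(k_r + ℓ)` — a quasi-steady-state
  reduction of L1 mRNAs competing with all other mRNAs for free ribosomes;
  `k_r` is the competition strength;
- **energy**: `b_R, b_L, b_S` scaled by Michaelis–Menten factors
  `e/(k_tr+e)` and `e/(k_int+e)` in the available energy `e`;
- **mixed**: both; plus a **two_predator** variant adding a second
  non-autonomous element `S2` with its own insertion constant `b_S2`.

Reference constants: `b_R=2, b_L=b_S=1, d_R=2, d_L=d_S=0.5, V=500`,
`v_max=300`, `k_r=149` ("normal" competition), `k_tr=0.2, k_int=3.2`.

Key analysis results the package computes from these ingredients:

- stationary branches with closed-form seeds, eigenvalues and stability;
  bifurcations of the ribosome model at `k_r = 199` (Alu stops) and
  `k_r = 200` (L1 stops); energy threshold at the positive root of
  `e² − 7e − 1.28 = 0` (≈ 7.178);
- noise-induced quasi-cycles whose period is `2π/|Im λ|` of the leading
  complex eigenvalue pair (≈ 27 generations at reference parameters);
- population statistics over ensembles of independent Gillespie cells:
  Kaplan–Meier survival of each element type, the split into pools
  (1: both active, 2: Alu extinct, 3: all replication stopped),
  time-averaged copy-number distributions, coefficients of variation,
  and sliding-frame oscillation amplitudes/periods.

## Worked example

```python
import numpy as np
import retrodyn as rd

params = rd.default_parameters("ribosome")           # v_max=300, k_r=149

# deterministic backbone: stationary states and their stability
for pt in rd.find_stationary_points(params):
    print(pt.branch, pt.state, pt.stable, pt.period)
# trivial      [0. 0. 0.]      False  None
# alu_free     [51.  0.  25.5] False  None
# coexistence  [1.  1.  0.5]   True   26.995462884927242

# where does Alu replication stop?
scan = rd.scan_parameter(params, "k_r", np.linspace(100, 210, 23))
print([(b.branch, round(b.value, 3)) for b in scan.bifurcations])
# [('coexistence', 199.0), ('alu_free', 200.0)]

# one stochastic cell: sustained quasi-cycles around 500 L1 copies
traj = rd.simulate_cell(params, [250, 250, 100], 700, seed=1)
L = traj.species("L")[100:]
print(round(L.mean(), 1), round(L.std(), 1))
# 501.6 66.7
```

The coexistence state `(L̄, S̄, R̄) = (1, 1, 0.5)` corresponds to 500 L1,
500 Alu and 250 machinery copies at `V = 500`; its complex eigenvalue
pair predicts the ≈27-generation predator–prey cycle that the stochastic
trajectory keeps exhibiting (standard deviation ≈ 70 copies) while the
ODE solution damps to a constant.  The scripts in `examples/` walk
through each capability (single-cell quasi-cycles, bifurcation scans,
population pools and survival, energy competition, two-predator
exclusion) and print interpreted output.

The CLI mirrors the library:

```sh
retrodyn scan --variant ribosome --out runs/scan
retrodyn simulate-population --variant ribosome --seed 1 --n-cells 300 --out runs/pop
retrodyn demo ribosome-kr-scan --out runs/demo
```

Every run directory contains the resolved config, seeds and a manifest,
and regenerates byte-identically from the same config and seed.

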