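# opmarray

Simulation framework for designing wearable (on-scalp) MEG sensor arrays.

Optically pumped magnetometers (OPMs) can be worn within millimetres of the
scalp, which raises a concrete engineering question: **how many sensors — at
what spacing — does a given neuroscience application actually need?** The
answer depends on source depth, signal-to-noise ratio, sensor calibration
(gain) errors, and on how much high-spatial-frequency field structure a
sparse array aliases into noise. `opmarray` provides the full simulation
chain to study these trade-offs on a controlled synthetic head:

1. **Geometry** — a spherical scalp and a folded cortical surface (~3 mm
   vertex spacing) with atlas-like parcels and depth-ranked source sets;
2. **Forward model** — exact closed-form fields of current dipoles in a
   spherical conductor (Sarvas), point magnetometers, lead-field matrices
   in fT/nAm;
3. **Array design** — point packing of sensors on the scalp at a target
   inter-sensor spacing, with on-scalp (6.5 mm) or cryogenic-helmet
   (20 mm) standoff;
4. **Simulation** — 10 Hz dipole epochs with 100 fT sensor noise and
   per-channel gain errors;
5. **Inversion** — empirical Bayesian beamformer with ReML hyperparameters
   and a variational free energy F (log model evidence);
6. **Discrimination** — the void-radius sweep: the smallest exclusion
   radius around the true source at which the competing model is 20 times
   less likely (ΔF ≤ −3) is the array's *spatial discrimination*;
7. **Aliasing** — nearest-neighbour reconstruction of a dense (~700
   sensor) lead field from a channel subset; variance explained (VE),
   worst-case aliased variance 1−VE, and the implied effective SNR
   10·log₁₀(VE/(1−VE)), with greedy subset optimisation.

## Worked example

Discrimination of one superficial source (100 nAm, ~30 mm array):

```bash
python examples/04_discrimination_sweep.py
```

```
81 channels at 30 mm spacing, 100 nAm source
  void    3 mm: dF =  -2796.9 <-- crosses -3
  void    4 mm: dF =  -2867.3
  ...
spatial discrimination: 3 mm
```

Excluding even the nearest ring of candidate sources (3 mm) already makes
the competing model overwhelmingly less likely than the base model at this
SNR, so this array discriminates the source at the sweep floor. At
moderate SNR the trade-offs appear; `examples/06_experiment_bundle.py`
aggregates them:

```
 offset  spacing  amplitude  mean_discrimination_mm
    6.5     30.0       10.0                6.166667
    6.5     30.0      100.0                3.000000
    6.5     45.0       10.0                9.333333
   20.0     30.0       10.0               10.833333
   20.0     45.0       10.0               12.666667
```

On-scalp arrays (6.5 mm standoff) discriminate better than off-scalp ones
(20 mm) at every matched condition, and coarser sampling costs
discrimination at moderate SNR — the central design trade-off. The
aliasing side (`examples/05_aliasing.py`) prints the dense-array rank
spectrum (95%/99% of lead-field variance in ~51/~96 spatial components)
and the worst-case aliased variance of an optimised 100-channel subset
with the effective SNR it implies.

Other examples: `01_build_head.py` (geometry), `02_design_array.py`
(packing: 222/81/41 channels at 20/30/45 mm spacing),
`03_snr_ladder.py` (the exact 20 dB-per-decade amplitude ladder). A thin
CLI mirrors the capabilities: `opmarray design-array --spacing 30
--offset 6.5 --seed 1`, `opmarray discriminate`, `opmarray aliasing`,
`opmarray run-experiment`.

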