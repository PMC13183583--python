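# nucleoflux

Analysis toolkit for studying how the local mechanical stability of a
protein's termini shapes its transport through the nuclear pore complex.
It covers the four quantitative layers such a study needs, each usable on
its own:

1. **Light-gated transport kinetics** — a two-compartment first-order
   exchange model for optogenetic import/export probes. During the
   recovery phase (illumination off) the nucleus-to-cytoplasm
   concentration ratio follows

   ```
   [N]/[C](t) = K_e (1 − e^{−kt}) / (1 + v K_e e^{−kt})
   ```

   with steady-state accumulation `K_e = [N]_e/[C]_e = k_I/k_E`, total
   relaxation rate `k = k_I + k_E` and nucleus-to-cytoplasm volume factor
   `v`. The package fits per-cell recovery curves, decomposes `k` into
   import/export rate constants, applies semi-automatic QC filtering, and
   computes the N- vs C-terminal split statistic
   `Split = 100 (K_e^N/K_e^C − 1)` with two-tailed Mann–Whitney
   comparisons.
2. **Live-cell image quantification** — background correction and
   mask-based normalization of TIFF stacks into `N_norm = ΣI_nuc/ΣI_cell`
   time courses (`N_norm + C_norm = 1`), the input to the kinetic fits.
3. **Force-ramp single-molecule analysis** — freely-jointed-chain
   elasticity `x(F) = ΔL_c [coth(F l_K/kT) − kT/(F l_K)]` (Kuhn length
   1.1 nm, kT = 4.11 pN·nm), change-point detection of unfolding steps on
   magnetic-tweezers ramp trajectories (1 pN/s), and conversion of step
   sizes to contour-length increments ΔL_c with per-event unfolding forces
   F_U.
4. **Structure and sequence context** — backbone hydrogen-bond counting on
   PDB structures under the 4 Å / 30° geometric criteria (e.g. the
   interstrand "mechanical clamp" that anchors terminal β-strands), and a
   transcription-factor survey comparing mean per-residue disorder of the
   NLS-to-closest-terminus region against the full sequence.

A seeded synthetic-data layer (`nucleoflux.simulate`) generates every
input with known ground truth — phased cell time courses, microscopy frame
stacks with masks, Bell-model ramp trajectories, and TF disorder datasets —
so each analysis stage can be validated end to end.

## Worked example

```python
from nucleoflux import (TransportParams, CellSimSpec, gen_cell_timecourse,
                        fit_recovery, rates_from_fit, split_percent)

truth = TransportParams.from_accumulation(K_e=1.87, k=4.94e-3, v=1.0)
tc, _ = gen_cell_timecourse(CellSimSpec(params=truth, activation_duration=0,
                                        noise_cv=0.1, seed=1))
res = fit_recovery(tc, v_policy=("fixed", 1.0))
print(round(res.params.K_e, 2), round(res.params.k_I * 1e3, 2))
```

prints `1.82 3.22`: the fitted steady-state accumulation and the import
rate constant in ks⁻¹ recovered from one noisy 45-frame recovery curve
(truth: 1.87 and 3.22 ks⁻¹). Running
`python examples/01_transport_kinetics.py` extends this to two 40-cell
cohorts and prints

```
N-term: n = 39, k_I = 3.15 +/- 0.03 ks^-1
C-term: n = 40, k_I = 2.01 +/- 0.02 ks^-1
import-rate split = 56%  (Mann-Whitney U = 1560, P = 2.1e-14)
```

i.e. the N-terminus-first construct imports ~56% faster, recovered with
its significance level from simulated cohorts. The other scripts under
`examples/` walk through image quantification, force-ramp step detection
(`examples/03` prints the FJC worked value: a 65 nm contour increment
extends 60.1 nm at 50 pN), the TF disorder survey, and hydrogen-bond
counting.

There is also a thin CLI (`nucleoflux simulate-cells|simulate-frames|
simulate-ramp|simulate-tf|quantify|fit|split|detect-steps|fjc|tf-survey|
hbonds`); run any subcommand with `--help`.

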