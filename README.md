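# cuepr

Tools for analysing multi-site Cu²⁺ binding to serum albumin by combining
crystal-structure geometry with EPR spectroscopy. Albumin binds Cu²⁺ at a
high-affinity N-terminal ATCUN motif and at several secondary sites (sites
A and B, and histidine sites around His287, His317 and His509). Whether
several of these sites are occupied *simultaneously* can be tested by
pulsed dipolar EPR: each pair of occupied sites contributes a spin–spin
distance, so the measured distance distribution is a fingerprint of the
occupancy configuration. `cuepr` implements that whole computational
chain on synthetic or experimental data:

- **`cuepr.structure`** — parse PDB/mmCIF, find Cu sites and their donor
  atoms, tabulate pairwise Cu–Cu distances (nm), count disulfides, and
  compute minimum crystallographic symmetry contacts.
- **`cuepr.occupancy`** — enumerate site-occupancy configurations and
  predict each one's distance distribution as an equal-amplitude Gaussian
  mixture (σ = 0.1 nm) over the occupied pairs; rank configurations
  against an experimental distribution by windowed histogram overlap.
- **`cuepr.cw`** — CW EPR powder spectra of axial Cu²⁺ (S = 1/2, I = 3/2,
  second-order resonance fields), superposition, double integration, and
  titration linearity (spin counting).
- **`cuepr.hyperfine`** — 3-pulse ESEEM and HYSCORE processing chains
  (exponential background division, Hamming/zero-fill/FFT magnitude,
  polynomial baseline + symmetrisation) and the blind-spot τ calculator.
- **`cuepr.ridme`** — RIDME dipolar traces: powder kernel
  (ν_dd = 52.04 MHz/(r/nm)³), simulation with stretched-exponential
  background, non-negative Tikhonov inversion with GCV-selected
  regularization, bootstrap confidence bands, field-position averaging,
  and the Tm / T1 relaxation fits (mixing time = 0.7 × T1).
- **`cuepr.synthetic`** — seeded generators for everything, including a
  six-site decoy structure whose Cu–Cu distances honour the
  experimentally anchored envelopes.

The model at the core: an occupancy configuration C (a subset of sites)
predicts P(r) = Σ_{pairs (i,j) ⊂ C} w · N(r; d_ij, σ) with equal weights
w = 1/|pairs|; a RIDME trace is V(t) = [(1−λ) + λ·(K P)(t)]·exp(−k t^d)
with the powder dipolar kernel K, and inversion recovers P by minimising
‖V_model − V‖² + α²‖L₂P‖² subject to P ≥ 0. See `docs/methods.md` for the
full account.

## Worked example

Generate the decoy structure, detect its sites, and rank occupancy
configurations against a distance distribution built from the
{ATCUN, siteB, H287} configuration:

```python
import numpy as np
from cuepr.synthetic import DecoySpec, make_decoy_structure
from cuepr.structure import detect_metal_sites, pairwise_distances
from cuepr.occupancy import (OccupancyConfig, enumerate_configs,
                             rank_configs, simulate_distribution)
from cuepr.ridme import BackgroundModel, simulate_ridme, invert_tikhonov

structure = make_decoy_structure(DecoySpec(seed=1))
sites = detect_metal_sites(structure)
table = pairwise_distances(sites)
print([s.label for s in sites])
print(round(table.get("ATCUN", "H287"), 3), "nm")

config = OccupancyConfig.of("ATCUN", "siteB", "H287")
p_true = simulate_distribution(config, table)
trace = simulate_ridme(p_true, BackgroundModel(k=0.05, d=1.5, lam=0.3),
                       noise_sigma=0.01, seed=1)
p_hat, bg, depth = invert_tikhonov(trace, alpha="gcv")
print("modulation depth", round(depth, 3))

ranked = rank_configs(enumerate_configs(table.labels, 2, 6), table, p_hat)
print(str(ranked[0].config), round(ranked[0].score, 3))
```

Output:

```
['ATCUN', 'siteB', 'siteA', 'H287', 'H317', 'H509']
3.5 nm
modulation depth 0.375
ATCUN+H287+siteB 0.754
```

The six sites come back in canonical order; the ATCUN–His287 separation
is the 3.5 nm anchor; the inversion recovers the modulation depth near
the simulated 0.3 (the slight overestimate on noisy traces is discussed
in `docs/methods.md`); and the generating configuration outranks all 56
alternatives when scored against the inverted distribution.

The same steps are available from the shell:

```bash
cuepr synth decoy --seed 1 -o decoy.pdb
cuepr sites distances decoy.pdb -o distances.tsv
cuepr occupancy simulate --table distances.tsv --config ATCUN,siteB,H287 -o pr.txt
cuepr ridme simulate --pr pr.txt --lambda 0.3 --noise 0.01 --seed 1 -o trace.txt
cuepr ridme invert trace.txt --alpha gcv -o pr_inverted.txt
cuepr occupancy rank --table distances.tsv --experimental pr_inverted.txt
```

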