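# nucstress

Mechanical analysis of nucleosomal DNA carrying a double-strand break (DSB).

In a nucleosome, 147 bp of DNA are wrapped left-handed around the histone
octamer in nearly two superhelical turns of ~8 nm diameter — far below the
~50 nm persistence length of free DNA — so the wrapped duplex stores large
bending and torsional stress. When both backbones are cut (a DSB), the broken
ends can only detach from the histone core by crossing a free-energy barrier
of adhesion, while the stored elastic stress pushes them to straighten out.
`nucstress` provides the analysis pipeline for studying this mechanics on MD
trajectories and stress fields, for structural-bioinformatics and molecular-
modelling users:

* **Tube geometry** — base pairing for the 187-bp duplex (dyad at base 94 of
  each chain, pair rule *i* ↔ 188−*i*), the neutral-axis centerline with
  local frames {**n**, **τ**, **b**} (**b** directed toward the curvature
  center), the detachment reaction coordinate ζ (distance of a broken end's
  axis center to the nearest histone atom, perpendicular to the superhelical
  axis), contact-distance and heavy-atom H-bond time series.
* **Stress projection** — for a stress field σ(**x**) on a grid (nine
  Gaussian-cube component files), the traction **T** = σ·**n**, the line
  tension *t*(**x**) = **τ**ᵀσ**τ** (compression positive on the inner half,
  tension negative on the outer half, zero on the neutral axis) and the twist
  stress *w*(**x**) = (σ·**τ**)·(**τ**×**r̂**), slice-averaged along the tube
  with an inner/outer split.
* **Essential dynamics** — least-squares superposition, displacement
  covariance **C** = ⟨δxδxᵀ⟩, eigen-decomposition, per-mode RMSF
  (√λₖ·‖vₖ‖ per atom), projections on principal planes, and RMSIP subspace
  overlap.
* **Configurational entropy** — the Schlitter upper bound
  S = ½k_B ln det[**I** + (k_B T e²/ħ²)**MC**] (e is Euler's number) and the
  excess entropy TΔS = T(⟨S_damaged⟩ − ⟨S_intact⟩).
* **Umbrella sampling / WHAM** — self-consistent weighted-histogram
  reconstruction of the potential of mean force A(ζ) from harmonically
  biased windows, barrier extraction and the Boltzmann escape probability
  p = 100·exp(−ΔA/k_BT).
* **Synthetic data** — a seeded generator for every input with analytic
  ground truth: the superhelical duplex with DSB sites M1–M4 (cuts spaced
  1 bp around a central A⋯T pair), Gaussian ensembles with planted
  covariance modes, Euler–Bernoulli bent-rod stress fields, and umbrella
  samples drawn exactly from a known PMF.

## Worked example

```python
import numpy as np
from nucstress import *

# build the synthetic nucleosome and recover its neutral axis
structure, pairs, truth = build_superhelix()
axis = compute_centerline(structure, pairs)
wrapped = (axis.pair_indices >= 28) & (axis.pair_indices <= 160)
print(f"curvature of wrapped DNA: {axis.curvature[wrapped].mean():.3f} nm^-1 "
      f"(analytic {SuperhelixSpec().curvature:.3f})")

# plant a 1.8 kcal/mol detachment barrier and re-measure it by WHAM
pot = double_well_potential(1.8, 0.0, 2.0)
truth_spec = UmbrellaTruthSpec(
    potential=pot, support=(-0.5, 2.5),
    windows=[(c, 200.0) for c in np.linspace(0.0, 2.0, 15)],
    samples_per_window=10000, temperature=310.0, seed=1)
profile = wham(sample_umbrella(truth_spec), n_bins=80)
dA, p = barrier_and_probability(profile, (0.0, 1.0))
print(f"barrier: {dA:.2f} kcal/mol -> {p:.1f}% Boltzmann escape probability")
```

prints

```
curvature of wrapped DNA: 0.239 nm^-1 (analytic 0.237)
barrier: 1.80 kcal/mol -> 5.4% Boltzmann escape probability
```

The recovered curvature matches the analytic superhelix value
R/(R² + (p/2π)²); the WHAM profile returns the planted 1.8 kcal/mol
(≈ 3 k_BT) barrier, whose Boltzmann factor at 310 K corresponds to a ~5%
probability of spontaneous detachment.

## Command line

A `nucstress` console script mirrors the library (`synth`, `centerline`,
`zeta`, `contacts`, `hbonds`, `ed`, `entropy`, `stress`, `wham`), and
`nucstress run --config run.yaml` executes the full synthetic end-to-end
demonstration (superhelix → DSB → planted ensemble → essential dynamics →
entropy → bent-rod stress profiles → umbrella windows → WHAM), writing a
provenance manifest with parameter echo and output hashes; identical config
and seed reproduce byte-identical outputs.

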