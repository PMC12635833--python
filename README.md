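# nctpipe

Network-control-theory (NCT) features from structural and functional brain
connectomes, with a synthetic cohort generator and the group statistics
needed to evaluate them.

## The problem

A parcellated brain can be modeled as a linear dynamical system

```
x'(t) = A x(t) + B u(t)
```

where `x(t)` holds the activation of the N regions, `A` is a symmetric,
zero-diagonal adjacency matrix built from connectivity data, and `B`
selects the control nodes (here: all parcels of one canonical resting-state
network, e.g. the default-mode network, DMN). Within this model two families
of features describe how efficiently a connectome supports state
transitions:

* **Minimum control energy.** After stabilizing `A` with the weighted
  Laplacian normalization `A ← −L/λ_max(L)`, the cheapest input driving the
  system from state `x0` to state `xf` over a horizon τ costs

  `E = ½ dᵀ W⁺ d`,   `d = xf − e^{Aτ} x0`,

  with `W` the controllability Gramian restricted to `B` (Lyapunov solution
  when strictly stable, finite-horizon integral otherwise). When the
  adjacency is updated over M sliding windows of dynamic functional
  connectivity, the propagators chain across windows and the Gramian
  composes per window, giving a *dynamic* energy `E_d`; the ratio of static
  to dynamic log-energy is a dynamic-efficiency feature.

* **Average and modal controllability.** After the Schur normalization
  `A ← A/(1 + λ_max(A))` (maximum *absolute* eigenvalue, so the
  discrete-time system is always stable), the eigendecomposition
  `A = V diag(λ) Vᵀ` yields per-node indices
  `AC_i = Σ_j v_ij²/(1−λ_j²)` and `MC_i = Σ_j (1−λ_j²) v_ij²`, averaged over
  a network's nodes.

Five adjacency scenarios are supported per subject: structural connectivity
(SC), static FC with and without negative correlations, and windowed
dynamic FC with and without negatives. A synthetic cohort generator
(regime-switching block-correlated BOLD, distance-decay structural
matrices, group metadata with hearing scores) makes every stage runnable
and testable without imaging data, including an injectable group difference
concentrated in one network. The statistics layer reproduces the evaluation
workflow: intra-/inter-individual coefficients of variation, OLS group
effects with age/sex (and graph-covariate) adjustment, ROC-AUC, Spearman
correlations with clinical scores, and Benjamini–Hochberg FDR across
networks.

## Worked example

```python
import numpy as np
from nctpipe import (
    CohortSpec, ControlSet, compute_sfc, compute_dfc, default_parcellation,
    dynamic_energy, laplacian_normalize, network_controllability,
    select_state_pairs, simulate_subject, static_energy,
)

scheme = default_parcellation()                      # 200 nodes, 7 networks
subject = simulate_subject(scheme, CohortSpec(seed=7), "NH",
                           np.random.default_rng(7), "sub-NH01")
dmn = ControlSet.from_network(scheme, "DMN")
pair = select_state_pairs(subject.bold, 1, np.random.default_rng(11))[0]

sfc = compute_sfc(subject.bold)
e_static = static_energy(laplacian_normalize(sfc), dmn, pair, tau=30.0,
                         scenario="sFC")
dfc = compute_dfc(subject.bold, window_seconds=50.0, tr_seconds=2.0)
e_dynamic = dynamic_energy(dfc, dmn, pair, tau=30.0)

print(f"static FC log-energy  (tau=30): {e_static.log_energy:.3f}")
print(f"dynamic FC log-energy (tau=30): {e_dynamic.log_energy:.3f}")
print(f"Gramian effective rank: {e_static.effective_rank} of {scheme.n_nodes}")

prof = network_controllability(sfc, dmn)
print(f"DMN average controllability: {prof.network_ac:.4f}")
print(f"DMN modal controllability:   {prof.network_mc:.4f}")
```

Output:

```
static FC log-energy  (tau=30): 23.698
dynamic FC log-energy (tau=30): 24.193
Gramian effective rank: 102 of 200
DMN average controllability: 1.1466
DMN modal controllability:   0.9930
```

The two log-energies quantify the cost of steering the DMN between two
resting states under a time-invariant vs a windowed adjacency; the
effective rank records how much of the state space is numerically
controllable from the DMN over this horizon (the pseudo-inverse restricts
the energy to that subspace). `AC ≥ 1` and `MC ≤ 1` always hold for stable
symmetric systems; values near 1 indicate a weakly coupled network.

## Command line

The same pipeline is scriptable through a YAML config:

```bash
nctpipe simulate --config config.yaml   # write a synthetic cohort
nctpipe intra    --config config.yaml   # energy CoV across 20 state pairs
nctpipe inter    --config config.yaml   # features + group statistics
nctpipe report   --config config.yaml   # summarize stats_report.tsv
```

Outputs are tab-separated tables (`energy_features.tsv`, `features.tsv`,
`stats_report.tsv`) plus a JSON summary and a run log carrying the seed and
config hash.

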