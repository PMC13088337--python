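# etkit

A desk-scale analysis toolkit for the computational workflow used to dissect
electron-transfer (ET) optimization in multi-domain **self-sufficient
cytochrome P450s** — enzymes that fuse the heme monooxygenase domain with its
flavin (FMN) and iron–sulfur ([2Fe-2S]) redox partner domains in one
polypeptide.  Catalysis in these chimeras is gated by (i) a distal→proximal
rotation of the ferredoxin domain that shortens the [2Fe-2S]-to-heme distance
d[FeS–Heme], (ii) the electron-tunneling pathway from the cluster to the heme
iron, and (iii) the positioning of the substrate over the reactive
Fe(IV)═O species (Compound I).  The toolkit implements the quantitative
machinery for all three axes, plus the assay statistics that connect them to
catalytic performance.  It is aimed at enzyme engineers and simulators who
want these analyses as small, tested, composable functions rather than as
steps buried in MD-suite pipelines.

## What it computes

**Tunneling pathways and ET rates** (`etkit.pathways`).  The empirical
pathways model assigns each step between heavy atoms a coupling decay —
ε = 0.6 for a covalent step, 0.36·e^(−1.7(d−2.8)) across a hydrogen bond,
0.6·e^(−1.7(d−1.4)) for a through-space jump — and the best donor→acceptor
route maximizes the product of decays (a Dijkstra search on −ln ε weights
with deterministic tie-breaking).  The summed route length R feeds the
distance-decay rate law

    k_ET = A₀ · e^(−β·R),   A₀ = 2×10¹² s⁻¹,  β = 1.06 Å⁻¹.

**Umbrella-sampling free energies** (`etkit.pmf`).  Biased windows are
reweighted with the multistate Bennett acceptance ratio (MBAR): the window
free energies f_k solve

    e^(−f_k/k_BT) = Σ_n e^(−U_k(x_n)/k_BT) / Σ_j N_j e^((f_j − U_j(x_n))/k_BT),

and the unbiased per-sample weights ω_n ∝ 1/Σ_j N_j e^((f_j−U_j(x_n))/k_BT)
project the potential of mean force onto any collective variable s via
F(s) = −k_BT ln P(s) — including the first principal component of
(cos, sin)-embedded backbone dihedrals.  Barrier extraction and the
distal (>22 Å) / proximal (<20 Å) classification of d[FeS–Heme] complete the
conformational analysis.

**Ensemble observables** (`etkit.ensembles`).  Per-frame cofactor distances,
the Fe═O⋯C attack angle, near-attack-conformation (NAC) fractions within a
4 Å cutoff, hydrogen-bond occupancy, Kabsch-superposed RMSD, and group–group
Coulomb / Lennard-Jones interaction-energy distributions.

**Assay statistics** (`etkit.assays`).  Conversion
(100·M_P/(M_P+M_S)), total turnover number (product/enzyme), coupling
efficiency (100·product/NADH consumed), nonlinear Michaelis–Menten fitting,
and Pearson correlation with a two-sided t-test.

**Synthetic ground truth** (`etkit.synthetic`).  Every analysis is validated
against generators with exact truth: Metropolis samples of analytic 1-D
potentials (the double well U = a(x²−b²)² has barrier a·b⁴ in closed form),
toy tunneling graphs small enough for exhaustive route enumeration,
trajectories whose distance/angle/H-bond series equal planted draws exactly,
and a two-domain structure whose optimal tunneling route is forced by
construction.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on synthetic
inputs and write their tables under `results/`:

```bash
python analysis/01_make_synthetic_inputs.py --seed 1
python analysis/02_pathway_analysis.py --seed 1
python analysis/03_pmf_reconstruction.py --seed 1
python analysis/04_ensemble_geometry.py --seed 1
python analysis/05_assay_statistics.py --seed 1
```

The pathway driver prints:

```
best route: 29 steps, R = 46.22 Å, coupling = 1.575e-07 (planted route recovered: True)
residue trace: FES101:A -> GLY1:A -> GLY2:A -> GLY3:A -> LYS4:A -> THR5:A -> GLY6:A -> GLY7:A -> GLY8:A -> HEM201:A
k_ET(32.36 Å) = 0.00254 /s, k_ET(28.31 Å) = 0.186 /s; a 4.05 Å shortening accelerates ET 73.2-fold
```

The route search recovers the fixture's planted route — iron–sulfur cluster
to heme iron through a covalent backbone, one side-chain hydrogen bond and
one through-space hop — and evaluating the rate law at the two reference
pathway lengths (32.36 Å vs 28.31 Å) quantifies what a 4.05 Å shortening is
worth: nearly two orders of magnitude in ET rate.  The PMF driver
reconstructs the analytic 1.5 kcal/mol double-well barrier from 46 biased
windows (`barrier on raw RC: 1.54 kcal/mol`, analytic 1.50); the ensemble
driver recovers planted NAC fractions (28 % vs 39 % at the 4 Å cutoff for
the reference and engineered distance laws) and an exactly planted 37.28 %
hydrogen-bond occupancy; the assay driver reproduces the strong TTN–coupling
correlation across the four-enzyme panel (`r = 0.97, two-sided p = 0.026`).

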