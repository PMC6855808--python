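# lipidmod

Quantitative analyses of how anionic phospholipids bind to and modulate a
pentameric ligand-gated ion channel (pLGIC), built for ion-channel
biophysicists working with native mass spectrometry, coarse-grained
membrane simulations, stopped-flow flux assays and patch-clamp recordings.

Anionic lipids such as POPG bind the model channel ELIC at specific
transmembrane sites, stabilize it thermally and slow its desensitization.
`lipidmod` implements the complete quantitative chain behind those
statements:

* **Native-MS binding** — from deconvoluted peak heights `I_n` of the
  n-lipid-bound pentamer, the average bound count
  `n̄ = Σ n·I_n / Σ I_n`, and a binomial equal-site model: N sites of
  affinity K, per-site occupancy `p = [A]/([A]+K)`, bound-state mole
  fractions `C(N,q) p^q (1−p)^{N−q}`. Fit K with N fixed (affinity
  comparisons across lipids) or select integer N with K fixed (site loss
  in mutants).
* **Thermal stability** — Hill fit
  `E(c) = 1 + (E_max−1)·c^n/(c^n+EC50^n)` of the stabilizing-effect
  ratio, and elimination of concentration between the binding and
  stability curves to express fractional stabilization as a function of
  bound-lipid count.
* **Boundary lipids** — classification of annular lipids (any bead
  within 6 Å of the transmembrane domain, periodic minimum image),
  the enrichment metric `B_i = ⟨(b_i/b_tot)/x_i⟩ − 1` (B>0 =
  enrichment, 0 = random mixing), and leaflet-resolved polar density
  maps of phosphate beads (4 Å radial × π/15 angular bins to 40 Å).
* **Stopped-flow flux kinetics** — stretched-exponential quench fits
  `F(t) = F_∞ + (F_0−F_∞)e^{−(t/τ)^β}`, influx rates at 2 ms
  `k = (β/τ)(t/τ)^{β−1}`, robust repeat screening, and decomposition of
  the rate-versus-agonist-delay course into activation (fast) and
  desensitization (slow) exponentials.
* **Patch-clamp kinetics** — activation and desensitization exponential
  fits with principled single/double model selection, amplitude-weighted
  time constants `(A₁τ₁+A₂τ₂)/(A₁+A₂)`, extent of desensitization at
  20 s, Hill (n = 2) dose-response fits, and the study's group statistics
  (ANOVA + Tukey HSD; reference-versus-variants t-tests with Bonferroni).
* **Synthetic data** — seeded generators for all five input classes with
  embedded ground truth, so every pipeline stage is testable end to end
  without any external download.

Fitted analyses follow a Model/Results pattern: build a model from data,
`fit()` returns a results object with estimates, standard errors and a
`summary()` table.

## Worked example

How much of the maximal thermal stabilization does a full lipid annulus
provide? Native MS measures an average of 2.9 bound POPG per pentamer at
12 µM; the stability assay gives EC50 = 52 µM with Hill n = 1.7; the
simulations put ~32 lipids in the annulus.

```python
import lipidmod as lm
from lipidmod.ms_binding import POPG

# binding curve anchored at the measured 2.9 bound at 12 uM
anchor = lm.BindingCurve(POPG, [(12.0, 2.9, 0.0, 3)])
hill = lm.HillCurve(ec50=52.0, hill_n=1.7, e_max=6.0)
coupling = lm.couple_binding_to_stability(anchor, hill, 32.0)
print(f"fractional effect at 32 bound lipids: {coupling.points[0][1]:.3f}")

# recover the dissociation constant from a synthetic titration
model = lm.BinomialBindingModel(n_sites=32, k_d=120.4)
peaksets, _ = lm.gen_peaksets(model, sigma=0.05, seed=7)
results = lm.BinomialSiteModel(peaksets).fit(mode="fit_K", n_sites=32)
print(results.summary())
```

prints

```
fractional effect at 32 bound lipids: 0.830
Binomial equal-site binding fit
===============================
parameter             estimate       std err
n_sites                     32            --
k_d                    121.324       0.43357
n obs: 71    rmse: 0.0043615
mode: fit_K    objective (SSR): 0.0013506
```

Reading: extrapolating the binding curve linearly through the origin and
the 12 µM anchor puts 32 bound lipids at ≈132 µM, where the Hill curve
sits at 83% of its maximal stabilizing effect — filling the annulus
captures most but not all of the protection. The titration fit recovers
the generating K = 120.4 µM to within 1% from 5%-noisy peak intensities.

The same analyses are scriptable from the shell:

```bash
lipidmod --seed 7 --out-dir run simulate --kind peaks
lipidmod --out-dir run ms-fit --input run/peaks.csv --mode fit_K --n-sites 32
lipidmod --out-dir run boundary --frames 'run/frame_*.gro' --species POPG
```

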