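# cosmokin

Single-molecule colocalization analysis of kinetochore assembly kinetics.

## The problem

The budding-yeast kinetochore assembles on centromeric DNA from distinct
protein subcomplexes, and the *order* in which they arrive can be measured
directly with a single-molecule reconstitution assay: fluorescent centromeric
DNA molecules (CEN DNA, Atto-647 labeled) are tethered sparsely on a
coverslip, incubated with cell extract containing a GFP-tagged kinetochore
protein for a chosen time, washed, and imaged by two-channel TIRF microscopy.
Colocalization single-molecule spectroscopy (CoSMoS) then scores, for each
DNA spot in the 647-nm channel, whether a GFP spot sits on top of it in the
488-nm channel.  Repeating over a schedule of incubation times (0, 5, 10, 30,
60, 90, 120, 150, 180 min) with ≥3000 DNAs pooled per timepoint and three
biological replicates yields a colocalization-vs-time curve per protein.

`cosmokin` implements the full analysis for this assay, plus a synthetic-data
generator with known ground truth so every stage is testable end to end:

* **synthetic** — two-channel field images (Gaussian-PSF spots, constant
  background, Gaussian camera noise), binomial count series drawn from a
  chosen kinetic curve, zero-binding mutant-centromere controls, and
  photobleach traces.
* **imaging** — spot detection (difference-of-Gaussians band-pass, robust
  MAD thresholding, Gaussian-masked subpixel centroids) and one-to-one
  nearest-pair colocalization within a 1.5 px radius, pooled into per-replicate
  time series.
* **photobleach** — exact penalized changepoint counting of bleaching steps;
  a predominance of single downward steps verifies that DNA foci are single
  molecules.
* **kinetics** — the core model fitting (below).
* **workflow / CLI** — a reproducible `simulate → detect → colocalize → fit →
  compare → report` pipeline driven by one TOML config (`cosmokin run`).

## The kinetic model

A protein reaching the kinetochore through *n* sequential irreversible
transitions, all with the same rate constant *k* (min⁻¹), accumulates as

&nbsp;&nbsp;&nbsp;&nbsp;*f*(*t*) = *C*ₘₐₓ · *P*(*n*, *kt*),&nbsp;&nbsp; *n* ∈ {1, 2, 3, 4},

where *P* is the regularized lower incomplete gamma function (the Erlang
CDF); for example *f*(*t*) = *C*ₘₐₓ(1 − e^(−kt)) for one step and
*C*ₘₐₓ(1 − (1 + kt)e^(−kt)) for two.  More steps give a longer lag followed
by a steeper rise.  Each dataset is fit with all four forms by minimizing

&nbsp;&nbsp;&nbsp;&nbsp;χ² = Σₜ ((f̄ₒᵦₛ(t) − f(t)) / σₜ)²

with exactly two free parameters (*k*, *C*ₘₐₓ) and σₜ the replicate SD
floored by the pooled binomial SE; the minimum-χ² form wins.  Curves are
compared by **T30**, the time at which the fitted curve crosses 30%
colocalization, reported as "> t_max" when the plateau never gets there, and
by **Cmax**, the fitted plateau.  Uncertainties come from a parametric
(binomial) bootstrap.

## Worked example

Simulate a fast-assembling protein (one step, T30 = 4 min, Cmax = 0.87) and
a slow one (two steps, T30 = 70 min, Cmax = 0.47) at the assay's design size
(3000 DNAs × 3 replicates), then fit and compare:

```python
import cosmokin as ck

fits = []
for label, truth in [("fast", ck.KineticTruth(1, 0.1057, 0.87)),
                     ("slow", ck.KineticTruth(2, 0.0327, 0.47))]:
    cfg = ck.SimConfig(seed=1, n_dna_per_field=200, n_fields_per_timepoint=15,
                       kinetic_truth=truth)
    series, _ = ck.simulate_series(cfg)
    series.protein_label = label
    fit = ck.select_model(series)
    ck.estimate_uncertainties(series, fit, n_boot=200, seed=1)
    fits.append(fit)
    print(f"{label}: n={fit.n_steps} k={fit.k:.4f}/min "
          f"Cmax={fit.c_max:.3f}±{fit.se_cmax:.3f} T30={fit.t30.render()}")

print(ck.compare_curves(fits)[["protein_label", "n_steps", "c_max", "t30"]])
```

Output:

```
fast: n=1 k=0.1062/min Cmax=0.869±0.002 T30=3.989 min
slow: n=2 k=0.0323/min Cmax=0.467±0.004 T30=67.74 min
  protein_label  n_steps     c_max        t30
0          fast        1  0.868526  3.989 min
1          slow        2  0.466630  67.74 min
```

The fitted step counts, rate constants, plateaus and crossing times match
the generating truths within the binomial counting noise of 9000 DNAs per
timepoint; the comparison table orders the fast assembler first, i.e. it
joins the kinetochore earlier.  A protein whose plateau stays below 30%
would appear last with `T30 = "> 180 min"`.

The same analysis runs from the shell: `cosmokin run --config run.toml`
writes series CSVs, fit JSONs (all four candidate fits plus the selection),
a comparison table, plots, and a manifest with content hashes so reruns are
verifiably identical.

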