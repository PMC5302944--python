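# radioqc

Radiobiological quality control for clinical ion beams.

Particle-therapy centres need routine biological benchmarks of their beams, not
just physical dosimetry. `radioqc` implements the quantitative read-outs of
such a benchmark for photon, proton, helium-, carbon- and oxygen-ion
irradiation of a tumour cell line at the mid spread-out Bragg peak:

* **Clonogenic survival and RBE.** Surviving fractions follow the
  linear-quadratic model, SF(D) = exp(−αD − βD²), for the photon reference and
  a purely linear model (β = 0) for the ions over the clinical dose range,
  with a nested F-test deciding between the two. The relative biological
  effectiveness at an isosurvival level S is RBE = D_ref(S)/D_test(S), with
  first-order (delta-method) uncertainty from the full parameter covariances.
* **Intranuclear hit statistics.** A nucleus of cross-sectional area A under
  fluence Φ receives Poisson-distributed traversals with mean λ = Φ·A·10⁻⁸
  (A in µm², Φ in cm⁻²); over a measured area sample the hit count is an
  equal-weight Poisson mixture with mean Φ·E[A] and variance
  Φ·E[A] + Φ²·Var(A).
* **FNTD track read-out.** Track spots on a fluorescent nuclear track
  detector plane are detected on the top-hat filtered image, peak photon
  counts are converted to APD count rates (counts/µs = MHz), and a count-rate
  threshold (5.3 MHz for carbon, 4.4 MHz for oxygen beams) separates primary
  ions from lighter fragments.
* **γ-H2AX focus analysis.** Nuclei are segmented from the nuclear stain
  (rolling ball → maximum projection → median filter → Otsu → watershed);
  DNA-damage foci are counted and sized per nucleus, background-corrected
  (~0.16 foci/nucleus), followed over time to estimate repair kinetics and
  residual (non-repaired) fractions, and correlated with survival.
* **Track–focus registration.** The detector plane and the cell layer are
  registered by a single rigid translation (the nuclei move a few µm between
  irradiation and imaging) and primary tracks are paired one-to-one with
  damage foci.

Every stage can be exercised on synthetic data with known ground truth
(`radioqc.synthetic`), so the whole pipeline is testable without any
microscope.

## Worked example

```python
from radioqc import BeamQuality, HitModel, fit_lq, fit_linear, rbe_at_survival
from radioqc import synthetic, survival

# simulate a photon survival assay (triplicate wells, Poisson colony noise)
data = synthetic.generate_survival_table(
    alpha=0.173, beta=0.032, doses=[1, 2, 4, 6, 8], seed=1,
    quality=BeamQuality("photon"))
photon = fit_lq(data)
print(photon.summary())

ion = fit_linear(synthetic.generate_survival_table(0.809, 0.0, [0.5, 1, 2, 4], seed=2))
r = rbe_at_survival(photon, ion, level=0.30)
print(f"RBE30(carbon) = {r.rbe:.2f} +/- {r.rbe_se:.2f}")

areas = synthetic.generate_nuclear_areas(1239, seed=0)   # ~90 um^2 mean
dist = HitModel(areas, fluence=3.8e6).distribution()
print(f"mean intranuclear hits: {dist.mean:.2f} +/- {dist.sem(1239):.2f}")
```

prints

```
Survival curve fit
==============================================
quality:       photon    model: LQ
nobs:              18    df_resid: 15
RSS (weighted log scale): 0.0397238
----------------------------------------------
alpha      0.1861  +/- 0.0163  Gy^-1
beta       0.0295  +/- 0.0020  Gy^-2
==============================================
RBE30(carbon) = 2.71 +/- 0.07
mean intranuclear hits: 3.36 +/- 0.06
```

The fitted α and β recover the generating parameters within their standard
errors; the RBE of 2.7 says the carbon beam needs 2.7× less dose than photons
for 30% clonogenic survival; the hit mean is Φ·E[A] for the simulated
nuclear-area sample.

## Command line

```sh
radioqc --outdir out --seed 7 simulate      # synthetic scenario + ground truth
radioqc --outdir out fit-survival           # LQ / linear fits per beam
radioqc --outdir out rbe                    # RBE at 30% survival vs photons
radioqc --outdir out hits fntd foci         # hit model, spot + focus read-out
radioqc --outdir out correlate report       # registration, summary table
```

Each stage writes CSV/YAML artifacts plus a JSON manifest; re-running with
the same seed reproduces every file byte-identically. Configuration is a
validated YAML file (`--config`); unknown keys are rejected. The full default
pipeline takes well under a minute on one CPU.

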