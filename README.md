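# rodeca

Robust unsupervised hyperspectral unmixing of weak cellular
autofluorescence.

Label-free fluorescence microscopy records the native emission of
compounds such as NADH, FAD, porphyrins and lipofuscin across many
excitation/emission channels. Each pixel's spectrum is a mixture of a
few pure-fluorophore spectra, and separating them ("unmixing") reveals
per-pixel biochemistry — e.g. the NADH/FAD redox ratio — without any
staining. The catch: autofluorescence is weak (real recordings sit near
5 dB SNR), the spectra overlap heavily, and no pixel is biochemically
pure, which defeats the classic pure-pixel endmember extractors.

This package implements the full analysis chain for that regime:

* **Linear mixing model.** Observations `y = M s + n` with `y` the
  L x N matrix of pixel spectra (L channels, N pixels), `M` the L x p
  endmember spectra, `s` the p x N abundance fractions (`s >= 0`,
  columns summing to 1) and `n` sensor noise. Noiseless pixels live in a
  simplex whose vertices are the endmembers.
* **Pre-processing** of raw camera counts: photon-per-second
  equalization, dark correction, despiking, background subtraction and
  flat-fielding against a calibration fluid, stationary-wavelet
  denoising (`rodeca.preprocess`).
* **HySime** signal-subspace identification: regression-based noise
  estimation plus minimum-MSE eigenvector selection, yielding the
  endmember count p and the reduced representation (`rodeca.subspace`).
* **RoDECA unmixing**: a SISAL minimum-volume simplex fit (split
  augmented Lagrangian, soft hinge on negative abundances, noise-adaptive
  hinge weight) initializes a Dirichlet-mixture generalized-EM estimate
  of `W = A^-1`; endmembers are re-normalized per channel and abundances
  are simplex-projected (`rodeca.unmix`).
* **Validation tools**: permutation matching, abundance/spectrum error
  statistics, SNR sweeps and VCA / raw-SISAL baselines
  (`rodeca.evaluate`), plus a generator for the four artificial test
  scenes (`rodeca.synth`).

The shipped channel table and fluorophore spectra are clearly-marked
synthetic stand-ins with the right qualitative shapes; see
`docs/methods.md` for the model, the parameter defaults and the design
rationale.

## Worked example

```python
from rodeca import simulate_case, unmix, UnmixConfig, evaluate_run

# case-A scene: 24 x 25 pixels, four fluorophores in disjoint stripes
# (dominant fractions 0.80-0.85), 18 channels, 20 dB white noise
cube, M_true, s_true = simulate_case("A", snr_db=20.0, seed=1)

result = unmix(cube, UnmixConfig(seed=1))
print("endmembers found:", result.subspace.p)

report = evaluate_run(
    result.endmembers.spectra, result.abundances.fractions,
    M_true.spectra, s_true.fractions,
)
print(f"abundance error xi_s = {report.xi_s:.4f}")
print(f"spectrum  error xi_M = {report.xi_M:.4f}")
print("matched truth order:", report.permutation)
```

prints

```
endmembers found: 4
abundance error xi_s = 0.0270
spectrum  error xi_M = 0.0090
matched truth order: (3, 0, 1, 2)
```

HySime recovered the true number of fluorophores (4) from the noisy cube
alone. The mean absolute abundance error of 0.027 means a typical pixel's
recovered fractions are within ~3 percentage points of truth at 10%
noise amplitude; the spectrum error of 0.009 is on normalized (max = 1)
spectra, i.e. recovered endmember spectra deviate by under 1% of their
peak per channel. The permutation reports which recovered column matches
which true fluorophore (unmixing is blind to ordering).

The same workflow is available from the shell:

```sh
rodeca run --case A --snr-db 20 --seed 1 --out runs/demo
rodeca sweep --case A --snrs 10,20,40,60 --reps 10 --seed 1 --out sweep.csv
```

`rodeca run` writes the cube (TIFF stack), true and recovered spectra
and abundances (CSV), per-fluorophore abundance maps (TIFF + PNG), the
fitted Dirichlet mixture, the objective trace and JSON manifests with
checksums; identical configuration reproduces identical checksums.

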