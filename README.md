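# handnir

Feasibility analysis of detecting rheumatoid-arthritis joint inflammation by
near-infrared (NIR) epifluorescence imaging at clinical depth.

Targeted NIR fluorescent probes accumulate in inflamed synovial tissue. For a
hand-held planar (epifluorescence) scanner to call a metacarpophalangeal (MCP)
joint inflamed, the signal from the synovium — buried a few millimetres under
the skin — must beat the variability of the background tissue signal. This
package answers the quantitative question behind that: **how many times higher
must the probe concentration in the synovium be than in the surrounding
tissue for confident detection?**

It provides:

* a **steady-state photon diffusion solver** — the diffusion approximation to
  light transport in highly scattering tissue,

  ∇·(−D∇u) + μₐu = f,  D = 1/(3(μₐ + μ′ₛ)),

  with Robin (partial-current) boundaries −n·(−D∇u) = u/(2·Cr) at every
  tissue/air face, discretized on a voxel grid with a 7-point finite-volume
  stencil and solved by conjugate gradients;
* a **two-pass epifluorescence forward model**: a planar excitation source one
  scattering length (1/μ′ₛ) below the surface drives the excitation solve;
  fluorophores re-emit with source density η·μ_fx·u_x·[C]; a second solve
  propagates the emission to the surface image;
* a **parametric hand geometry**: tissue slab with a curved, dye-filled
  synovial pocket whose crown sits at the clinical joint depth (2.3 mm);
* **detection statistics**: target-to-background ratio (TBR) from ROI masks,
  contrast-to-noise ratio CNR = (TBR − 1)/CV under proportional background
  noise (CV = 64%), the one-sided z-threshold (1.645 at 95% confidence), the
  interpolated minimum concentration ratio, and a Monte-Carlo verification of
  the detection probability;
* **non-compartmental pharmacokinetics** (trapezoidal AUC, dose-normalized
  bioavailability, Cmax/Tmax) with a Bateman-curve synthetic generator;
* **synthetic-data generators** for optical-phantom configurations
  (Intralipid/India-ink optics, 10 nM background, 50/100 nM cavity) and noisy
  background replicates.

## Worked example

```python
from handnir.io import load_config, build_from_config
from handnir.feasibility import required_ratio_analysis

cfg = load_config(overrides={"geometry": {"spacing_mm": 1.0}})
domain, props_ex, props_em, dye, _ = build_from_config(cfg)
res = required_ratio_analysis(domain, props_ex, props_em, dye,
                              ratios=range(1, 15))
print(res.table.head(3).round(3))
print(f"threshold CNR = {res.threshold:.3f}")
print(f"required ratio = {res.required_ratio:.2f}")
```

prints

```
   ratio    tbr    cnr
0    1.0  1.019  0.029
1    2.0  1.140  0.218
2    3.0  1.259  0.404
    threshold CNR = 1.645
    required ratio = 10.20
```

Reading: at a synovium:background concentration ratio of 1 the image is flat
(TBR ≈ 1, CNR ≈ 0); TBR grows linearly with the ratio; the CNR curve crosses
the 95% z-threshold at the *required ratio* — the minimum preferential uptake
an imaging agent must deliver. On this flat-slab geometry the crossing is at
≈ 9–10:1 (grid-dependent); see `docs/methods.md` for why this parametric
geometry is conservative relative to an anatomically contoured hand, where
the same operating point is nearer 5.5:1.

The same analysis is available from the shell:

```bash
handnir threshold-curve --out curve.csv
handnir pk plasma.csv --iv-csv iv.csv --dose 1.5 --iv-dose 1.5
handnir generate phantom-config --ratio 10 --depth 2.5 --out phantom.yaml
```

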