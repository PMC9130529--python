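# pacolloid

A multi-scale forward model of **initial photoacoustic pressure generation
in aqueous colloidal suspensions** (silica and alumina), the liquid tissue
phantoms used to calibrate photoacoustic imaging systems.

When a short laser pulse is absorbed in a turbid medium, the initial
pressure at position **r** is

```
p0(r; η) = Γ(η) · μa(r) · Φ(r; η)
```

where η is the particle volume fraction, Γ the Grüneisen parameter
(Γ = βV²/C = β/(ρκC), the dimensionless photoacoustic efficiency),
μa the absorption coefficient, and Φ the fluence (light energy density).
`pacolloid` models every factor's dependence on η from the microscale up,
with a paired **no-interaction (NO)** and **hard-sphere (HS)** variant at
each scale, so the effect of inter-particle interactions on the generated
pressure can be isolated:

| scale | quantity | NO variant | HS variant |
|---|---|---|---|
| thermodynamic | Γ(η) | weight-based + Urick mixtures | same mixtures with Carnahan–Starling packing factors on the particle phase |
| scattering | μs′(η) | independent scattering theory (Mie, linear in η) | dependent scattering theory (Mie × Percus–Yevick structure factor) |
| propagation | Φ(r; η) | photon diffusion equation with the IST μs′ | same with the DST μs′ |

The package ships the thermodynamic and optical coefficients of silica,
alumina and water as a built-in registry, a YAML configuration layer, a
3D finite-volume photon-diffusion solver (Robin partial-current
boundaries, conjugate-gradient solution, deterministic), and an
end-to-end sweep pipeline that decomposes the absorber-pressure decrease
into its Grüneisen and fluence contributions.

Intended users: researchers in quantitative photoacoustic tomography and
tissue-phantom design who need volume-fraction-resolved forward models of
pressure generation.

## Worked example

```python
import pacolloid as pc
from pacolloid import thermo, optics

silica = pc.load_registry()["silica"]
for eta in (0.01, 0.20):
    hs = thermo.thermo_state(eta, silica, "HS")
    dst = optics.scattering_properties(eta, silica, "DST")
    print(f"eta={eta:.2f}  Gamma_HS={hs.gamma:.4f}  "
          f"musp_DST={dst.musp_percm:6.2f} 1/cm  g={dst.g:.4f}")
```

prints

```
eta=0.01  Gamma_HS=0.1261  musp_DST=  2.01 1/cm  g=0.0494
eta=0.20  Gamma_HS=0.1140  musp_DST= 11.56 1/cm  g=-0.0205
```

Going from a 1% to a 20% silica suspension, the Grüneisen parameter drops
by only ~10% (thermal efficiency is mildly affected), while the reduced
scattering coefficient grows almost sixfold — light transport, not
thermal expansion, dominates the pressure change.  The slightly negative
anisotropy factor at 20% is the dependent-scattering signature: the
hard-sphere structure factor suppresses forward scattering for particles
much smaller than the wavelength.

The full pipeline on the reference phantom (5.2 cm cube, 0.04 cm voxels,
0.8 cm central absorber with μa = 0.5 cm⁻¹ in a 0.05 cm⁻¹ background,
source on the x = 0 face):

```python
df = pc.run_sweep(silica, pc.default_geometry(),
                  pc.RunOptions(etas=(0.01, 0.20), models=("HS",)))
```

yields an absorber-mean pressure decrease of 0.66 decades between η = 0.01
and 0.20, of which the fluence ratio accounts for 93.4% and the Grüneisen
ratio for 6.6% — the decay of light energy density with increased
scattering is by far the dominant mechanism.

A command-line interface mirrors the library:

```sh
pacolloid registry --out registry.csv
pacolloid thermo --material silica --model both --out thermo.csv
pacolloid musp --material alumina --out musp.csv
pacolloid fluence --material silica --eta 0.15 --theory DST --out field.h5
pacolloid sweep --config config.yaml --out-dir results/
```

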