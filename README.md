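# parkzoning

Risk–value zoning for protected-area management: a tested Python pipeline
from a categorical land-use raster and a core/general park mask to
per-unit ecological-risk and ecosystem-service-value fields, kriged
surfaces, natural-breaks grade maps, and a four-zone management map
(CHR / CLR / GHE / GLE) with area and service-value reports.

## The problem

National parks managed under a "one park, two zones" model split into a
strictly protected **core area** and a **general control area** where
residents live and work. Useful zoning policy needs finer structure than
that binary split: *where inside the core is the ecosystem least able to
absorb disturbance?* and *where inside the general area are ecological
services most valuable to convert into sustainable income?* This package
answers both questions quantitatively for landscape ecologists and
protected-area planners working from land-use/land-cover rasters.

## The model

The park is tessellated into square assessment units (400 m by default).
For each land-use class *i* within an analysis region of area *A*:

- fragmentation `C_i = n_i / A_i` (patch count per class area),
- isolation `N_i = (A / 2A_i) * sqrt(n_i / A)`,
- dominance `D_i = (M_i + L_i) / 2` (mean of patch-number share and area
  share),
- disturbance `S_i = a*C_i + b*N_i + c*D_i`, weights `(a, b, c) =
  (0.6, 0.3, 0.1)`.

Each class also carries an ecological vulnerability rank `F_i` (1 =
building land … 12 = bare land); the loss index is `R_i = F̂_i * S_i` with
`F̂_i = F_i / ΣF` by default. The **Ecological Risk Index** of unit *k* is
the composition-weighted average

    ERI_k = Σ_i (A_ki / A_k) * R_i,

computed over the core protected area. The **Ecosystem Service Value** of
unit *k* uses the equivalent-factor method

    ESV_k = Σ_i A_ki * VC_i,

over the general control area, where `VC_i` prices each class per km²
from a table of dimensionless service equivalents (11 subcategories in
four groups: provisioning, regulating, supporting, cultural) times the
monetary value of one equivalent (231 427 yuan/km² by default; the whole
table is a config input).

Both unit fields are interpolated by ordinary kriging (WLS-fitted
spherical variogram, local neighborhoods, weights summing to 1), the
surfaces are classified into five grades by exact Fisher–Jenks natural
breaks (boundary values belong to the upper grade), and the four-zone map
is cut at the first ERI break (core: CHR vs CLR) and the second ESV break
(general: GHE vs GLE).

Because real park rasters are rarely redistributable, a synthetic-data
module generates forest-dominated clumped mosaics (modified random
clusters), contiguous core/general masks, border fragmentation hot-spots
and water pockets, so the whole pipeline is testable end to end.

## Worked example

```python
from parkzoning import ZoningModel, load_config

model = ZoningModel.from_synthetic(load_config({"seed": 1}))
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Risk-value park zoning results
==================================
assessment units: 2436 (1227 core, 1209 general) at 400 m
park area: 376.22 km2
weights (a,b,c): (0.6, 0.3, 0.1), connectivity 8, normalize_F True
ERI variogram: spherical nugget=0.03911 psill=0.0297 range=1356 m (1227 samples)
ERI breaks: 0.135, 0.3404, 0.6096, 1.073
ESV variogram: spherical nugget=1560 psill=654.3 range=1909 m (1171 samples)
ESV breaks: 61.47, 105.1, 189.9, 313.8
cuts: ERI >= 0.135 -> CHR; ESV >= 105.1 -> GHE

zone  area_km2  percent
 CHR     96.96    25.77
 CLR     99.36    26.41
 GHE     19.98     5.31
 GLE    159.92    42.51

         service_type  value_wanyuan  percent
Provisioning services        6223.54     6.18
  Regulating services       69936.73    69.48
  Supporting services       20154.85    20.02
    Cultural services        4347.53     4.32
total: 100662.66 wanyuan (1006.63 RMB million)
```

Reading it: on this synthetic park of 376 km², a quarter of the core area
(CHR, 96.96 km²) exceeds the first natural-breaks risk threshold and
would receive the strictest protection; 5.3% of the park (GHE) carries
high service value — dominated, as in real forest parks, by regulating
services (69.5%) — and is the natural focus for ecotourism conversion.
`results.save(outdir)` writes all fields, surfaces, maps and reports
(CSV + ESRI ASCII grids); `results.plot("maps.png")` draws them.

The same analysis runs from the shell on your own rasters:

```sh
parkzoning run --landuse landuse.asc --mask mask.asc --out out/
parkzoning simulate --seed 1 --out scene/     # synthetic inputs
```

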