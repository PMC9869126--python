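# aneuwall

Wall-thickness analysis of saccular intracranial aneurysms by a membrane
blow-molding surrogate.

The wall of a saccular intracranial aneurysm is thinnest where it is about to
fail: intraoperatively visible *translucent* areas and rupture points sit on
super-thin wall. Wall thickness cannot be measured from angiography — but it
can be estimated. If the patch of parent-artery wall that ballooned into the
sac is treated as an incompressible membrane inflated into the sac-shaped
"mold", local thickness falls as the inverse of local area stretch, and the
thinnest spots of the simulated field predict the translucent/rupture sites.

`aneuwall` implements that chain for vascular-modelling researchers: from a
vessel-with-sac surface mesh (Model A) and a reconstructed parent artery
(Model B) it computes, per aneurysm,

- **I_S = S_A / S_B** — area-increase multiple (sac surface area over neck
  patch area; the neck is treated as a curved surface, never a planar cut),
- **I_BA = δ_B / δ_B′** — thinning magnification at the minimum extreme
  point (initial thickness over minimum simulated thickness),
- **I_δ = I_BA / I_S = δ̄_B / δ_B′** — the inhomogeneity coefficient
  (mean over minimum thickness), the headline rupture-risk marker,

plus the thickness field itself, its 200-isoline contour structure, the
local-minimum extreme points, and cohort-level statistics (Spearman
correlations, Mann–Whitney/KS comparisons, empirical ROC curves with
Youden-optimal cutoffs, stratified bootstrap CIs) for a bundled cohort table
of 48 aneurysms (20 ruptured / 17 translucent-unruptured / 11
non-translucent-unruptured).

Because no patient meshes are deposited anywhere, the package ships a
first-class synthetic generator: parametric saccular sacs (ellipsoidal domes
with controllable neck width, optional blebs) grown on tubular parent
arteries, with refined ground-truth areas and volumes, and analytic
benchmark molds (disk→hemisphere, coaxial cylinders) for which the stretch
field is known exactly.

## Worked example

One synthetic aneurysm through the whole pipeline (synthesize → split at the
neck → inflate into the mold → analyze):

```bash
$ aneuwall run --out-dir demo/
I_S=6.7199 I_BA=37.2007 I_delta=5.5359 -> demo/report.json
```

`demo/report.json` (abridged):

```
S_A_mm2   53.666      # sac surface area (ground truth 53.946)
S_B_mm2    7.986      # neck patch area  (ground truth  8.042)
volume_mm3 41.910     # sac volume, vol(A) - vol(B)
I_S        6.7199     # vs generator ground truth 6.7076
I_BA      37.2007     # max thinning at the predicted rupture site
I_delta    5.5359     # inhomogeneity coefficient
```

An I_δ of 5.54 lies above the rupture cutoff (4.3991) derived from the
bundled cohort below — this synthetic sac, with its strongly ballooned dome,
would be called high-risk.

The bundled-cohort analysis:

```bash
$ aneuwall reproduce-paper --out report/
Spearman I_S-volume: group A: 0.241, group B: 0.745, group C: 0.900
idelta_translucency: AUC=0.927 cutoff=2.0753 sens=1.000 spec=0.727
iba_translucency:    AUC=0.812 cutoff=6.4424 sens=1.000 spec=0.636
idelta_rupture:      AUC=0.767 cutoff=4.3991 sens=0.500 spec=0.962
```

The I_S–volume correlation weakens from the stable group (0.900) through the
translucent group (0.745) to the ruptured group (0.241): as aneurysms
approach rupture, area and volume stop growing in step. I_δ separates
translucent from non-translucent unruptured aneurysms almost perfectly
(AUC 0.927); at the 2.0753 cutoff every translucent aneurysm is caught at
73% specificity.

Library use mirrors the CLI:

```python
import aneuwall as aw

pair = aw.make_model_pair(aw.AneurysmSpec(neck_radius=1.6, dome_axes=(2.2, 2.0, 2.4)))
sac, _ = aw.split_at_neck(pair.model_a, pair.neck_curve)
patch, _ = aw.split_at_neck(pair.model_b, pair.neck_curve)
result = aw.inflate_to_mold(patch, sac)
delta_min, delta_bar, i_ba = aw.thickness_summary(result)
i_s = aw.compute_IS(aw.surface_area(sac), aw.surface_area(patch))
print(aw.compute_Idelta(i_ba, i_s))
```

## Layout

| module | contents |
| --- | --- |
| `aneuwall.mesh` | triangle-mesh kernel: areas, divergence-theorem volumes, boundary loops, port capping, 1-rings |
| `aneuwall.synthetic` | parametric aneurysm/benchmark generators, synthetic cohorts |
| `aneuwall.neck` | sac/parent splitting along the neck curve, harmonic neck-patch reconstruction |
| `aneuwall.inflation` | quasi-static membrane inflation into the mold; stretch and thickness fields |
| `aneuwall.analysis` | isolines, extreme points, isoline-regularity CV, the three coefficients |
| `aneuwall.cohort` | bundled table, Spearman/ROC/Youden/bootstrap statistics, full report |
| `aneuwall.pipeline`, `aneuwall.cli`, `aneuwall.io` | end-to-end runs, command line, STL/CSV/JSON IO |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
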