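# lyothick

Quantitative microstructure and storage-stability analytics for freeze-dried
(lyophilized) probiotic pellets.

Freeze-dried pellets protect bacteria inside walls of amorphous
sugar/polysaccharide matrix left behind between the ice crystals. How thick
those walls are — a few tenths to a few micrometres, set by freezing rate and
any annealing step — governs how well the matrix shields the cells during
storage. `lyothick` implements the full analysis chain that connects the two:

1. **Segmentation** (`lyothick.preprocess`): a reconstructed X-ray
   microtomography volume (TIFF stack + voxel size) is despeckled with a 3D
   median filter (default 4×4×4) and binarized by grey-level thresholding
   (Otsu by default).
2. **Local thickness** (`lyothick.thickness`): for every material voxel, the
   diameter of the largest sphere fully inscribed in the material that
   contains the voxel (Hildebrand–Rüegsegger). The per-voxel map is binned
   into a volume-weighted thickness distribution with volume-weighted mean

   $$d_\mathrm{vol} = \frac{\sum_j d_j V_j}{\sum_j V_j}$$

   over thickness classes $j$ with representative diameter $d_j$ and class
   volume $V_j$, and a mode value (the class carrying the most material
   volume).
3. **Storage stability** (`lyothick.viability`): CFU/g time courses under
   accelerated storage are modelled as exponential decay
   $C(t_\mathrm{end}) = C(t_\mathrm{start})\,
   e^{-(t_\mathrm{end}-t_\mathrm{start})/\lambda}$ with
   $\lambda = (t_\mathrm{end}-t_\mathrm{start}) /
   [\ln C(t_\mathrm{start}) - \ln C(t_\mathrm{end})]$ and half-life
   $t_{1/2} = \ln(2)\,\lambda$, estimated per observation window
   (default 0–28 d and 28–56 d). Freeze-drying survival is the plated CFU
   relative to the initial viable concentration, as a percent.
4. **Association** (`lyothick.report`): thickness summaries are joined with
   half-lives per sample and the thickness–stability correlation (Pearson,
   Spearman, least-squares line) is reported per storage group.
   Samples whose structure is below the tomographic resolution are flagged
   and excluded from the numeric correlation.

Because µCT scans and viability panels of this kind are rarely shareable,
`lyothick.phantoms` generates synthetic 3D structures with closed-form wall
thickness (parallel plates, radial lamellae mimicking sheets oriented toward
a pellet centre, spherical pores) plus simulated CFU series, so every stage
is verifiable against known ground truth.

## Worked example

`examples/demo.toml` defines a four-sample synthetic study: plate phantoms
with walls of 2, 3, 5 and 7 voxels (0.64 µm voxels), rendered with 10 %
contrast noise and 0.5-voxel blur, each paired with a simulated decay series
whose half-life increases linearly with wall thickness.

```sh
lyothick run examples/demo.toml -o demo_out
```

prints

```
group=canister window=0-28d n=4 spearman_rho=1.000 pearson_r=0.996
group=canister window=28-56d n=4 spearman_rho=1.000 pearson_r=0.996
```

and `demo_out/summary.json` records, per sample, the recovered thickness
mode and half-lives — e.g. the 5-voxel wall (3.2 µm) segments back to a mode
of 3.25 µm with $d_\mathrm{vol}$ = 3.24 µm and a 11.0 d half-life in both
windows. Spearman ρ = 1 says the recovered thickness ordering exactly
matches the stability ordering, which is how a thickness–stability
relationship shows up in a real annealing study. Artefacts:
`distributions/*.csv` (per-sample thickness classes), `halflives.csv`,
`association.csv`, `summary.json`.

Single stages are available as `lyothick segment`, `lyothick thickness` and
`lyothick viability`, e.g.

```sh
lyothick segment scan.tif --voxel-um 0.64 --median-window 4 -o mask.tif
lyothick thickness mask.tif --voxel-um 0.64 --bin-um 0.5 -o dist.csv
```

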