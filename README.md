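# tme3d

Quantitative 3D analysis of the tumor microenvironment (TME) in cleared,
multiplex-immunolabeled tissue imaged by light-sheet fluorescence
microscopy — built for the lymphoma setting, where the spatial arrangement
of immune cells around T cells (B cells, Tregs, tumor-associated
macrophages, neutrophils, monocytes) carries diagnostic and prognostic
signal.

The package takes multichannel 3D image stacks (or generates
ground-truthed synthetic ones), localizes immunolabeled cells as 3D point
sets, and computes the spatial statistics used to characterize the TME,
with a rank-based comparison across disease groups. It is a library first:
`import tme3d` and compose the pieces, or use the thin `tme3d` CLI for the
shell-friendly stages.

## What it computes

For typed cell coordinates $\{x_i\}$ with marker labels (panel: CD3, CD8,
CD20, CD68, CD163, CD14, CD15, FOXP3, Ki67), within axis-aligned ROIs:

- **Cell density** — cells of a type per ROI volume (cells/mm³), half-open
  box membership.
- **Radial neighbor profile** — counts of neighbor-type cells in concentric
  5-μm shells $[r, r+5)$ out to 50 μm around each center T cell; under
  complete spatial randomness the shell mean is
  $\lambda \cdot \tfrac{4}{3}\pi (r_2^3 - r_1^3)$, so enrichment over that
  curve is spatial attraction.
- **Conjugation** — unordered pairs of cells of two different types with
  centroid distance strictly $< 15\,\mu m$, treated as interacting
  (e.g. CD8/CD20, CD8/FOXP3, CD3/CD163).
- **Co-positivity** — the fraction of base cells (e.g. CD8⁺) validated by a
  second-marker detection (Ki67⁺) within a 5-μm matching radius, greedy
  nearest-first, one marker detection per base cell.
- **Group comparison** — tie-corrected Kruskal–Wallis
  $H = \big[\tfrac{12}{N(N+1)}\sum_j R_j^2/n_j - 3(N+1)\big] /
  \big[1 - \sum_t (t^3-t)/(N^3-N)\big]$ across disease groups over per-ROI
  values, $p$ from $\chi^2_{k-1}$, $\alpha = 0.05$.

Upstream of the statistics it provides: a synthetic-data generator with the
instrument's acquisition geometry (0.59 μm lateral pixels, 2 μm plane
steps, ~300 μm optical sections tiled every 250 μm → 16.7% overlap,
3.5 μm sheet thickness, wavelength-dependent depth attenuation, Poisson
shot noise); a scale-normalized Laplacian-of-Gaussian 3D spot detector with
anisotropy-aware σ, non-maximum suppression and subvoxel refinement; and
cross-correlation z-registration with feathered fusion of overlapping
sections.

## Worked example

`examples/compare_disease_groups.py` simulates one tissue block per
packaged condition (reactive lymph node RLN-like, diffuse large B-cell
lymphoma DLBCL-like, angioimmunoblastic T-cell lymphoma AITL-like), selects
ten 150-μm ROIs per block, computes all statistics and compares them. The
run prints (abridged):

```
               metric       key     H  df   pvalue  significant highest_median_group
radial_neighbors_50um      CD20  19.9   2 4.69e-05         True                DLBCL
radial_neighbors_50um     FOXP3  19.5   2 5.76e-05         True                 AITL
          conjugation CD3/CD163  19.4   2 6.25e-05         True                 AITL
          conjugation  CD8/CD20  19.5   2 5.85e-05         True                DLBCL
         copositivity  Ki67/CD8  24.8   2 4.09e-06         True                  RLN
         copositivity Ki67/CD20 0.622   2    0.733        False                DLBCL
...
13/23 statistics differ across conditions at p<0.05.
```

Reading it: B cells are enriched around T cells in the B-cell-dominated
DLBCL-like condition; immunosuppressive Treg and TAM neighborhoods (and
T–TAM conjugations) dominate in the AITL-like condition; CD8 T-cell
proliferation (Ki67/CD8) is highest in the reactive condition while B-cell
proliferation does not differ — exactly the structure the generator
encodes. Markers configured identically across conditions (CD68, CD14)
stay non-significant.

The other examples each run one capability end to end:
`simulate_tissue_block.py`, `detect_cells.py` (F1 = 1.000 on a rendered
field of 40 spaced cells), `stitch_z_tiles.py` (jittered 4-section stack
re-registered exactly, fused error 0.000 gray levels) and
`spatial_statistics.py`.

## Command line

```bash
tme3d simulate --group DLBCL --size 600,600,300 --seed 1 --out truth.csv
tme3d detect --in ch_CD3.tif --voxel 2.0,0.59,0.59 --diameter 10 --threshold auto --out cd3_points.csv
tme3d stitch tiles/*.tif --nominal-step 250 --search 10 --out fused.tif
tme3d analyze --points truth.csv --domain 600,600,300 --out tables/
tme3d compare --in conjugation.csv --value pair_count --group group
tme3d run --seed 7 --out results/run
```

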