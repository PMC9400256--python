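# palato3d

3D virtual analysis of palatal soft-tissue thickness and volume from a
bone-surface model (CBCT-derived) and a gingival-surface model (intraoral
scan or digitised cast).

## What it computes, and why

Free gingival and connective-tissue grafts are harvested from the palatal
masticatory mucosa. Planning the harvest needs to know how much soft tissue
is available and where. The mucosa is exactly the layer between two surfaces
of the same anatomy: the bony palate (from CBCT) and the gingival surface
(from a surface scan). After rigid superimposition of the two models:

* the **thickness** at a point of the gingival surface is its distance to
  the bone surface, and
* the **graft volume** over a region of interest (ROI) is the integral of
  that thickness over the region.

The pipeline stages are:

1. **Segmentation** — threshold a HU volume (default window 150–2000 HU),
   keep the largest component, extract the bone surface by marching cubes,
   close small holes.
2. **Registration** — coarse landmark alignment, then best-fit ICP
   restricted to tooth surfaces (teeth are rigid and visible in both
   modalities; mucosa is not reliable for registration).
3. **ROI partition** — the measured region lies 3 mm inside the gingival
   sulcus (geodesically, on the surface) and anterior to the posterior
   hard-palate border; it is split into five antero-posterior bands
   (ROI 1 = canine/first-premolar … ROI 5 = second-molar) through
   per-tooth boundary landmarks.
4. **Deviation analysis** — signed nearest-surface distances with validity
   filters (≤ 15 mm, ≤ 60° incidence), per-ROI area / mean / min / max
   distance, per-face frustum-integrated volume, volume-per-area ratio,
   and a colour-coded distance map (PLY).
5. **Statistics** — pairwise per-ROI Wilcoxon signed-rank tests (exact
   enumeration for n ≤ 25, midranks for ties) with Benjamini–Hochberg
   adjustment across the test family.

Because no patient data ship with the package, a **synthetic palate
generator** produces bone/gingiva mesh pairs with analytically known
per-ROI thickness, area and volume (an anatomically shaped vault with
alveolar ridges and tooth crowns, plus a smooth anterior→posterior
thickness profile with per-patient variability). Every end-to-end claim in
the test suite is checked against this ground truth and against independent
oracles (0.1 mm voxel counting, brute-force 2ⁿ Wilcoxon enumeration,
analytic plates/shells). See `docs/methods.md` for the model and numerics.

## Worked example

Generate a synthetic patient and run the full pipeline on it:

```
$ palato3d synth --seed 42 --out-dir demo
synthetic palate (seed 42) written to demo

$ cat > demo/config.json <<'EOF'
{
  "bone_mesh": "demo/bone.stl",
  "gingiva_mesh": "demo/gingiva.ply",
  "landmarks": "demo/landmarks.json",
  "landmarks_bone": "demo/landmarks.json",
  "out_dir": "demo/out",
  "seed": 1
}
EOF

$ palato3d run --config demo/config.json
...
  roi    area_mm2  mean_mm   min_mm   max_mm     vol_mm3  ratio_mm
 ROI1  174.596861 2.009167 1.662976 2.424027  347.189399  1.988520
 ROI2  239.747368 2.495860 1.911799 2.866082  593.554903  2.475751
 ROI3  337.171269 2.816686 2.280289 3.157963  944.197340  2.800349
 ROI4  287.795531 3.059984 2.409470 3.875162  864.937650  3.005389
 ROI5  204.693243 4.122904 3.104964 4.466563  840.045333  4.103923
total 1244.004272 2.912736 1.662976 4.466563 3589.924625  2.885782
```

`demo/out/` then contains `report.csv` / `report.json` (the table above),
`roi_labels.csv` (per-face ROI assignment), `transform.json` (the estimated
rigid registration), `distance_map.ply` (colour-coded thickness map) and
`run.json` (effective config, versions, seed — re-running the same config
reproduces `report.csv` byte-identically).

The mean-distance column increases anterior → posterior (ROI 1 ≈ 2.0 mm to
ROI 5 ≈ 4.1 mm for this seed), the characteristic clinical gradient the
generator is calibrated to.

The same pipeline runs from a HU volume instead of a bone mesh
(`palato3d segment`, or a `"volume"` entry in the config), and
`palato3d cohort` generates and analyses a whole synthetic cohort with a
Table-style aggregate report and pairwise statistics.

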