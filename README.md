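# tumorica

Automatic tumor-tissue delineation from resting-state BOLD fMRI by
repeated spatial ICA with d-prime template matching.

Tumors perturb local vascularization and perfusion, so intra-tumor
voxels share coherent low-frequency BOLD fluctuations distinct from the
surrounding tissue. `tumorica` turns a routine presurgical resting-state
scan into a lesion map, with no contrast agent and no extra acquisition:
it decomposes the 4D series by spatial ICA at a swept model order
(TNCs), and automatically picks the tumor-related component — and the
model order that produced it — by matching each thresholded component
against a rough binary tumor template. It is written for neuroimaging
methodologists and presurgical-mapping researchers; a fully synthetic
lesion phantom with ground truth makes every stage testable without
patient data.

## The statistic

Each z-scored component map is binarized (z > 1, 26-connected clusters
of more than 20 voxels) and compared with the template T inside the
brain mask M:

    HR   = |B ∩ T| / |T|                 hit rate (sensitivity)
    FAR  = |B ∩ M\T| / |M\T|             false-alarm rate
    DICI = Φ⁻¹(HR) − Φ⁻¹(FAR)            discriminability index (d′)

The component with the largest DICI at each TNCs is a candidate; the
global maximum over the TNCs grid fixes the optimal model order and the
final tumor-related component. Rates of exactly 0 or 1 are clamped to
1/(2N); empty binarized maps are excluded as invalid. A region-growth
template generator (seed point + radius + intensity tolerances) and a
seed-based correlation baseline (6-mm sphere, Pearson maps at r > 0.5 /
0.8) round out the toolbox.

## Worked example

Generate a synthetic lesion phantom and run the identification end to
end (both commands also work on real NIfTI data):

```sh
tumorica phantom --preset small_fast --seed 4 --out-dir demo/data
tumorica identify --bold demo/data/bold.nii.gz \
    --template demo/data/truth_tumor.nii.gz \
    --tncs 10,20,30,40 --runs 5 --seed 9 --out-dir demo/out
```

prints

```json
{
  "optimal_tncs": 10,
  "best_component_index": 0,
  "best_dici": 5.0204128109705675
}
```

and writes `dici_report.tsv` with the four best-scoring components per
model order:

```
tncs  rank  component_index  hr        far       ...  dici       n_supra_voxels  valid
10    1     0                0.998559  0.020658  ...  5.020413   455             True
10    2     4                0.001441  0.032135  ... -1.129761   168             True
20    1     12               0.674352  0.018745  ...  2.532344   332             True
20    2     13               0.544669  0.016450  ...  2.245507   275             True
30    1     13               0.677233  0.018363  ...  2.548781   331             True
```

Reading it: at TNCs = 10 one component covers essentially the whole
lesion (hit rate 0.999) with 2% false alarms — DICI 5.02. At higher
model orders the lesion splits into per-compartment components (rank
1–2 with hit rates ≈ 0.54–0.68 each), so their DICI drops to ≈ 2.5.
The sweep therefore selects TNCs 10, component 0, and the ΔDICI
diagnostics in `dici_summary.json` (1st−2nd ≈ 6.2 here) confirm the
winner is well separated from the runner-up. The run also writes the
selected component as a z-map and binarized NIfTI, an overlay PNG, and
a JSON manifest with checksums.

Other subcommands: `template` (region-growth template from an
anatomical image), `decompose` (single fixed-TNCs decomposition),
`seedcorr` (seed-correlation baseline), `run` (full pipeline including
template growth).

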