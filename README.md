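# synquant

Quantification toolkit for studies of synapse-type-specific connectivity and
local protein synthesis in cortical interneurons.  The package re-implements,
as tested and reusable Python, the measurement layer such studies build from
FIJI macros, Clampfit sessions and spreadsheet statistics:

* **Confocal puncta / synapse quantification** — threshold-based spot
  detection with watershed splitting and a minimum particle size (0.05 μm²),
  soma/dendrite ROIs with perimeter bands, and explicit colocalization rules:
  a presynaptic punctum is a *bouton* when it lies outside the cell and
  ≥ 0.1 μm² of it overlaps the perimeter band; a postsynaptic punctum is a
  *cluster* when it lies inside the cell with ≥ 0.2 μm² band overlap; a
  *synapse* is a bouton–cluster pair whose masks intersect by ≥ 0.03 μm²
  (all thresholds inclusive).  Densities are reported per μm of soma
  perimeter or dendrite skeleton length.
* **Plated-synaptosome analysis** — the same ≥ 0.03 μm² pairing rule between
  pre- and postsynaptic puncta, plus per-synaptosome integrated density of a
  measurement channel (e.g. phospho-S6) over the union of the paired masks.
* **RNAscope counting** — particles counted inside a soma mask, and
  integrated density corrected for soma size (2D area or voxel-based 3D
  volume).
* **Patch-clamp feature extraction** — RMP; membrane time constant TC from a
  single-exponential fit to a 10 mV hyperpolarizing step; input resistance
  IR as the mean ΔV/ΔI over five increasing 10 pA steps; Ih sag on a 1 s
  pulse to −100 mV; AP peak, maximum firing frequency and fast AHP from
  increasing 100 pA steps; capacitance ≡ TC/IR; and paired-pulse ratio
  PPR = amplitude₂/amplitude₁ over ten sweeps 50 ms apart, with recordings
  flagged when the first amplitude is below 50 pA.
* **Gene-program statistics** — expressed-gene filtering against an
  intergenic background (RPKM above the 99th background percentile), DEG
  classification at p ≤ 0.05 and fold change ≥ 1.5, four-criterion candidate
  scoring with an FPKM < 5 exclusion, and gene-set overlap fold enrichment
  `(k/|query|)/(|reference|/universe)` with a two-sided Fisher's exact test.
* **Synthetic data with ground truth** — seeded generators for decorated
  cells, synaptosome fields, RC-membrane/LIF spiking protocols, paired-pulse
  EPSC sweeps and gene tables, so every stage is testable end-to-end without
  any experimental data.

## Worked example

Simulate three decorated cells (planted bouton density 0.15/μm along the
soma perimeter, 80% of boutons paired with a postsynaptic cluster) and run
the full pipeline with a minimal `config.yaml`:

```yaml
experiment: demo
preprocess: {contrast_saturation_fraction: null}
detection: {intensity_threshold: 60.0}
roi: {threshold: 60.0}
```

```sh
synquant sim cell-images --n-cells 3 --seed 7 --out images
synquant quantify-synapses \
    --image images/cell000.ome.tif --image images/cell001.ome.tif \
    --image images/cell002.ome.tif --config config.yaml --out out
```

which prints the group summary (mean ± s.e.m. across cells):

```
experiment                 metric  n      mean      sem
      demo              n_boutons  3  7.000000 0.577350
      demo             n_clusters  3  6.000000 1.154701
      demo             n_synapses  3  6.333333 0.881917
      demo synapse_density_per_um  3  0.152868 0.021282
      demo   mean_bouton_area_um2  3  0.612004 0.031122
      demo  mean_cluster_area_um2  3  0.905417 0.110497
      demo              length_um  3 41.429544 0.005459
```

Per cell, the estimated synapse densities (0.1207, 0.1931, 0.1448 /μm in
`out/per_cell.csv`) match the generator's ground truth (0.1208, 0.1933,
0.1450 /μm in `images/ground_truth.csv`) to within a fraction of a percent:
every planted bouton–cluster pair is detected, classified and paired, and
the measured soma perimeter (41.4 μm) agrees with the analytic ellipse
perimeter.  The same library functions are available programmatically
(`synquant.detect_puncta`, `synquant.classify_puncta`,
`synquant.call_synapses`, `synquant.compute_intrinsic_properties`,
`synquant.overlap_enrichment`, …).

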