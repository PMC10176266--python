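# trophoquant

Per-cell immunofluorescence quantification for trophoblast differentiation
assays.

Human trophoblast stem cells (hTSCs) differentiate into either multinucleate
syncytiotrophoblast (STB) or invasive extravillous trophoblast (EVT), and
experiments probing what switches that fate — e.g. exposure to laminin-111 —
are read out through quantitative microscopy: how many cells are in a field,
how much HLA-G or Notch1 each cell expresses relative to an isotype control,
whether a cell sits alone or in a colony, and what fraction of nuclei have
fused into syncytia. `trophoquant` implements that readout as a tested,
reproducible pipeline for researchers doing image-based single-cell
profiling of differentiation experiments:

- **Nucleus detection** from the DAPI channel: binarization (Otsu or global
  threshold), mask cleaning, optional watershed splitting of touching
  nuclei, per-field cell counts.
- **Per-cell marker assignment**: each cell receives the mean intensity of
  the connected stain component nearest its nucleus; if the nearest stain is
  farther than the nearest *other* nucleus (the signal likely is not its
  own), the cell falls back to the isotype-control average. A nuclear mode
  restricts averaging to DAPI-overlapping pixels (for HIF1α/HIF2α). All
  values are normalized as fold over the pooled isotype reference, so
  fallback cells normalize to exactly 1.0.
- **Spatial and score layers**: single-cell vs. colony classification (no
  neighbor within 50 μm ⇒ single), quartile stratification by a primary
  marker after excluding double-negative cells (equal-sized bottom/top
  groups of floor(n/4)), and the syncytial fusion index
  (N − S)/T from manual counts or membrane-partitioned images.
- **Statistics**: large-sample Mann-Whitney U (midranks, tie-corrected
  variance) for non-normal per-cell intensities, an exact enumeration oracle
  for small samples, an F-test-gated Student/Welch t-test, and ΔΔCT log2
  fold changes normalized to the geometric mean of GAPDH/ACTB and a
  reference condition.
- **Synthetic data with ground truth**: every stage is testable end-to-end
  on generated fluorescence fields (colonies + single cells, anti-correlated
  marker populations, isotype fields, membrane fields with a known fusion
  index) and Ct tables with known fold changes.

See `docs/methods.md` for the full model, parameter defaults, and
limitations.

## Worked example

Quantify six day-6 EVT fields against an isotype control, then ask whether
the cells lowest in HLA-G express more Notch1 — the signature of
column-stage vs. mature EVTs:

```python
import numpy as np
import trophoquant as tq
from trophoquant.pipeline import (RunConfig, run_quantification,
                                  classify_dataframe, dataframe_to_measurements)
from trophoquant.spatial import quartile_stratify
from trophoquant.stats import mann_whitney_large_sample, significance_marker

mk = lambda seed: tq.FieldSpec(n_colonies=2, cells_per_colony=(5, 8),
                               n_single_cells=5, noise_sd=2.0, seed=seed)
experimental = [tq.generate_field(mk(s), field_id=f"d6_f{s}", group_id="d6_EVT")[0]
                for s in range(1, 7)]
isotype = [tq.generate_isotype_field(mk(100), field_id="iso1")[0]]

cells, manifest = run_quantification(RunConfig(seed=0), experimental, isotype)
cells = classify_dataframe(cells)
print(f"{len(cells)} cells quantified; green isotype reference = "
      f"{manifest['isotype_references']['green']['value']:.2f}")

measurements = dataframe_to_measurements(cells)
labels, bottom, top = quartile_stratify(measurements, "green", "red")
b = [c.normalized["red"] for c in bottom]
t = [c.normalized["red"] for c in top]
res = mann_whitney_large_sample(b, t)
print(f"bottom HLA-G quartile (n={len(b)}): median Notch1 = {np.median(b):.1f}x isotype")
print(f"top    HLA-G quartile (n={len(t)}): median Notch1 = {np.median(t):.1f}x isotype")
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.2e} {significance_marker(res.p_value)}")
```

Output:

```
108 cells quantified; green isotype reference = 8.00
bottom HLA-G quartile (n=27): median Notch1 = 25.0x isotype
top    HLA-G quartile (n=27): median Notch1 = 6.3x isotype
Mann-Whitney U = 729, p = 2.87e-10 ***
```

The isotype reference recovers the background level of the control field
(8.0), the equal-sized quartile groups hold floor(108/4) = 27 cells each,
and the anti-correlated populations built into the synthetic field come out
as a ~4-fold difference in median Notch1 between HLA-G quartiles, highly
significant under the Mann-Whitney test.

The same stages are available from the shell:

```bash
trophoquant simulate --out fixtures --seed 1     # ground-truthed fields + Ct table
trophoquant all --out demo --seed 1              # full demo run
trophoquant stats --ct fixtures/ct_table.csv --out fold_changes.csv
trophoquant fuse --counts counts.csv --out fusion_summary.csv
```

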