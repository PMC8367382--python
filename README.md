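# coreshell

Quantification and cell-typing pipeline for iterative multiplexed
fluorescent in situ hybridization (mFISH) of the mouse claustrum, built
around the observation that claustral excitatory neurons form two
spatially nested subtypes — a *Synpr*-expressing **core** surrounded by
an *Nnat*-expressing **shell** — that project preferentially to the
retrosplenial cortex (RSC) and lateral entorhinal cortex (LEC)
respectively.

The package is aimed at labs doing iterative smFISH (rounds of
hybridize / image / cleave with a DAPI counterstain per round) who want
a tested, scriptable version of the classic Fiji-style analysis:
register rounds on DAPI, segment and dilate nuclei, binarize probe
channels at a histogram-tail threshold, score cells by percent area
covered, cluster, and overlay retrograde tracer labels.  Because raw
imaging data of this kind is large and rarely shareable, the package
ships a first-class synthetic-data generator with planted ground truth
(cell positions, phenotypes, transforms, projection labels), so every
stage is testable end to end on any machine.

## The statistic at the core

For cell *i* and gene *g*, the **percent area covered** is

    PAC(i, g) = 100 · |{positive pixels of g} ∩ ROI_i| / |ROI_i|

where the positive pixels are those above a per-gene quantile threshold
(the last 0.2–1 % of the intensity histogram; default tail 0.5 %) and
ROI_i is the cell's segmented nucleus expanded isotropically by 5 µm
into the surrounding cytosol, with contested pixels assigned to the
nearest nucleus.  Cells with PAC(Slc17a7) ≥ 1 are retained as
excitatory; Slc17a7 is then dropped, profiles are L1-normalized within
each cell, embedded with UMAP (k = 15) and clustered per animal with
Leiden community detection at the resolution yielding five clusters.
Marker genes assign phenotypes (Synpr → core, Nnat → shell, Ctgf → deep
layer 6, Pcp4 ranks the cortical clusters), and retrograde label
channels are overlaid to build the core/shell × RSC/LEC contingency
table after excluding dual-projecting cells.  Group comparisons use
two-sided Mann–Whitney U tests with Bonferroni correction.

A small companion module reproduces the scRNA-seq bookkeeping: CPM
normalization and the sequential quality-control filters (Snap25
CPM < 0.001, then Slc17a7 CPM < 1e-10) that take 1112 harvested cells
to 1011 retained excitatory neurons.

## Worked example

One fully synthetic 1024 × 1024 µm section with 600 cells, analyzed end
to end:

```python
from coreshell.pipeline import RunConfig, run_all

config = RunConfig(seed=7, n_cells=600, field_um=(1024.0, 1024.0),
                   core_radius_um=130.0, shell_radius_um=215.0,
                   deep_l6_radius_um=275.0, include_umap=False)
result = run_all(config)

rep = result.report
print(rep["counts"], rep["clustering"]["phenotype_map"],
      rep["projection"]["percent"])
```

prints (abridged):

```
cells planted/segmented/gated: 600/597/585
clusters: 5 at resolution 0.1
phenotypes: {1: 'core', 0: 'shell', 4: 'deep_L6', 2: 'cortex_a', 3: 'cortex_b'}
labeled: 64 (dual fraction 3.1%)
contingency percentages: {'RSC': 81, 'LEC': 94}
Synpr: U=789  adjusted p=4.06e-07  ***
Nnat: U=160  adjusted p=1.23e-05  ***
```

Reading this: of 600 planted cells, 597 nuclei were segmented and 585
passed the excitatory gate; Leiden found exactly five clusters which the
markers mapped onto the five planted phenotypes; of 64 tracer-labeled
cells, 3.1 % carried both labels and were excluded; 81 % of the
remaining RSC-projecting core/shell cells sat in the core cluster and
94 % of LEC-projecting ones in the shell (single-section values —
pooled over ten sections these converge to the affinity-implied
85 %/84 %); and Synpr/Nnat were differentially expressed between the
projection groups in the planted directions.

The same stages are exposed as a CLI
(`coreshell simulate|register|segment|quantify|cluster|project|scqc|run-all`),
each reading and writing plain TIFF/CSV/JSON/MatrixMarket artifacts.

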