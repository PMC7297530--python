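# adsyn — synaptic innervation analysis of apical dendrites

`adsyn` quantifies how inhibitory and excitatory synapses are distributed
over the apical dendrites (ADs) of cortical pyramidal neurons, starting
from webKnossos-style NML skeleton annotations in which every synapse,
spine neck and landmark is a node comment. It is aimed at connectomics
groups analysing dense EM reconstructions of upper cortex: the package
turns raw annotation files into per-dendrite synapse densities,
inhibitory input fractions, axonal target-preference statistics,
cell-type classifications, and distance-dependence model fits — and ships
a synthetic-annotation generator with ground truth so that the whole
analysis chain is testable end to end.

## The quantities at the core

* **Synapse identity.** Synapses on dendritic shafts, spine necks and
  secondary innervations of a spine head are counted *putative
  inhibitory* (i); primary spine innervations are *excitatory* (e).
  Densities are per µm of spine-neck-free shaft path length, the
  inhibitory input fraction is i/(i+e).
* **Main-bifurcation window.** Analyses concentrate on a ±10 µm
  path-length window around the main bifurcation (MB), the Y-shaped
  branch point of the apical trunk near the layer 1/2 border.
* **Axonal target preference.** Axons reconstructed from a seed synapse
  on an AD are described by their 8-category output fractions (L2 AD,
  deep-layer AD, other shafts, single/double-innervated spines, somata,
  AIS, glia), giving the conditional innervation probability p(B|A).
  Group differences are tested with a pooled-resampling bootstrap
  (10,000 resamples, Bonferroni correction over 8 categories).
* **Distance dependence.** The inhibitory fraction at the MB follows a
  single-term exponential with offset, I(d) = a·e^(b·d) + c, of the
  soma→bifurcation path distance d; excitatory density and inhibitory
  fraction of L5 cells follow linear and linear-fraction
  ((a·x+b)/(c·x+d)) models of "thick-tuftedness" (PC 1 of four L5
  morphology features).

## Worked example

```python
import numpy as np
from adsyn import (GeneratorConfig, generate_dendrite_annotations,
                   density_result, mb_window)

cfg = GeneratorConfig()
ads, truth = generate_dendrite_annotations(cfg, {"L2": 41, "DL": 41}, seed=1)
for ct in ("L2", "DL"):
    rs = [density_result(ad, window=mb_window(ad))
          for ad in ads if ad.celltype == ct]
    print(ct,
          round(float(np.mean([r.dens_shaft_len for r in rs])), 3),
          round(float(np.mean([r.inh_fraction for r in rs])), 3))
```

prints

```
L2 0.412 0.345
DL 0.229 0.126
```

i.e. layer-2 ADs receive ~0.41 shaft (putative inhibitory) synapses per
µm at their main bifurcation — about a third of their synaptic input —
while deep-layer ADs receive ~0.23 per µm, only ~13% of their input: the
cell-type-specific inhibitory targeting the analysis is built to detect.
The same functions run on parsed NML files
(`parse_nml` → `to_physical` → `dendrite_from_tree`).

A shell interface covers the pipeline stages:

```sh
adsyn simulate --seed 1 --out-dir run/          # NML + truth tables
adsyn quantify run/dendrites.nml                # per-dendrite densities
adsyn report --seed 1 --out-dir run/            # full pipeline + JSON report
```

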