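# atollnet

Residency, activity-space and movement-network analysis of passive
acoustic-telemetry detections from fixed receiver arrays.

`atollnet` is a Python library (plus a thin `atollnet` command-line
wrapper) for the standard analysis chain applied to long-term shark and
reef-fish tracking studies: clean the raw detection logs, compute
per-animal residency and roaming indices, estimate kernel-density
activity spaces, and build empirically derived Markov-chain (EDMC)
movement networks over the receiver array.  It was written around a
seven-year study of 77 Caribbean reef sharks (*Carcharhinus perezi*)
tracked on an 18-receiver array at a remote Caribbean atoll, ships that
study's per-shark summary table as a regression fixture, and includes a
fully seeded synthetic-detection generator so every stage is testable
end to end without field data.

## The metrics and models

For an animal with `D` detection days (days with ≥ 2 detections):

* **Residency index** `RI = D / 1877`, the nominal tag life in days
  (denominator shortened for reported captures and for tags that
  outlived their rating) — a conservative measure of array use.
* **RI_max** `= D / span(tagging → last detection)` — the optimistic
  counterpart.
* **Roaming index** `= receivers visited / 18` — array-wide spread.
* **Activity space**: detections collapse to one relocation per
  occupied 30-min bin; a bivariate normal kernel (default h = 1000 m)
  gives a utilisation distribution whose 50% / 95% percent-volume
  contours are the core / total activity space (areas in km²).
* **EDMC movement networks**: hourly presence states over 16 merged
  receiver nodes plus an ABSENT state; transition-count matrices are
  row-normalised and the stationary distribution π (πP = π), found by
  the power method, serves as an eigenvector-centrality proxy for where
  an animal is most likely to be.

Cleaning rules, sex-specific life-history stages, Gaussian GLMs with
AIC model selection, Mann–Whitney / Kruskal–Wallis comparisons with a
Dunn post hoc, and the synthetic generator are described in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import atollnet as an
from atollnet.residency import fit_linear_model, summarize_cohort

table = an.load_table1()        # packaged 77-shark summary table
s = summarize_cohort(table)
fit = fit_linear_model(table, "roaming_index", ("tl",))
```

Running [examples/02_cohort_summary.py](examples/02_cohort_summary.py)
prints:

```
n = 77 sharks
mean RI     = 0.22 +/- 0.21 sd (90% below 0.5)
mean RI_max = 0.44 +/- 0.29 sd (30 animals above 0.5)
site- and array-faithful (RI_max > 0.5 and roaming < 0.5): 19 animals, 63% of them mature females
  size class A: 24 (14 F, 10 M)
  size class B: 14 (5 F, 9 M)
  size class C: 39 (20 F, 19 M)

roaming_index ~ TL (Gaussian GLM):
           estimate    s.e.  t-value  p-value
intercept    0.7843  0.1093   7.1748   0.0000
TL          -0.0021  0.0007  -3.2603   0.0017
```

Mean residency is low (most animals are detected on well under half of
their tags' expected days), a fifth of the cohort is simultaneously
site-faithful (high RI_max) and spatially restricted (low roaming) —
mostly mature females — and the roaming regression's negative slope
says larger sharks spread over fewer receivers.

The other example scripts each demonstrate one capability on a small
synthetic cohort: detection cleaning and residency
(`01_filter_and_residency.py`), activity spaces (`03_activity_space.py`),
movement networks (`04_movement_network.py`) and generator parameter
recovery (`05_parameter_recovery.py`).

## Command line

```sh
atollnet simulate --seed 1 --config sim.yaml --out data/
atollnet filter --detections data/detections.csv --stations data/stations.csv \
         --sharks data/sharks.csv --out cleaned/
atollnet residency --from-table --out results/
atollnet kde  --detections ... --stations ... --out kd/
atollnet edmc --detections ... --stations ... --out networks/
atollnet report --from-table --out report/
```

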