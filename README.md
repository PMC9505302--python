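# repgvhd

Analysis of T-cell receptor β-chain (TRB) repertoires in patients
receiving donor lymphocyte infusion (DLI) after allogeneic stem-cell
transplantation, where the clinical question is whether clonal expansion
of the CD4⁺CD25⁺CD127^low regulatory T-cell (T_reg) or CD4⁺ conventional
T-cell (T_con) repertoire tracks — or predicts — graft-versus-host
disease (GVHD).

The package takes per-sample clonotype tables (MIXCR/VDJtools-style TSV
or AIRR Rearrangement TSV), equalizes sequencing depth, computes
repertoire diversity and clonality statistics, classifies samples
against a healthy-control reference, quantifies longitudinal changes,
and compares GVHD incidence between repertoire classes with
competing-risk survival statistics. Because real patient repertoires of
this kind are rarely public, the package ships first-class synthetic
generators that reproduce the statistical structure the analysis
assumes, so the whole chain is testable end to end.

## Statistics at the core

For a sample with clone frequencies *p₁ … p_S* (recomputed from read
counts after random downsampling of every sample to a common depth of
20,000 reads):

- **Inverse Simpson diversity** 1/D = 1 / Σᵢ pᵢ² — the effective number
  of equally abundant clones; low values mean clonal expansion.
- **Clonal-space occupancy** — the minimal number of most-abundant
  clonotypes whose summed frequency reaches 25 / 50 / 75 / 100% of the
  repertoire.
- **Top-20 clonal proportion** — the summed frequency of the 20 most
  abundant clonotypes.

A sample is **expanded** when its 1/D lies strictly below the 25th
percentile of healthy-control 1/D (healthy controls contribute their
per-individual mean over repeated samples), otherwise **healthy-like**.
Longitudinal change is reported as 100·(post − pre)/pre around a
clinical anchor (e.g. GVHD onset). Group comparisons dispatch through a
Shapiro–Wilk normality gate to t / Mann–Whitney / Wilcoxon tests; GVHD
incidence between repertoire classes is compared with the
Aalen–Johansen cumulative incidence estimator, Mantel–Haenszel hazard
ratios, and Gray's test, treating relapse and non-relapse mortality as
competing events over a 36-month follow-up.

## Worked example

```python
from dataclasses import replace
from repgvhd import (RepertoireSimConfig, simulate_repertoire,
                     downsample_reads, compute_metrics)

cfg = RepertoireSimConfig(seed=7)                       # 2000 clones, 100k reads
healthy = downsample_reads(simulate_repertoire(cfg, sample_id="healthy"),
                           20_000, seed=1)
expanded = downsample_reads(
    simulate_repertoire(replace(cfg, expansion_factor=20.0),
                        sample_id="expanded"), 20_000, seed=1)

for t in (healthy, expanded):
    m = compute_metrics(t)
    print(f"{t.sample_id:9s} 1/D={m.inv_simpson:7.2f}  "
          f"cs25={m.clonal_space[0.25]:3d}  top20={m.top_n_proportion:.3f}  "
          f"n_unique={m.n_unique}")
```

```
healthy   1/D=  55.00  cs25=  6  top20=0.440  n_unique=1776
expanded  1/D=   5.54  cs25=  1  top20=0.903  n_unique=894
```

Multiplying the five largest clone masses by 20 collapses the effective
clone number from 55 to 5.5, lets a single clone fill the top quarter of
the clonal space (cs25 = 1 instead of 6), and pushes the top-20 clones
from 44% to 90% of the repertoire — the qualitative signature that
separates GVHD-associated repertoires from healthy-like ones.

The same analysis runs from the shell on real clonotype tables:

```sh
repgvhd simulate --preset cohort --seed 3 --out sim/      # or your own data
repgvhd normalize --manifest sim/samples.tsv --out-dir norm/ --seed 1
repgvhd metrics --manifest sim/samples.tsv --out metrics.tsv
repgvhd survival --events sim/events.tsv --out-dir surv/
repgvhd run --config config.yaml                          # full pipeline
```

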