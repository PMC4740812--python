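# tbpnoise

Why are some yeast genes expressed with large cell-to-cell variability
while others with the same mean expression are quiet?  A major
determinant is the TATA-box binding protein (TBP) and what happens to it
at the TBP-binding site (TBS) of a promoter: TBP can arrive inside the
TFIID holo-complex and initiate transcription stably, or bind the DNA as
a monomer and then be either captured by the SAGA co-activator
(transcription in large bursts) or evicted by the ATPase Mot1p (no
transcription).  `tbpnoise` models this decision process and implements
the analysis stages around it, so the whole chain — from promoter
sequence to population noise — can be run and tested on synthetic data.

The core is a discrete-time Markov chain over five promoter microstates

```
f (free) --a--> T (TBP:TBS) --p_e·c--> M (TBS:TBP:Mot1p)      Off
                    |       --p_e·(1-c)--> S (TBS:TBP:SAGA)   On
f --p_D--> D (TBS:TBP:TFIID)                                  On
```

with per-step binding probability `a` (the TBS affinity for monomeric
TBP), direct TFIID recruitment `p_D`, partner engagement `p_e`,
competition `c` (probability the partner is Mot1p rather than SAGA), and
geometric residence times `r_M < r_S < r_D`.  States S and D are the
transcribing ("On") macrostate; expression accrues per step spent there
(`b_S > b_D`: SAGA initiation is burstier), and population noise is the
coefficient of variation (CV = s.d./mean) of per-cell totals over 500
cells × 150 steps.

Around the simulator the package provides:

* `tbs_classify` — TATA-box / TATA-like / other classification of 8-mers
  against the `TATAWAWR` consensus (0 / 1–2 / ≥3 mismatches) with the
  T5/A5 position-5 subsets, and a promoter scanner;
* `cofactor_classes` — median-split TFIID/SAGA regulation classes
  (+/+, +/−, −/+, −/−) from Taf1p and Spt20p occupancy, and TBP turnover
  binning;
* `pbm` — protein-binding-microarray probe aggregation to per-8-mer
  medians and class-level comparisons;
* `noise_metrics` — CV and DM (distance of log10 CV from a running
  median over mean abundance), Wilcoxon rank-sum, Benjamini–Hochberg,
  χ² and box-plot summaries;
* `cytometry` — the GFP reporter-noise processing chain (ADC filtering,
  5% scatter-tail trim, small-cell gate, size correction by regression,
  replicate-averaged CV);
* `synthetic_data` — seeded generators for every input with planted
  truth labels.

## Worked example

```python
import numpy as np
from tbpnoise import (TATA_BOX_PARAMS, TATA_LIKE_PARAMS,
                      build_transition_matrix, simulate_population,
                      population_noise)

for name, params in [("TATA-box", TATA_BOX_PARAMS),
                     ("TATA-like", TATA_LIKE_PARAMS)]:
    m = build_transition_matrix(params)
    res = simulate_population(m, params, n_cells=500, n_steps=150, seed=1)
    print(f"{name}: mean expression {res.expression.mean():.0f}, "
          f"CV {population_noise(res):.3f}")
```

prints

```
TATA-box: mean expression 136, CV 0.382
TATA-like: mean expression 144, CV 0.070
```

Under Mot1p-dominant competition (`c = 0.9`) the TATA-box promoter —
which delivers TBP mostly as a monomer — is five times noisier than the
TATA-like promoter, which relies on stable TFIID recruitment: monomeric
TBP is usually evicted by Mot1p and only occasionally captured by SAGA,
producing sparse large bursts.  Sweeping competition and SAGA residence
(`tbpnoise sweep`, or `sweep_phase_diagram`) reverses the ordering in
the SAGA-dominant / long-residence corner, where the same TATA-box
promoter becomes the quieter one.

The numbered scripts under `analysis/` run the full narrative on
synthetic data (generate inputs → classify TBS → occupancy classes →
PBM → DM → simulations → cytometry), writing tables under `results/`:

```
python analysis/01_synthesize_inputs.py 1
python analysis/02_classify_tbs.py
...
python analysis/07_cytometry.py
```

The same stages are available as CLI subcommands
(`tbpnoise synth|classify|pbm|noise|simulate|sweep|cytometry|report`),
each writing a manifest with config and seed beside its outputs.

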