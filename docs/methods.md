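# Methods

## The promoter-state Markov chain

A single promoter is modelled as a discrete-time Markov chain over five
microstates of TBP assembly at the TBS: free (`f`), monomeric TBP bound
(`T`), and the three partner complexes Mot1p (`M`), SAGA (`S`) and
TFIID (`D`).  `S` and `D` are the transcribing (On) macrostate, the
rest are Off.  The transition graph encodes the promoter decision tree:

* `f → T` with probability `a` (TBS affinity for monomeric TBP) and
  `f → D` with probability `p_D` (holo-TFIID recruitment); otherwise the
  promoter stays free.
* From `T`, a partner engages with probability `p_e`; the competition
  parameter `c` decides whether it is Mot1p (`T → M`, probability
  `p_e·c`) or SAGA (`T → S`, `p_e·(1−c)`); `t_off` is spontaneous
  dissociation (`T → f`).
* `M`, `S`, `D` each return to `f` with probability `1/r` where `r` is
  the complex's mean residence time in steps (geometric residence — the
  memoryless discrete-time analogue of a mean dwell time).

All other transitions are zero.  In particular `T → D = 0`: TFIID
arrives only as a pre-assembled holo-complex on a free promoter, never
by completing around pre-bound monomeric TBP.  `f → M` and `f → S` are
zero because both Mot1p and SAGA act on DNA-bound monomeric TBP.

A population is `n_cells` independent chains started cold in `f`.
Expression accrues `b_S` per step in `S` and `b_D` per step in `D`
(burst-per-entry is available as a switch); there is no degradation
term.  Population noise is the CV (sample s.d. with `n−1`, divided by
the mean) of final per-cell totals; a zero-mean population yields a
flagged NaN rather than an infinity.

### Default parameters

| parameter | TATA-box | TATA-like | meaning |
|---|---|---|---|
| `a` | 0.50 | 0.05 | monomeric TBP binding / step |
| `p_D` | 0.10 | 0.55 | holo-TFIID recruitment / step |
| `p_e` | 0.80 | 0.80 | partner engagement of bound TBP |
| `c` | 0.90 | 0.90 | P(partner is Mot1p) |
| `t_off` | 0.05 | 0.05 | spontaneous TBP dissociation |
| `r_M, r_S, r_D` | 2, 10, 50 | 2, 10, 50 | mean residences (steps) |
| `b_S, b_D` | 5, 1 | 5, 1 | expression per On step |

The residence ordering (Mot1p fast, SAGA intermediate, TFIID stable)
and the SAGA burst size `b_S = 5·b_D` reflect the biochemistry of the
three complexes; the absolute values are the package's own calibration
— chosen once so that all qualitative regimes of the model are
expressed at the standard 500 cells × 150 steps — since no measured
per-step probabilities exist for this abstraction level.  The two
archetypes share the total delivery propensity `a + p_D = 0.6` and
differ only in *how* TBP arrives, which isolates the delivery-route
effect on noise.

### Affinity sweep

`affinity_sweep` varies `a` while holding `a + p_D` fixed (default
`couple_tfiid=True`): a better TBS shifts TBP delivery from the
holo-TFIID route to the monomeric route.  Under Mot1p-dominant
competition this makes CV strictly increasing in `a` (Spearman ρ = 1.0
over the default 8-point grid).  Without the coupling the relation is
non-monotone — at `a → 0` with a fixed small `p_D`, expression comes
from rare long TFIID bursts and CV rises again — so the uncoupled sweep
is available but not the default.

### Phase diagram

`sweep_phase_diagram` overrides `(c, r_S)` in both archetypes over a
10×10 grid (c ∈ [0.05, 0.95], r_S ∈ [2, 100] geometric), 3 replicate
populations each, and records replicate-averaged CVs and their
difference.  Two regimes appear: Mot1p-dominant / short-SAGA-residence
cells where the TATA-box archetype is noisier (CV difference up to
≈ +0.7), and a SAGA-dominant / long-residence corner where it is
quieter (≈ −0.4): with SAGA winning the competition and residing long,
the monomeric route becomes the *stable* one and TFIID's 50-step
residence is what limits the TATA-like promoter.

### Derived statistics

* **Waiting times** — lengths of maximal Off-runs (`{f,T,M}`) strictly
  between two On visits; leading/trailing runs are censored and
  excluded by default.
* **Turnover** — transitions from `f` into a TBP-acquiring state
  (`T` or `D`) per simulated step, averaged over cells; Mot1p cycling
  back and forth through `f` makes TATA-box promoters turn TBP over
  ≈ 3× faster than TATA-like promoters at defaults.
* **Stationary distribution** — power iteration to L1 tolerance 1e−12
  (cap 200,000 iterations); reducible chains are flagged and resolved
  on the component reachable from `f`.  Tests cross-check against an
  eigen-decomposition oracle, and the sampler against the exact
  asymptotic variance from the chain's fundamental matrix.

### Random numbers

One integer master seed; each cell's uniform stream derives from
`SeedSequence(seed, spawn_key=(cell,))`, so enlarging a population
extends rather than reshuffles it, and identical `(params, seed)` give
bit-identical results.  Sweeps derive per-grid-cell/replicate seeds the
same way (all below 2³¹).

## TBS classification

8-mers are scored against the yeast consensus `TATAWAWR` (W = A/T,
R = A/G): 0 mismatches → TATA-box, 1–2 → TATA-like, ≥3 → other.  Exact
matches split into T5/A5 by the base at motif position 5 (1-based).
Only 8 exact instances exist (2 × 2 × 2 choices at the degenerate
positions), 4 per subset.  The promoter scanner reports the
minimal-mismatch window, leftmost on ties, forward strand by default
(reverse-complement scanning optional; offsets always 0-based on the
forward strand).  Classification is sequence-only: the experimental
definition of a TATA-like site additionally requires measured TBP
binding, which synthetic promoters supply by construction.

## Occupancy classes and turnover bins

A gene is TFIID-regulated if its Taf1p occupancy is strictly above the
across-gene median, SAGA-regulated likewise for Spt20p; at-median
values count as not regulated (deterministic under ties).  Medians are
taken per factor over genes where that factor was detected; genes
missing either factor are excluded.  Per-column standardization
(`rescale_center`) is provided for display and provably cannot change
the classification (tested invariant).  Turnover values are split
low/high at their median, reporting the bin boundaries.

## PBM aggregation

Replicate probe intensities collapse to a per-motif median (midpoint
convention for even counts; single-replicate motifs flagged).  Class
comparisons use motif medians; the T5-vs-A5 comparison uses probe-level
intensities when the probe table is available, because 4-vs-4 motif
medians cannot resolve significance below p = 0.029 by rank-sum.  All
pairwise tests are two-sided Wilcoxon rank-sum with BH correction.

## Noise metrics

DM is the residual of log10 CV from a running median over genes ranked
by mean abundance.  Gene *i* (rank order, n genes) uses the symmetric
rank window `i−k … i+k`, `k = min(window//2, i, n−1−i)`, default window
50.  The symmetric shrink keeps the gene centered, which makes DM
identically zero whenever log CV is monotone in the mean — the exact
`cv = k/√mean` cohort is the degenerate test case — and makes DM
invariant under rescaling all means.  Window size and log base are
configuration; defaults are declared, not measured.

Rank-sum tests use exact enumeration for tie-free samples of ≤ 8
observations and the tie-corrected normal approximation otherwise;
BH adjustment is the standard step-up with monotonicity enforcement;
χ² goodness-of-fit rescales expected counts to the observed total (the
test compares ratios).  Box-plot summaries use linear-interpolation
quartiles and 1.5×IQR fences; outliers are flagged for display only and
never removed from any computation.

## Cytometry chain

Fixed stage order, each stage a pure subset selection or annotation,
applied per replicate: (1) keep events with both scatter channels in
the open interval (0, 2¹⁸−1) — the 18-bit ADC range — then trim
⌊0.05·n⌋ events from each tail of total scattering (FSC-A·SSC-A by
default; per-channel trimming optional); (2) gate to events strictly
below the 0.5 quantile of the scatter product (the small unbudded
subpopulation; a degenerate all-tied gate falls back to ≤ with a
warning); (3) fit OLS `GFP ~ FSC-A + SSC-A` with intercept and derive
corrected fluorescence.  Two corrections are provided:

* `squared` (default): `GFP²/fitted`, the protocol formula as printed.
  When fluorescence is multiplicative in size (`GFP = s·g`) and the
  regression captures `s`, this equals `s·g²/ḡ`, whose CV is ≈ 2× the
  expression CV — it removes the size *trend* but inflates the scale of
  relative fluctuations.
* `ratio`: `GFP/fitted`, the conventional normalisation; this is the
  variant that recovers the underlying expression CV (0.5–1% error at
  20,000 events under the generator's defaults) and is what the CV
  recovery checks use.

Per-replicate CVs are averaged; the s.e. across replicates is
s.d./√k.

## Synthetic data

Generators are pure functions of `(config, seed)` (independent
substreams per generator) and emit truth tables for exact planted-label
checks.  Noise is lognormal throughout: strictly positive and
right-skewed like the underlying assays.  Defaults (the study
conditions): 2,000 genes with class mix 10% T5 / 10% A5 / 30% TATA-like
/ 50% other; 3-fold regulated-vs-not occupancy shift with σ = 0.2 and
1.3-fold per-class steps on Spt20p and TBP (Taf1p flat; Mot1p built
from the Spt20p and TBP draws); PBM medians 3000/2200/1200/600 a.u.
(T5/A5/TATA-like/other) with σ = 0.25 and 8 probes per motif;
`cv = 9.5/√mean` with log10 DM offsets +0.15/+0.10/0/−0.05 and residual
σ = 0.05; turnover uniform in class sub-ranges of the observed
[0.008, 0.051] a.u.; 20,000 events × 2 replicates with size σ = 0.25,
5% channel noise and a multiplicative size confound on GFP.

Promoter backgrounds are GC-rich (80%) and rejection-sampled so the
planted TBS window is the strict mismatch minimum (with a ≥3 floor for
"other" genes).  A global "≥3 mismatches everywhere else" guarantee is
impossible for periodic planted motifs — windows overlapping
`TATATATA` inherit most of its bases — so strict dominance is the
contract; it suffices for 100% class and offset recovery.

What the generators do **not** emulate: real promoter base composition
and nucleosome context, probe-sequence effects and spatial artefacts on
PBM chips, instrument drift and spillover in cytometry, and any
correlation structure between assays beyond the shared class labels.
Passing tests therefore demonstrate that the pipeline recovers planted
structure of the stated form and effect size, not that real data meet
those assumptions.

## Problem sizes and numerical conventions

Simulations use 500 cells × 150 steps (3 replicates per condition; 10
seeds for ordering checks; 50,000 single-cell steps for
stationarity/ergodicity checks); the phase diagram is 10×10; the
synthetic cohort is 2,000 genes and 20,000 events × 2 replicates —
sizes at which every reported effect is resolved with comfortable
margin.  Row-stochasticity is asserted to 1e−12 at matrix construction;
sampling uses cumulative rows with the last bin closed at 1 against
rounding; CV conventions are sample s.d. (`ddof=1`) everywhere.

## Known limitations

* Per-step probabilities are an abstraction; no mapping to physical
  time or measured rate constants is attempted, so only orderings and
  regime structure — not absolute CV values — are meaningful.
* No mRNA/protein degradation, nucleosome dynamics or explicit TF
  binding; expression totals are undiluted accumulations over 150
  steps from a cold start.
* Sequence-only TATA-like classification over-calls sites relative to
  the binding-verified experimental definition.
* The squared size-correction is kept as the default for fidelity to
  the protocol despite its CV inflation; quantitative noise estimates
  should use `method="ratio"`.
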