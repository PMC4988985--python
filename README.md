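# pitsync

Synchrony analysis for pituitary gonadotrope networks imaged with calcium
indicators, plus the electrophysiological and promoter-level companions of
that analysis. The package is aimed at labs quantifying gap-junction-mediated
coordination in endocrine (or other compact) cell networks: it takes raw
fluorescence trace tables and ROI coordinates, and answers *how synchronous
is this network, over what distances, and does synchrony differ between two
genotypes or treatments?*

## What it computes

* **Trace normalization and responder calling** — relative fluorescence
  changes F\_i/F\_0, with F\_0 the per-cell mean of the first 50 frames;
  GnRH responders are cells whose ratio exceeds baseline mean + k·SD
  (default k = 3) for a sustained run after stimulus onset, classified as
  *biphasic* (rise then plateau/decay) or *oscillatory* (≥3 recurring peaks).
* **Pairwise synchrony** — Spearman rank correlation ρ between all
  responding cell pairs inside canonical half-open windows before
  (100–200 s), during (250–350 s) and after (500–600 s) stimulation, with
  sliding-window correlation matrices for heat maps and two-sided
  Mann–Whitney comparisons of ρ distributions between groups. ρ is the
  Pearson correlation of midranks, p from the t approximation on n−2 df.
* **Distance-resolved synchrony** — intercellular distances (centroid or
  membrane-to-membrane), OLS regression of positive ρ on distance, the
  between-group slope/intercept test
  t = (b₁−b₂)/√(SE₁²+SE₂²) on n₁+n₂−4 df (α = 0.001), and the short-range
  (<5 μm) Mann–Whitney comparison.
* **Electrical coupling** — the coupling coefficient
  CC = ΔV_follower/ΔV_injected from steady-state deflections of paired
  current-clamp sweeps (averaged over 10–60 sweeps), with SEM from per-sweep
  ratios and a bidirectional z-score coupling classification.
* **Promoter scanning** — a generic JASPAR PWM scan of a window upstream of
  a TSS, scoring sites as min-max-normalized log-odds percentages
  (100 × (S−S_min)/(S_max−S_min)) on both strands, positions reported in bp
  upstream of the TSS.
* **Synthetic ground truth** — a coupled/uncoupled gonadotrope network
  simulator (hard-core cell placement, biphasic/oscillatory evoked
  waveforms, distance-dependent gap-junction graph with diffusive signal
  mixing and timing entrainment, optional tonically coupled baseline
  fluctuations, log-normal + additive noise) and a paired-recording
  simulator, so the whole chain is validated with no external data.

## Worked example

```bash
python examples/simulate_and_compare_arms.py
```

```
window   n_coupled n_uncoupled median_c median_u  Mann-Whitney p
before        1733        2029    0.003    0.001  0.834
during        1733        2029    0.826    0.321  0
after         1733        2029    0.254    0.019  8.13e-254
```

Seven simulated slice experiments per arm, ~60 cells each, give ≈1700–2000
responder pairs per arm. Before stimulation both networks are at baseline:
median pairwise ρ ≈ 0 and the arms are indistinguishable (p = 0.83). During
GnRH application the gap-junction-coupled arm reaches a median ρ of 0.83
against 0.32 without coupling (p ≪ 0.001): coupling entrains the evoked
responses. `examples/distance_regression.py` continues the analysis — the
uncoupled arm's ρ-vs-distance slope (−0.00166/μm) is an order of magnitude
steeper than the coupled arm's (−0.00017/μm; comparison p = 1.9 × 10⁻¹⁹),
and with tonically coupled baseline fluctuations the <5 μm pairs differ in
all three windows. `examples/coupling_coefficient.py` recovers a true
coupling coefficient of 0.025 from noisy paired sweeps, and
`examples/promoter_scan.py` finds a planted estrogen-response-like element
725 bp upstream of the TSS at a 100% matching score.

A thin CLI wraps the same functions:

```bash
pitsync simulate --out wt --n-datasets 7 --coupled --seed 1 --label wt
pitsync simulate --out ko --n-datasets 7 --uncoupled --seed 2 --label ko
pitsync analyze --group-a wt/wt00 ... --group-b ko/ko00 ... --out run
pitsync ephys --sweeps sweeps.csv
pitsync scan-motifs --fasta promoter.fa --pwm er.jaspar --min-score 75
```

## Layout

```
src/pitsync/     simulate, traces, synchrony, distance, ephys, motifs, io,
                 pipeline, cli
examples/        narrative scripts, one per capability
tests/           pytest suite (unit, property and end-to-end tests)
docs/methods.md  model description, parameter defaults, limitations
```
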