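# strainprint

Model-based extraction of **activation time (AT)** and **contractility
(Con)** from myocardial strain traces, using parameter-space fingerprints.

Speckle-tracking echocardiography yields regional longitudinal strain
curves, but mapping them back to local tissue properties is an inverse
problem with strongly non-unique solutions: in conditions such as left
bundle branch block (LBBB), many (AT, Con) combinations produce almost the
same strain pattern. `strainprint` turns that ambiguity into signal. It is
aimed at researchers in computational cardiac physiology who want a small,
fully reproducible testbed for fingerprint-based parameter extraction.

## Method

1. **Forward model.** A lumped three-element Hill sarcomere — contractile
   element `Cs` in series with spring `Ks`, spring `Kp` in parallel — is
   driven by a fixed external wall tension `G(t)` (the patch is too small to
   affect global mechanics). Fiber strain is
   `E_f(t) = L_s(t) / L_s(t_mvc) − 1`, sampled every 2 ms.
2. **Scan.** The model is run over a 41 × 41 grid: AT ∈ [−100, 100] ms and
   Con ∈ [2, 202] % in 5-unit steps — 1,681 simulations.
3. **Fingerprints.** Pattern similarity is the windowed RMS difference
   `S(p,i) = √(Σ (E_p − E_i)² / N)` over the first two-thirds of systole.
   The *fingerprint* of a reference trace is the binary 41 × 41 image of all
   grid cells with `S ≤ 0.03` (the strain measurement error) — a blob whose
   shape encodes the local non-uniqueness of the inverse problem.
4. **Proximity map.** Each cell's intensity is the reciprocal of the mean
   Euclidean distance between the nonzero points of that cell's synthetic
   fingerprint and of the data fingerprint, scoring blob *shape and
   position* agreement.
5. **Extraction.** (AT, Con) mean ± SD are the intensity-weighted mass
   center of either image: the binary data fingerprint (simple cohort
   average) or the proximity map (shape-aware extraction).

## Worked example

```sh
strainprint demo --seed 3 --out demo
```

builds the library, generates six noisy LBBB-like pseudo-measurements
(early- to late-activated, near-uniform contractility), and runs both
extraction methods. Output (also written to `demo/results.csv`):

```
   config_digest source        method  at_mean_ms  at_sd_ms  con_mean_pct  con_sd_pct
db74d44e9de40024      1   fingerprint       -62.2      13.0         116.1        39.0
db74d44e9de40024      1 proximity_map       -18.3      55.1         107.5        55.6
db74d44e9de40024      2   fingerprint       -26.4      12.3          99.0        12.6
db74d44e9de40024      2 proximity_map        -9.9      52.8         103.1        53.5
db74d44e9de40024      3   fingerprint        -2.3      10.8         100.9        14.5
db74d44e9de40024      3 proximity_map        -0.8      52.3         103.4        53.2
db74d44e9de40024      4   fingerprint        -4.2      10.8         116.2        16.4
db74d44e9de40024      4 proximity_map        -1.6      52.1         109.3        53.4
db74d44e9de40024      5   fingerprint         7.9      12.1          84.1        13.1
db74d44e9de40024      5 proximity_map         3.1      52.7          96.9        53.4
db74d44e9de40024      6   fingerprint        21.2      11.3         106.6        18.1
db74d44e9de40024      6 proximity_map        8.1      52.8         105.6        53.5
```

Trace 1 was generated early-activated (AT = −60 ms): the cohort average
recovers −62.2 ms, and its negative initial strain slope is the
early-activation signature. The proximity-map results span a much narrower
AT and Con range with uniform, wide SDs: the shape-aware weighting spreads
mass over the whole parameter space, compressing extracted values toward
the grid center — see `docs/methods.md` for why, and for what each method
is good for. Per-trace fingerprints and proximity maps are written
alongside as CSV (+ optional PNG with `--png` on the single-trace
commands).

Other subcommands: `simulate` (one trace), `scan` (the 1,681-trace
library), `fingerprint`, `proximity`, `extract` — run
`strainprint <cmd> --help`.

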