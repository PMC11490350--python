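# Methods

## The forward model

The simulated tissue element is a three-element Hill sarcomere: a
contractile element in series with a linear spring `Ks` (the active
branch), in parallel with a linear spring `Kp` (passive tissue). The
element is a vanishingly small patch of the ventricular wall, so the wall
tension it experiences, `G(t)`, is prescribed and identical for every
simulation; changing the patch's own properties never feeds back on its
load. This isolates the effect of two local parameters:

* **AT (activation time, ms)** — delay between contractile activation and
  the onset of the external tension pulse. Negative = the patch activates
  before the wall loads it (early activation), positive = after (late).
* **Con (contractility, %)** — scaling of the contractile element's
  maximum isometric tension. 100 % is baseline; 2 % is an essentially
  passive patch; 202 % is maximal stimulation.

Mechanics. With `Lc` the contractile-element length and `Ls` the sarcomere
length, the force balance is algebraic in `Ls`:

    G(t) = Ks (Ls − Lc) + Kp (Ls − Ls_ref)
      ⇒  Ls = (G + Ks Lc + Kp Ls_ref) / (Ks + Kp)

and the contractile element follows first-order tension-imbalance dynamics
(a lumped force–velocity relation):

    dLc/dt = −visc (T_iso(t) − T_s),   T_s = Ks (Ls − Lc)
    T_iso(t) = (Con/100) · amp · a(t − t_onset − AT) · g(Lc)

`a(·)` is a smooth activation twitch: raised-cosine rise over
`twitch_rise_frac · twitch_duration`, raised-cosine decay over the rest.
The rise is deliberately faster than the decay (`twitch_rise_frac = 0.25`
of a 450 ms twitch): cardiac tension develops in ~100 ms and relaxes more
slowly, and — mechanistically important here — an early-activated patch
must already bear tension when the external pulse arrives, so that it
shortens first and its strain trace starts with a *negative* slope, while a
late-activated patch is stretched by the remote wall and starts *positive*.
A symmetric slow-rising twitch loses this signature, which is the main
qualitative fact about LBBB strain morphology the model must reproduce.

`g(Lc) = max(0, (Lc/Ls_ref − z)/(1 − z))` with `z = 0.5` is a linear
length-dependence of activation clipped at zero: tension capacity falls as
the element shortens and vanishes at half the reference length. This
produces the saturation that shapes the parameter space: at high Con extra
contractility buys little extra shortening (cohort blobs elongate along the
Con axis), while at very low Con the patch barely contracts and timing is
nearly unobservable (blobs elongate along the AT axis).

Strain is reported relative to mitral valve closure (MVC):
`E_f(t) = Ls(t)/Ls(t_mvc) − 1`, so every trace is exactly zero at the MVC
sample.

### External tension pulse

`G(t)` is a deterministic analytic pulse: diastolic baseline
`0.02 · G_peak`, smoothstep rise over 60 ms starting at `t_onset = 20` ms,
plateau at `G_peak = 1` (this defines the tension unit), raised-cosine
decay over 80 ms ending 50 ms after mitral valve opening. Default timing is
heart-failure-like: MVC at t = 0, MVO at 350 ms, cycle length 800 ms.

### Parameter values

The model is phenomenological; its constants are not measurements. They
were fixed once, during model design, to make the simulated strains
realistic in shape and scale:

| parameter | default | unit | role |
|---|---|---|---|
| `Ks` | 20 | tension/µm | series stiffness |
| `Kp` | 4  | tension/µm | passive stiffness; sets the ~+0.12 passive stretch at Con = 2 % |
| `Ls_ref` | 2.0 | µm | slack sarcomere length |
| `twitch_amp` | 3.0 | tension | peak isometric capacity at Con = 100 %; sets baseline peak shortening ≈ −0.12 |
| `twitch_duration` | 450 | ms | twitch length |
| `twitch_rise_frac` | 0.25 | – | rise/decay asymmetry (see above) |
| `visc` | 0.01 | µm/(ms·tension) | contraction speed; sets the ~25 ms response time |
| `length_dep_zero` | 0.5 | – | fraction of `Ls_ref` where active tension vanishes |

With these values the baseline cell (AT = 0, Con = 100 %) shortens to about
−0.12 strain, Con = 2 % gives pure passive stretch, and the cohort blobs
span tens of grid cells with the AT/Con elongation pattern described above.

### Numerics

Fixed-step explicit Euler on `Lc` with `dt_int = 0.5` ms sub-steps, output
every `dt_out = 2` ms. The dynamics are smooth and first-order with an
effective time constant ≫ dt, and halving `dt_int` changes the baseline
trace by < 2·10⁻⁴ strain (asserted in the tests at < 10⁻³). Integration
starts 250 ms before MVC from the exact passive equilibrium under the
baseline load, so even the earliest activation (AT = −100 ms, i.e. −80 ms
absolute) develops inside the integrated interval. The whole 1,681-cell
scan is one vectorised integration (the dynamics are elementwise across
cells), which both makes the scan take ~0.2 s and guarantees that a library
row is bitwise-identical to the corresponding single simulation.

## Inverse method

* **Similarity** of two patterns is the RMS difference over the analysis
  window: from the MVC sample to `t_mvc + (2/3)(t_mvo − t_mvc)`, floored to
  the 2 ms grid, endpoints inclusive (N = 117 samples with default timing).
  Only the first two-thirds of systole is used because speckle-tracking
  strain drifts late in the cycle.
* **Fingerprints** mark all cells with similarity ≤ 0.03, the realistic
  strain measurement error; the comparison is inclusive and the reference's
  own cell is kept in its cohort (its self-similarity is exactly 0).
  Components are counted with 8-connectivity — diagonally touching cells
  belong to one blob.
* **Proximity map**: `1 / max(mean point distance, 0.5)` per cell, where
  the mean runs over all pairs of nonzero points of the two masks in
  grid-index units (1 cell = 5 ms = 5 %, both axes weighted equally). The
  0.5-cell floor keeps the reciprocal finite when the data fingerprint
  coincides with a synthetic one; it is sub-resolution, so it never reorders
  distinct cells. Intensities are stored raw (no normalisation): the
  absolute level carries information — a uniformly dim map means no
  synthetic blob shape resembles the data blob.
* **Extraction** is the intensity-weighted mass center: means and
  *population* standard deviations (divide by Σw) of the physical AT/Con
  coordinates. Population moments are the natural reading of "mass center
  of image intensity"; no sample correction is applied. Results are
  reported to one decimal in ms and %.

Measured traces are linearly resampled onto the 2 ms grid and re-zeroed at
the MVC sample before comparison (strain is by definition relative to MVC).

## Synthetic pseudo-measurements

Real LBBB strain recordings with independently verified AT and Con do not
exist publicly, so the generator fabricates stand-ins from the model
itself: a simulated trace plus i.i.d. Gaussian noise per sample, re-zeroed
at MVC. The default noise sd of 0.01 strain units is one third of the 0.03
cohort threshold: the RMS deviation of a noisy trace from its own noiseless
simulation is ≈ 0.014 (MVC re-zeroing doubles the per-sample variance), so
the true cell stays inside its own cohort with high probability and
round-trip recovery is a meaningful test. The six-trace LBBB-like set uses
AT ∈ {−60, −25, −5, 0, 5, 20} ms at Con ∈ {95, 100, 105} % — an
early-activated septum through a late-activated lateral wall at
near-uniform contractility, which is the physiological expectation for a
pure conduction defect. An optional low-frequency sinusoidal wobble
(off by default) emulates model misfit for robustness studies.

What passing these tests does **not** show: fidelity to speckle-tracking
physics. The generator's noise is white and its "truth" comes from the same
model family used for inversion, so recovery results are best-case; real
measurements contain drift, spatial smoothing, and intermediate
shortening/stretching dynamics the model cannot produce.

## Known limitations

* **Center-of-grid bias of the proximity-map mass center.** The reciprocal
  mean distance decays only like 1/r away from the data blob, and in two
  dimensions the mass contributed at radius r is then roughly constant in
  r, so the far field of the 41 × 41 image carries most of the total
  intensity. The full-image mass center of such a map is therefore pulled
  strongly toward the grid centroid (AT = 0 ms, Con = 102 %): noiseless
  recovery errors reach tens of ms for cells near the grid edge, and the
  extracted AT/Con ranges across a set of traces are compressed two- to
  three-fold relative to the fingerprint route, with large, nearly uniform
  SDs. This is an intrinsic property of taking the global mass center of a
  raw reciprocal-distance image, not a calibration artifact — it persists
  with single-cell blobs. Near the grid center the two effects align and
  recovery is within one grid step. The package implements the map and its
  mass center exactly as defined and reports both methods side by side;
  interpret proximity-map means as shape-aware *scores* biased toward the
  prior middle of the scanned range, not as unbiased point estimates.
* The fingerprint route is unbiased only where the cohort blob is symmetric
  and fully inside the grid; edge cells and the elongated low-Con blobs
  shift its mass center by several cells.
* Absolute strain amplitudes are model-specific (the tension unit is
  arbitrary); all claims about real data are qualitative (slope signs,
  blob topology), not amplitude matches.
* The diastolic part of the cycle after MVO is simulated but unused: the
  analysis window ends at two-thirds of systole.

## Problem sizes

The test suite and `scripts/acceptance.py` use the full 1,681-cell scan
throughout (it is cheap); recovery statistics use 20 random interior cells
noiseless and 100 seeded noise trials at one cell; oracle-equivalence
checks use 200 random pairs each. The complete suite runs in well under a
minute.
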