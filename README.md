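# oriturn

Quantitative analysis of how fast a DNA-binding protein exchanges on its
chromosomal binding sites, built around the replication initiator **DnaA**,
whose residence at the origin of replication (*oriC*) is only a few seconds
and whose turnover sets the pace of replication-initiation control in
bacteria.  The package implements, as one tested pipeline, the three
complementary live-cell readouts used to measure such turnover:

* **FRAP** — single/double normalization of bleach-recovery traces,
  clustering of cells with similar intensity, least-squares fitting of the
  single-exponential recovery model

      f(t) = A · (1 − e^(−k_r t)),     t½ = ln 2 / k_r

  with the immobile (non-exchanging) fraction 1 − A from double-normalized
  fits, and Student's t comparison of half-times between strains;
* **single-molecule tracking** — apparent diffusion coefficients D* from a
  mean-weighted ensemble MSD fit (slope = 4 D* for free 2D motion); a
  zero-mean Gaussian mixture decomposition of the per-axis step-size
  distribution, σᵢ² = 2 dᵢ Δt, whose weights give the static and mobile
  population fractions; static-interval (trapping) detection within a
  230 nm radius with residence-time CDFs and Kolmogorov–Smirnov comparison;
  trajectory heat maps; and the analytic false-positive model
  p = 1 − e^(−r²/(4DΔt)), P(n) = Σ C(n−2, n−r) pʳ(1−p)ⁿ⁻ʳ for free
  molecules misclassified as static;
* **oscillation** — anti-correlation of whole-cell-normalized intensities
  of two cell regions, the signature of coordinated relocation of molecules
  between chromosome regions.

Because raw microscopy data of this kind are rarely deposited, the package
ships seeded simulators (`oriturn.simulate`) producing trajectories, FRAP
traces and oscillation traces with exactly the statistical structure the
analyses assume, so that every stage is testable against ground truth.

Intended users: microscopists and quantitative biologists with trajectory
tables (CSV from any spot tracker) or ROI intensity series who want
turnover numbers, and method developers who need a reference implementation
with a verifiable test surface.

## Worked example

Simulate a two-population track set (20% static at d = 0.027 µm²/s, 80%
mobile at 0.51 µm²/s, 41 ms frames, photobleaching-limited track lengths of
mean 5.7 frames) and analyze it:

```sh
$ cat mix.yaml
frame_interval: 0.041
components:
  - [0.027, 0.2]
  - [0.51, 0.8]
track_length_law: {distribution: geometric, mean: 5.7, minimum: 2}

$ oriturn simulate tracks --config mix.yaml --seed 7 --n-tracks 2400 --out tracks.csv
wrote 2400 tracks to tracks.csv

$ oriturn smt mixture --in tracks.csv --out mix.json
d = 0.02397 um^2/s, weight = 18.4%
d = 0.506 um^2/s, weight = 81.6%

$ oriturn smt msd --in tracks.csv --out msd.json
D* = 0.4347 +/- 0.012 um^2/s (2400 tracks, 4 lags)

$ oriturn smt residence --in tracks.csv --out residence.json
1641 static intervals, mean residence 176.5 ms

$ oriturn smt fpr --d 0.51 --in tracks.csv
analytic: p = 0.4687, rate = 14.07%
```

The mixture fit recovers the generating populations (18.4/81.6% vs the true
20/80%, component coefficients 0.024/0.51 vs 0.027/0.51 µm²/s).  The
whole-population MSD coefficient (0.43 µm²/s) sits between the two
components — it averages over both populations and is a different estimator
from the mobile-component d, so the two are reported independently.  The
residence command reports trapping events of ≥ 3 frames within 230 nm
(mean 176 ms here, uncorrected for the ≥ 3-frame threshold), and `smt fpr`
gives the analytic probability that a free molecule diffusing at
0.51 µm²/s would nonetheless be counted as static.

The same pattern works for FRAP (`oriturn simulate frap`, `oriturn frap
fit --mode single|double`, `oriturn frap compare`) and oscillation traces
(`oriturn simulate oscillation`, `oriturn osc correlate`).  Every simulator
writes a `*.params.json` sidecar with its generating parameters.  All
functionality is equally available as a library (`import oriturn`).

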