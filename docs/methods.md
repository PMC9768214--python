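# Methods

## Scope and model

`neurostates` implements a four-stage analysis of multichannel scalp EEG
under distinct mental states: (1) preprocessing and band splitting, (2)
phase-lag-index (PLI) connectivity, (3) proportional-threshold binary
graphs with small-world metrics normalized by degree-preserving random
references, (4) two-group statistics with effect sizes, ROI aggregation,
and subjective-scale state labeling. Because no public recordings
accompany the protocol it targets, the package ships a first-class
synthetic-EEG generator whose six state profiles encode the qualitative
network contrasts the analysis is meant to expose; every stage is
validated against that ground truth.

## Signal processing

* **Bands.** Low = 4.0-13.0 Hz (theta + alpha analyzed jointly), high =
  14.0-30.0 Hz (beta). Delta is excluded by design: it dominates only in
  sleep, deep anesthesia, and pathological states. Band edges are
  configurable (`BandDefinition`); both must lie below Nyquist.
* **Filters.** All filtering is a 4th-order Butterworth applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase — any group delay
  would corrupt a lag-based connectivity measure. Preprocessing removes
  the per-channel mean and restricts to 1-45 Hz (and removes the tiny
  offset the filter transients reintroduce). Ocular-artifact removal is
  out of scope: it needs reference channels or ICA, and the synthetic
  data are artifact-free.
* **Phase.** Instantaneous phase and amplitude are the angle and modulus
  of the analytic signal (`scipy.signal.hilbert`). The first and last
  second of every record are flagged and excluded downstream — the
  analytic transform is circular and distorts the record edges.
* **Epochs.** PLI is estimated per epoch and averaged. The default epoch
  is 8 s: the PLI estimator takes an absolute value, so uncoupled
  narrowband channels have a positive noise floor that shrinks with the
  number of effectively independent phase samples per epoch. At 8 s the
  floor for 4-13 Hz white-noise channels is about 0.08 (below the 0.1
  the estimator contract promises at 60 s); at 4 s it would be about
  0.11. Recordings shorter than one epoch fall back to a single epoch
  spanning the retained samples. Generic epoching (`epoch`) defaults to
  4 s windows with no overlap.

## Connectivity

`PLI = |<sign(Delta phi)>|` with the phase difference wrapped to
(-pi, pi] before the sign; `sign(0) = 0`, which makes self-PLI exactly 0
and renders the estimator blind to zero-lag (volume-conducted) coupling.
The vectorized path evaluates `sign(sin(Delta phi))` via the cross
product `sin(a)cos(b) - cos(a)sin(b)`, identical to the wrapped sign
everywhere except the measure-zero point `Delta phi = pi`. Epoch-mean
PLI (not pooled samples) is the default; explicit epoch index sets are
accepted. Matrices are symmetric, zero-diagonal, entries in [0, 1].

## Graphs and small-world metrics

* **Thresholding.** At sparsity `s`, the `round(s * N(N-1)/2)` strongest
  off-diagonal weights become edges (round-half-up; 5% of a 30-node
  matrix keeps 22 edges). Ties at the cutoff break by lexicographic
  channel-pair order, so graphs are deterministic and, for tie-free
  weights, nested across the grid.
* **Path length.** The printed definition of `L` is an arithmetic mean,
  but disconnected graphs — the rule rather than the exception at 5%
  sparsity — would make it infinite. The harmonic reading
  `L = N(N-1) / sum(1/L_ij)` (disconnected pairs contribute 0, so
  `L = 1/E_g`) is the default; the arithmetic mean over connected pairs
  is available via `method="arithmetic"`. This choice is flagged, not
  silently resolved.
* **Conventions.** `C_i = 0` and `NE_loc = 0` for nodes of degree < 2
  (standard convention). `E_g` is the mean inverse shortest-path length
  over ordered pairs; `NE_loc(i)` is the global efficiency of the
  subgraph induced on i's neighbors.
* **Random reference.** Each of `n_realizations` (default 20)
  realizations applies 10x|E| successful Maslov-Sneppen double-edge
  swaps, preserving the degree sequence; `C_random`, `L_random` are
  means over realizations. A graph admitting no valid swap falls back to
  an Erdos-Renyi graph with matched N and |E| (logged). Very sparse
  graphs can yield a triangle-free batch (`C_random = 0`, leaving
  `gamma` undefined); then additional batches are drawn
  deterministically up to 10x the requested count, and as a last resort
  `C_random` takes the configuration-model expectation
  `(<k^2>-<k>)^2 / (N<k>^3)`. All randomness is seeded.
* **Sweep.** Default grid 5-40% in 5% steps (8 points). `gamma`,
  `lambda`, `sigma` are computed per sparsity and then averaged (not
  recomputed from range-averaged C and L); per-node vectors average
  element-wise. At 5% sparsity on 30 nodes, `sigma` is intrinsically
  heavy-tailed — both C and `C_random` are ratios of near-zero triangle
  counts — so single-subject range averages carry occasional spikes;
  group means at n = 13 remain well behaved.

## Synthetic generator

Each band carries four unit-power narrowband Gaussian *drivers*, one per
channel-pair class: the left hemispheric ROI {F3,F7,FC1,FC5,C3,T7}, the
mirror right ROI, a fronto-occipital group (frontal/occipital channels
outside those ROIs: Fp1, Fp2, Fz and the occipital row), and a global
background shared by all 30 channels. The classes partition all channel
pairs, so each class's stated coupling is exactly the locking its pairs
exhibit. A member channel receives a driver rotated by a fixed
per-channel analytic phase offset; two channels sharing a driver thus
hold a constant nonzero phase lag — the asymmetric phase-difference
signature PLI detects — while zero-lag leakage contributes nothing.
Offsets are golden-angle sequences assigned by rank within each class
group with a per-group shift; the left and right ROIs therefore see
identical within-class lag multisets and respond identically to equal
coupling, so hemispheric contrasts reflect coupling strength, never
offset luck.

Profile couplings are *effective pair locking* values in [0, 1]; a
specific class's driver weight is derived by subtracting the shared
global background in quadrature (`u = sqrt(w^2 - w_g^2)`, clipped at 0),
and the remaining channel variance is filled with independent
narrowband noise. Bands mix at relative amplitudes 1.0 (low) and 0.6
(high) at a 20 uV scale, plus broadband white noise of relative
amplitude `noise_sd`.

The six profiles encode the target contrasts: fatigue floods the low
band with near-uniform strong coupling (density rises sharply; the
clustering advantage over a degree-matched random graph erodes, so
`gamma` and `sigma` fall) and carries extra broadband noise; attentive
strengthens fronto-occipital coupling; inattentive dilutes structure
with global coupling and noise; positive/negative tilt the dense ROI to
the right/left hemisphere, the negative state with more unstructured
coupling. Couplings were chosen so that, at 60 s and 250 Hz, the
downstream PLI ranks the four pair classes in each profile's stated
order (rank correlation 1.0 across validation seeds), the fatigue-rest
low-band density gap exceeds 0.1, and the hemispheric asymmetries
recover in essentially every seed. Magnitudes are package choices — the
study protocol reports its contrasts only qualitatively (denser/sparser,
higher/lower).

What the generator does **not** emulate: volume conduction and field
spread (PLI is blind to them by construction, so simulated zero-lag
leakage would be invisible anyway), 1/f broadband structure beyond the
two analysis bands, artifacts (ocular, muscle, line noise),
non-stationarity within a recording, and between-subject variability
beyond independent noise realizations (cohort subjects share a profile
and differ only by seed, so group variances are small and effect sizes
for real contrasts are large). Passing tests therefore demonstrate that
the chain recovers known phase-coupling structure and controls false
positives under the null — not that it handles artifact-laden clinical
recordings.

## Statistics

Pooled-variance Student's t (df = n_a + n_b - 2) is the default, Welch
behind a flag; two groups with zero variance and equal means return
(t=0, p=1), zero variance with unequal means is rejected. Cohen's d uses
the n-1-weighted pooled SD; its sign follows mean_a - mean_b. No
multiple-testing correction by default (each metric's raw p is
reported); a Bonferroni option exists. Tests are unpaired; pairing is
out of scope. ROI aggregation is the arithmetic mean of nodal values
over lobe sets or the hemispheric ROI sets.

Scale labeling evaluates the five rule rows in fixed order (attentive,
inattentive, fatigue, positive, negative); "/" entries match any grade,
">= medium" is an inclusive ordinal threshold on the five-grade scale,
the first match wins, multi-matches are logged, and vectors matching no
row return "unclassified". The mapping is total and deterministic over
all 5^6 = 15,625 grade vectors (exhaustively tested).

## Numerical and reproducibility choices

* Every stochastic operation takes an explicit seed; cohorts derive
  per-subject seeds from a master seed, and pipeline re-runs are
  byte-identical.
* Hot loops (all-pairs BFS, neighbor-subgraph efficiency, PLI sign
  counting, edge rewiring) are numba-compiled; the BFS agrees with a
  Floyd-Warshall oracle to machine precision.
* Monte-Carlo validation sizes are chosen for a single-CPU desk run: the
  null-calibration suite uses 200 repetitions of 13-vs-13 cohorts at
  20 s per recording with 5 random-reference realizations (the null
  rejection rate does not depend on the precision of the shared sigma
  normalization); contrast-recovery uses 20 cohort seeds at the same
  scale. Production defaults are 60 s and 20 realizations.
* CSV recordings store float32-precision samples (microvolts) with a
  JSON sidecar for the sampling rate and labels; EDF input is read via
  mne when installed. There is no EDF writer dependency, so generated
  cohorts are always written as CSV + sidecar.

## Known limitations

* `sigma` at the sparse end of the grid is noisy for weakly structured
  connectivity (ratio of small clustering values); interpret per-subject
  range averages with that in mind.
* The positive-vs-negative contrast is expressed primarily in the
  hemispheric NE_loc balance; the accompanying sigma difference is small
  at desk scale and not reliably resolved at 20 s per subject.
* The harmonic path length equals 1/E_g, so L and E_g are not
  independent observables under the default convention.
* Proportional thresholding fixes edge count per sparsity: condition
  differences in overall PLI level appear as differences in *which*
  edges survive (topology), not in density of the binary graph.
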