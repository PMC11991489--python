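# Methods

This note documents the models the package implements, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions made where the design was
genuinely open.

## Study layout and preprocessing

A recording is a channels × samples matrix in microvolts with 10-10 scalp
labels, two mastoid references (M1, M2) and one bipolar biceps EMG channel
(`EMG_L`/`EMG_R`).  The study design is subjects × sleep condition
{good, poor} × motor state {rest, left contraction, right contraction}.

The EEG cleaning chain is: band-pass 1–100 Hz → band-stop 48–52 and
98–102 Hz → resample to 500 Hz → subtract the M1/M2 mean from every EEG
channel → cut into 2 s epochs → reject epochs.  The EMG chain is a 20–150 Hz
band-pass applied as a cascade (implemented as one zero-phase pass with
doubled order, which has the same magnitude response), then resampling and
epoching.  All filters are 4th-order Butterworth run forward–backward
(`sosfiltfilt`): zero phase distortion is required because instantaneous
phase feeds the PLV, and a causal filter would bias it.  Notches are
specified as band-stop *ranges* rather than Q-factor notches so the stop
bands are exactly the stated 48–52/98–102 Hz intervals.

Manual epoch vetting is replaced by a deterministic rule: drop an epoch when
any sample exceeds 150 µV in magnitude or any channel's RMS is more than 5
SDs from that channel's mean RMS across epochs.  Both thresholds are
config-exposed; independent component analysis is deliberately out of scope.

## EMG fatigue indices

Per epoch and band (20–100, 100–150 Hz): RMS of the band-filtered time
signal; MPF = ∫f·P df / ∫P df and MF = the smallest grid frequency whose
cumulative band power reaches half the band total, both on a Welch spectrum
(1 s Hann windows, 50 % overlap — ≈1 Hz resolution, the surface-EMG
default).  The left-continuous MF tie-break makes the estimate deterministic
on a discrete grid.  Features are computed per epoch and aggregated to
subject level afterwards, so both granularities are available in the table.

## PLV connectivity

PLV between two band-limited signals is the modulus of the time-averaged
unit phasor of their Hilbert phase difference.  Estimation is
epoch-then-average: phases are extracted per 2 s epoch, the PLV is computed
within each epoch over samples and averaged across epochs — concatenating
epochs would put phase discontinuities at the seams.  ROI values are means
over all cross-ROI channel pairs.

The 13 ROIs are sensorimotor Brodmann areas (no right BA3 — absent from the
scout template this layout mirrors).  Source modelling is replaced by a
sensor-space proxy: each BA maps to its nearest 10-10 channels
(BA1/2/3→C3|C4+CP3|CP4, BA4→C3|C4+C1|C2, BA5→CP1|CP2+CPz, BA6→FC3|FC4+FCz,
BA8→F3|F4+AF3|AF4, mirrored).  The map is data (editable JSON), because no
verifiable scout-to-channel table exists without subject anatomy; all
synthetic validation therefore targets recovery of *injected* coupling, not
any particular empirical matrix.  Band edges follow the conventional
1–4/4–8/8–13/13–30 partition with γ1 30–60 and γ2 60–100 Hz.

## Graph metrics

Weighted PLV matrices are binarised by sparsity: the strongest
round(s·N(N−1)/2) off-diagonal weights become edges, with a deterministic
(weight desc, row, col) tie-break.  The analysis range is s = 0.22–0.29 in
steps of 0.01; per-level values and the across-level arithmetic mean are
both reported (whether to analyse one level or the mean is genuinely open;
the mean is the package's default summary).

On the binary graph: binary Watts–Strogatz clustering C; characteristic path
length L over *connected* ordered pairs (with the disconnection recorded);
E_g with zero contribution from disconnected pairs (the only convention the
1/d form admits); E_loc as the mean over nodes of Σ_{j,h∈N_i} (1/d_jh) /
(k_i(k_i−1)) with d taken inside the neighbour subgraph and degree < 2
contributing 0.  σ = (C/C_rand)/(L/L_rand) against an ensemble of
degree-preserving Maslov–Sneppen rewirings (100×E attempted swaps per null;
1000 nulls by default, config-exposed; the test suite uses 10–100 for
speed).  Shortest paths use scipy's C-level BFS; all metrics are verified
against exhaustive pure-python BFS oracles and networkx on every graph size
the analysis uses.

## Network-based statistic

Edges are tested with a paired t-test; edges with two-sided p < 0.05 form
the suprathreshold set.  Components are formed **per contrast direction**
(increases and decreases connected separately): a "component" mixing
opposite-signed effects is not a coherent finding, and on a 13-node network
sign-mixed noise edges connect so often that the null max-component-size
distribution would otherwise swamp any 5-edge effect.  The component
statistic is extent (edge count) with the summed |t| as a lexicographic
tie-breaker — the integer extent alone is so discrete at this scale that the
permutation test would be badly conservative (empirical family-wise rate
~0.01 instead of 0.05).

The null is the largest component over both directions under per-subject
sign flips of the difference matrices (the exchangeability unit of a matched
design), with p = (1 + #{null ≥ observed}) / (n_perm + 1); 2000 permutations
by default.  Calibration: on 200 independent null replicates (12 subjects,
13×13, 500 permutations) the family-wise significant-component rate is
within the binomial 95 % CI of 0.05, and a 5-edge injected component is
recovered (≥ 4/5 edges) in ≥ 90 % of power replicates.

Outlier handling for scalar endpoints replaces values with |z| > 3 by the
mean of the unflagged values (one documented reading of "sequential means";
the replacement is idempotent).  Scalar contrasts use paired t, Wilcoxon or
Friedman tests from scipy; BH-FDR comes from statsmodels.

## MVAR and partial directed coherence

The joint (C3, C4, EMG) series — EMG resampled to the common 500 Hz — is
modelled as x_t = Σ_k A_k x_{t−k} + e_t, fitted by OLS on the stacked lag
regression with BIC order selection (max order 20 by default).  Stability is
verified via the companion-matrix spectral radius.  Because the cleaned
series is spectrally hollow (band-pass plus notches leave near-empty bands),
high-order fits sit close to the unit circle; a small white measurement-noise
floor (5 % of each channel's SD, seeded, config-exposed) is added before
fitting to keep the regression well-conditioned and the fits stable.

PDC is computed on a 1–100 Hz grid (0.5 Hz steps) in two variants.  The
default, `H`, normalises the squared transfer function |H_ij(f)|² by its
column sum (per-source columns then sum to exactly 1 at every frequency);
note that an H-based quantity is conventionally the *DTF*, but this
normalisation is common in applied corticomuscular work under the PDC name —
the textbook Ā-based PDC is exposed as variant `Abar` for cross-checking.
The two agree on uncoupled systems and differ on coupled ones; tests cover
both.  γ2 is 60–100 Hz.

Band means over β/γ1/γ2 are contrasted between conditions per directed pair
with paired t-tests and BH-FDR over the 18-test family, reporting the
direction of the mean change.

## Synthetic data: what it emulates, and what it does not

* `gen_phase_coupled_pair` draws iid von Mises(0, κ) phase differences on a
  narrow-band carrier; the population PLV is exactly I₁(κ)/I₀(κ).  Because
  iid per-sample jitter is broadband, Hilbert extraction cannot recover
  those phases from the real-valued signal; the generator therefore also
  returns the ground-truth phase series, and the Bessel-ratio oracle is
  checked on them (the Hilbert path is validated separately on smooth
  signals).
* `gen_study` builds the full design: 28 EEG + M1/M2 + one EMG channel at
  1000 Hz.  Alpha-band coupling is implanted with *slow* (0.5–3 Hz band)
  Gaussian phase jitter on a shared 10 Hz carrier — for Gaussian jitter the
  pairwise PLV factor is exp(−(σ_x² + σ_y²)/2), and the jitter is
  narrow-band enough for the filter→Hilbert chain to track.  Injected
  effects: (i) extra jitter (σ = 1.0 rad) on the right-hemisphere target
  channels in deprived rest, lowering interhemispheric PLV; (ii) the EMG
  spectral centroid drops from 95 to 82 Hz for the deprived left
  contraction (between-subject SD 2 Hz); (iii) a 3-channel MVAR(2) trio
  resonant at 45 Hz couples C4↔EMG with lag-1 coefficients 0.02/0.25 that
  swap between conditions (the loop gain — the product of the two
  directions — must stay small or the near-resonant pair destabilises).
  Effect magnitudes were set by the package's own calibration so that the
  scaled-down 12-subject study detects all three effects; all are
  config-exposed (`StudyEffects`), and `StudyEffects.zeroed()` gives the
  null study for calibration runs.
* Not emulated: volume conduction, ocular/cardiac artifacts, non-stationary
  fatigue dynamics within a contraction, electrode impedance drift, and any
  anatomy-based source geometry.  Passing tests therefore demonstrate that
  the *pipeline* recovers known effects through the full filtering and
  estimation chain — not that real recordings would show these effects.

## Problem sizes

Defaults follow the full study design (35 subjects, 180 s recordings, 1000
null networks, 2000 permutations).  The test suite and the analysis scripts
run the package's desk-scale configuration: 12 subjects, 30 s recordings,
500–1000 permutations, 10–100 graph nulls — sizes chosen so the whole suite
runs in minutes while keeping every estimator in its working regime
(≥ 15 epochs per PLV matrix, ≥ 15 000 samples per MVAR fit).

## Degenerate inputs and other numerical choices

* EDF I/O is a minimal 16-bit codec (1 s records, physical range padded so
  constant channels stay encodable; the true sample count is stored in a
  reserved header field so partial final records round-trip).  Reading is
  cross-checked against MNE's independent EDF reader in the tests.
* A constant channel has no defined instantaneous phase and is refused.
* A zero-variance nonzero paired difference is treated as an arbitrarily
  large |t| rather than an error inside the NBS edge tests.
* Thresholding that would yield zero edges, empty frequency bands, all
  epochs rejected, and unstable simulation requests all raise typed errors
  naming the offending quantity.
* All randomness flows from one master seed through named per-stage
  substreams (`RunConfig.stage_seed`), so reruns are bit-reproducible.

## Known limitations

* The ROI map is a sensor-space proxy; its PLV matrices are not comparable
  to source-space scout values from anatomical pipelines.
* The H-based default "PDC" is a DTF-style normalisation (see above); users
  comparing against other toolboxes should select the `Abar` variant.
* PLV is not volume-conduction-robust (no imaginary-part or wPLI variant).
* The NBS implements the extent statistic only, for matched two-condition
  designs; k-group designs are handled by scalar Friedman tests, not by a
  network statistic.
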