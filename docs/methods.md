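# Methods

`opmbeta` implements a complete analysis chain for somatosensory
OPM-MEG (optically pumped magnetometer magnetoencephalography)
beta-oscillation studies — preprocessing, LCMV beamforming, Hilbert-envelope
metrics, orthogonalized amplitude-envelope connectomics and a three-state
time-delay-embedded hidden Markov model (TDE-HMM) for pan-spectral burst
detection — coupled to a forward-simulated cohort generator in which every
effect the analysis is supposed to measure is planted with known
parameters.  Validation is by parameter recovery: the pipeline is run on
simulated cohorts and its estimates are compared with the generator's
ground truth.

## The synthetic world

**Geometry.** The head is a homogeneous conducting sphere (origin at the
centre, radius 0.09 m).  Up to 64 triaxial sensors (192 channels) sit
quasi-uniformly (Fibonacci placement) on a sphere 15 mm outside the scalp;
each sensor measures the field along one radial and two tangential
orthonormal axes.  Magnetic fields are computed with the closed-form
expression for a current dipole in a spherically symmetric conductor, which
is exact, fast, and shared by simulation and inversion.  This replaces a
realistic single-shell cortical mesh deliberately: the synthetic study
tests the analysis, not the forward model, and the sphere makes radial
sources exactly silent — which the lead fields respect by restricting each
voxel's source space to the two tangential orientations.

**Paradigm.** Alternating index/little-finger stimulation: 0.5 s of
stimulation every 3.5 s, 42 trials per finger by default (the full task is
294 s plus a 1 s lead-in).  Epochs are cut at [−0.5, 3.0) s around each
onset with a half-open sample convention (1050 samples at 300 Hz).

**The sensorimotor burst source.** A tangential dipole at
(−45, 5, 40) mm ("left sensorimotor") emits:

- *Pan-spectral bursts*: a non-overlapping point process of burst onsets;
  each burst is Tukey-windowed coloured noise whose power spectrum on
  1–48 Hz follows f^(−tilt) plus a fixed Gaussian alpha bump at 9 Hz,
  scaled to in-burst RMS = burst amplitude.
- *Burst suppression*: within 0–0.8 s after each stimulus the burst onset
  rate drops by the modulation depth d ∈ [0, 1].  Candidate events are
  drawn at a dead-time-compensated rate so empirical rates match the
  nominal ones exactly in the stationary case.
- *A phase-locked M50*: a Gaussian bump (peak 50 ms post-onset, σ=10 ms)
  added identically on every trial.
- *Heterogeneous background*: ongoing activity alternating (≈0.7 s
  episodes) between an alpha-band (8–10 Hz) texture and a weaker
  theta-band (3–6 Hz) texture, plus a white floor.  This matters: a
  homogeneous background would be modelled by a single HMM state whose
  occupancy mirrors the entire burst modulation with opposite sign, and
  the "most task-modulated state" selection rule would then pick the
  background rather than the burst state.  Real ongoing activity is
  heterogeneous in exactly this sense.

Shipped burst statistics: 1.8 bursts/s, mean duration 0.2 s (≈36%
occupancy), burst amplitude 1.0, floor SD 0.15, alpha texture RMS 0.5.
The occupancy is set so the trial-averaged burst probability sits in the
0.2–0.5 range that characterises sensorimotor burst analyses; at a few
percent occupancy the binarized occupancy statistics of one-minute
recordings are too noisy to recover anything.

**Cohort trends.** Ages are evenly spaced on [2, 34] years; per-subject
parameters are drawn from linear age trends with Gaussian scatter
(per-subject seed = master seed + subject index):

| parameter | intercept | slope / year | scatter | note |
|---|---|---|---|---|
| modulation depth d | 0.10 | +0.022 | 0.05 | clipped to [0, 0.95] |
| spectral tilt | 1.4 | −0.025 | 0.05 | low frequencies fall, high rise with age |
| alpha bump weight | 0.5 | 0 | — | age-invariant by design |
| burst amplitude | 1.0 | 0 | — | age-invariant by design |
| M50 amplitude | 0.5 | 0 | — | |
| frontal node degree | 0.26 | +0.27 | — | target for the connectome |
| occipital node degree | 2.92 | +0.10 | — | children: strongest posterior coupling |
| other regions | 1.50 | +0.18 | — | |

**The 78-region network.** A deterministic Fibonacci parcellation on an
inner sphere (radius 0.06 m) with frontal/occipital/other tags by the
anterior-posterior coordinate.  Each region emits a constant-amplitude
frequency-modulated carrier wandering inside the beta band, amplitude
modulated by a smooth (≤1 Hz) positive envelope; envelopes are correlated
Gaussians whose correlation matrix is built from the per-region degree
targets above (projected to the nearest correlation matrix), so the
planted pairwise envelope correlation is recoverable by AEC.  Region
sources are projected at RMS 0.12 source units — well below the burst
source, as task-relevant sensorimotor beta dominates its own cortex.

**Sensor-space nuisance.** White noise (SD set so the burst source's best
channel has a 3:1 RMS ratio), 50/100/150 Hz line sinusoids with
per-channel gains, a slowly varying homogeneous field (the exact subspace
homogeneous field correction removes, at 5× the white SD), one flat and
one broken (×10 noise) channel, and two high-variance trials per subject.

## The analysis chain

1. **Bad channels** — flat channels (zero variance) and channels whose
   mean log-PSD (1–150 Hz) exceeds 3 SD across channels.
2. **Filters** — zero-phase notches (50/100/150 Hz, Q=30) and a 1–150 Hz
   4th-order Butterworth band-pass; at 300 Hz sampling the upper edge is
   clipped to 135 Hz and recorded in the provenance log.
3. **Homogeneous field correction** — projection of the data out of the
   3-dimensional column space of the channel-orientation matrix; exact
   for a spatially uniform interference field, idempotent.
4. **Epoching and trial rejection** — one epoch per onset; trials whose
   channel-mean variance strictly exceeds mean + 3 sample SDs (single
   pass) are masked.
5. **Beamforming** — data covariance over all kept data, Tikhonov
   regularised with 5% of the largest eigenvalue.  Per voxel, the LCMV
   weights w = C⁻¹Lη / (ηᵀLᵀC⁻¹Lη) pass unit gain; the orientation η is
   the tangential direction maximising output power (the generalized
   eigenvector with the smallest projected-precision eigenvalue), sign
   fixed so the largest component is positive.  Pseudo-T maps contrast
   beta-band (13–30 Hz) window power, T = (P_a − P_c)/(P_a + P_c), active
   0.3–0.8 s vs control 2.5–3.0 s, on a 10 mm whole-sphere grid plus a
   4 mm refined grid over a 15 mm sensorimotor region of interest (the
   synthetic analogue of restricting the peak search to left sensorimotor
   cortex anatomically; configurable, and both grids are coarser than the
   4 mm / 1 mm pair a full-scale study would use).  The virtual electrode
   is the broadband-covariance projection at the refined peak.
6. **Envelope metrics** — Hilbert envelopes are computed on the
   *concatenated* kept-trial series (contiguous epochs), because the
   baseline window (2.5–3 s) abuts the epoch edge where per-epoch filter
   and Hilbert transients would bias it.  TFS: 4 Hz-wide bands centred
   every 1 Hz from 3 to 46 Hz, fractional change from baseline.
   βmod = (βPost − βStim)/βBaseline over 0.3–0.8 / 1.0–1.5 / 2.5–3.0 s
   window means of the trial-averaged 13–30 Hz envelope.  M50 is the
   signed trial-averaged 4–40 Hz value at the sample nearest 50 ms (no
   peak search; a beamformer virtual electrode has an arbitrary sign, so
   group analyses of M50 should use magnitudes or a sign convention).
7. **Connectivity** — beamformer time courses at the 78 centroids,
   pairwise orthogonalization in both directions, Pearson correlation of
   the 13–30 Hz Hilbert envelopes, averaged over directions.  Because the
   Hilbert transform is linear, the residual envelope is |Z_y − βZ_x|,
   and the band-limited analytic signals are decimated ×4 (no content
   above the reduced Nyquist) before the pairwise step.  A fully leaked
   copy has a numerically zero residual envelope and maps to AEC 0 with
   a warning.  Global connectivity = mean off-diagonal entry; node degree
   = column sums.
8. **Bursts** — the virtual electrode is resampled to 100 Hz per epoch,
   band-passed 1–48 Hz, standardized and lag-embedded.  The pipeline
   default is ±5 lags (±50 ms): at realistic burst rates the ±70 ms
   window turns burst-boundary mixture rows into ~25% of all samples,
   which captures an entire HMM state and defeats burst-state selection;
   ±50 ms leaves the background split across two states.  The 3-state
   zero-mean Gaussian HMM (states distinguished by covariance over the
   embedded space) is fitted by Baum–Welch EM with scaled forward–backward
   recursions, best of 3 restarts (restart seeds derived from the master
   seed), convergence at relative log-likelihood change < 1e−6 or the
   iteration cap.  Posteriors are binarized at a strict 2/3 threshold
   (exactly 2/3 maps to off; at most one state on per sample).  The burst
   state maximises |mean occupancy in 1.0–1.5 s − mean occupancy in
   0.3–0.8 s| (ties to the lowest index); ΔP is the signed difference.
   State spectra are occupancy-weighted multitaper PSDs (2 s windows,
   time-bandwidth 4, 7 Slepian tapers); burst amplitude is the mean
   1–48 Hz analytic-signal magnitude during burst-on samples.
9. **Group statistics** — Pearson fits (two-sided t-test p, n−2 df,
   sample-SD conventions), within-group (child < 18 y / adult) z-scores
   for the cross-metric association, per-region degree-vs-age slopes, and
   per-frequency burst-PSD-vs-age correlations flagged at p < 0.01
   uncorrected (Benjamini–Hochberg optional).  For the spectral trend the
   burst-state PSDs are normalised to unit integral first, so that the
   per-subject amplitude scale (which depends on the unit-gain weights at
   the chosen voxel) drops out and the planted *shape* trend is what is
   correlated with age.

## Validation design and problem sizes

The default validation cohort is 30 subjects at 300 Hz with the full
42-trials-per-finger paradigm (~295 s/subject): binarized occupancy
statistics need the full trial count for stable per-subject ΔP.  The
replicate (seed-fraction) checks for alpha stability, the burst-amplitude
age null and the frontal/occipital degree ordering run 10 replicate
cohorts at reduced size (10–12 subjects, shorter recordings) at the
source/region level with projection-level noise, which isolates those
statistics from the (separately validated) beamformer stage.  Dipole
localization is validated on a continuous beta source whose power drops
×0.25 during active windows (sensor SNR 1, 64 sensors, 4 mm grid); the
burst-probability depth grid (depths 0/0.25/0.5) runs 7 fixed-depth
subjects per depth through the full sensor-level chain and summarises
each depth by its median ΔP;
two-regime variance switching validates the HMM against a brute-force
path-enumeration oracle and label-aligned recovery; LCMV weights are
checked against a constrained-quadratic-program (KKT) oracle.

## Numerical choices and degenerate inputs

- Covariances are inverted via Cholesky of the regularised matrix.
- Voxels whose tangential lead field is numerically zero (e.g. the sphere
  origin) are flagged unlocalizable and skipped.
- HMM covariance collapse triggers escalating diagonal loading with a
  logged warning.
- The EM log-likelihood is asserted non-decreasing in the tests.
- AEC of a zero-variance envelope returns 0 with a warning, keeping
  cohort matrices complete.
- All CSV outputs use a fixed float format; re-running a configuration
  with the same seed reproduces byte-identical tables.

## What passing tests do and do not show

The generator emulates the statistical structure the analysis assumes —
linear age trends, spectrally structured bursts, envelope-correlated
networks, uniform-field interference — but not real physiology: no
blink/cardiac artifacts, no head movement, a spherical conductor rather
than cortical anatomy, stationary backgrounds, and a single task-relevant
source at a site shared across subjects.  Parameter recovery therefore
demonstrates internal consistency of the method chain (what was planted
is what is measured, through the full sensor-level round trip), not
performance on real recordings.  Known limitations: burst-state selection
by maximal occupancy modulation mis-selects an anticorrelated background
state in roughly one cohort subject in ten (the displaced-occupancy
mirror is intrinsic to a 3-state decomposition); localization degrades
for subjects with weak planted modulation, exactly as weak task effects
do in practice; and the non-overlap dead time of the burst process biases
the suppressed-window onset-rate ratio upward at high occupancy.
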