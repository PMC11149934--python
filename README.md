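# opmbeta

Beta-band burst, modulation and connectivity analysis for somatosensory
OPM-MEG (optically pumped magnetometer magnetoencephalography), with a
forward-simulated cohort generator that makes every stage of the analysis
verifiable by parameter recovery.

## Who this is for

Developmental and sensorimotor electrophysiologists who want the full
wearable-MEG beta-oscillation analysis chain — from raw multichannel
recordings to cohort-level age trends — as tested, seedable Python, and a
synthetic-cohort harness for validating each stage without any data
download.

## What it computes

Given stimulus-locked recordings of an alternating two-finger tactile task
(0.5 s stimulation every 3.5 s), the pipeline:

1. cleans the data: bad-channel masking, 50/100/150 Hz notches + 1–150 Hz
   band-pass (zero-phase), homogeneous field correction
   `X' = (I − S(SᵀS)⁻¹Sᵀ)X`, epoching, and rejection of trials whose
   variance exceeds mean + 3 SD;
2. localizes task-modulated beta power with an LCMV beamformer
   (`w = C⁻¹Lη / (ηᵀLᵀC⁻¹Lη)`, Tikhonov regularisation at 5% of the
   largest covariance eigenvalue) and pseudo-T contrast maps
   `T = (P_active − P_control)/(P_active + P_control)` between the
   0.3–0.8 s and 2.5–3.0 s windows;
3. extracts a virtual electrode at the modulation peak and measures the
   Hilbert-envelope time-frequency spectrum, the beta modulation index
   `βmod = (βPost − βStim)/βBaseline`, and the evoked M50;
4. builds a 78-region amplitude-envelope-correlation (AEC) connectome with
   pairwise orthogonalization for leakage suppression, plus global
   connectivity and node degree;
5. detects pan-spectral bursts with a three-state time-delay-embedded
   Gaussian HMM on the 1–48 Hz virtual electrode (Baum–Welch EM,
   posteriors binarized at 2/3), selects the most task-modulated state as
   the burst state, and derives the burst probability time course, its
   stimulus-to-post modulation ΔP, occupancy-weighted multitaper state
   spectra and the burst amplitude;
6. fits cohort-level age trends (Pearson fits, within-group z-scored
   cross-metric associations, per-region degree slopes, per-frequency
   burst-PSD-age correlations).

The synthetic module simulates the whole study: triaxial sensor arrays on
a conducting sphere (closed-form dipole fields), a left-sensorimotor burst
source with age-dependent burst-probability modulation and spectral tilt
(amplitude and alpha peak age-invariant), an envelope-correlated 78-region
network whose coupling grows faster frontally (degree slope 0.27/year)
than occipitally (0.10/year), line noise, homogeneous interference, bad
channels and bad trials.  See `docs/methods.md` for the model and all
defaults.

## Worked example

Simulate and analyse an 8-subject cohort at the full paradigm scale
(64 triaxial sensors, 42 trials/finger, 78 regions; about two minutes):

```python
from opmbeta import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, n_subjects=8, out_dir="demo_out")
bundle = run_pipeline(config)
print(bundle["table"][["subject", "age", "beta_mod", "delta_p",
                       "global_connectivity"]].round(3).to_string(index=False))
print(f"beta_mod vs delta_p (within-group z): r={bundle['cross_metric'].r:.2f}")
```

prints

```
subject    age  beta_mod  delta_p  global_connectivity
   S000  2.000    -0.033   -0.068                0.007
   S001  6.571     0.071   -0.084                0.006
   S002 11.143     0.083    0.196                0.010
   S003 15.714     0.094    0.162                0.017
   S004 20.286     0.099    0.133                0.013
   S005 24.857     0.133    0.220                0.015
   S006 29.429     0.200    0.336                0.023
   S007 34.000     0.227    0.287                0.025
beta_mod vs delta_p (within-group z): r=0.77
```

Each row is one simulated subject: `beta_mod` is the recovered beta
modulation index (suppression during stimulation followed by recovery —
larger in older subjects, as planted), `delta_p` the burst-probability
modulation from the HMM burst state (near zero or noisy in the youngest
subjects, whose planted modulation is weakest), and `global_connectivity`
the mean off-diagonal AEC (rising with age, as planted).  `demo_out/`
receives the
cohort table, age fits, degree slopes, PSD-age correlations, ground truth
and a provenance log as CSV/JSON (byte-identical across re-runs with the
same seed), plus scatter figures when `figures=True`.

The same chain is scriptable from a shell:

```bash
opmbeta run-all --seed 1 --n-subjects 6 --out demo_out
opmbeta simulate --seed 2 --n-subjects 4 --out cohort_dir   # HDF5 + JSON sidecars
opmbeta fixtures --out fixture_dir
```

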