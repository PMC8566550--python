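# Methods

## Trace model and windows

All trace operations act on uniformly sampled series (default 0.1 s,
the camera frame interval; spacing enforced to 1 ns tolerance). Raw
fluorescence is background-subtracted sample-wise before ΔF/F
normalization against the mean of the baseline window; a non-positive
baseline mean is a hard error (the trace cannot be normalized), which in
practice only occurs for puncta at background level that the background
gate removes first.

Analysis windows on traces are half-open `[start, end)` seconds. The
source conventions write windows as "(10–20 s)" without endpoint
semantics; half-open windows make adjacent windows partition the trace.
One deliberate exception: the window AUC integrates over the closed
interval `[start, end]` with the trapezoid rule, so that AUC is exactly
additive across adjacent windows sharing a boundary sample and a
constant ΔF/F of 1 over a 10 s window integrates to exactly 10 ΔF/F·s.
Behavior-track windows (spanning tests, per-sample inclusion) are
inclusive at both ends — a track "spanning 465–497 s" covers both
endpoints.

## Smoothing, baseline statistics, gates

The moving average is a centered boxcar of `floor(width/dt)` samples,
rounded down to the nearest odd count ≥ 1 (a 1 s filter at 0.1 s
sampling is 9 samples), with the window truncated symmetrically at the
trace edges so the output length equals the input length. Centering
avoids phase shift of peak times; truncation avoids inventing data
beyond the recording.

SD always means the sample standard deviation (n−1). The baseline
mode — used instead of the mean for GCaMP recordings, because a large
pre-stimulus transient inflates the mean — is estimated by histogram
binning with default bin width 0.01 ΔF/F. Bin centers are aligned to
the window's data minimum (edges at min − bin/2 + i·bin), so constant
data returns its own value exactly; ties resolve to the lowest bin.

Gate conventions follow the exclusion inequalities as stated:

* Background gate: a trace is **excluded** when its baseline mean F is
  ≤ background mean + 3 SD over the same window — equality excludes.
* Responder gate: smoothed (1 s) extremum over the response window must
  be **strictly** greater than baseline mean + 3 SD of the smoothed
  trace (mirrored with a sign flip for decreases, used for the MES
  quench). Both the threshold statistics and the extremum come from the
  filtered trace.
* GCaMP pre-stimulus exclusion: traces smoothed at 0.5 s; a trace is
  excluded when its baseline max exceeds its own baseline **mode** +
  5 × the genotype's **pooled SD** (the mean of per-trace baseline SDs).
  Pooling is essential: a single trace's own SD is inflated by the very
  transient the rule is meant to catch, which masks the exclusion.

The nominal false-positive rate of the 3-SD responder rule is not the
per-sample Gaussian 0.13%: the rule takes a maximum over a ~10 s window
of a smoothed (autocorrelated) series against an estimated threshold,
giving an effective multiple-look rate near 15% on white noise. Tests
therefore benchmark the classifier against an independent Monte-Carlo
recomputation of the rule rather than a textbook constant.

## Vesicular pH inference

The calibration equations and the δ factor are given in the README. γ is
the maximum of the 5 s-smoothed ΔF/F during NH₄Cl application
([20, 60) s), ε the magnitude of the minimum during MES application
([20, 80) s); responder gating uses the separate 1 s filter. The two
filter widths serve different purposes: 1 s preserves response peaks for
detection, 5 s suppresses the high-frequency fluctuations that would
bias a plateau amplitude taken as an extremum.

The intersection SF_γ(pH) = SF_ε(pH) is found by scanning the difference
on a 10⁻³-pH grid over (5.5 + 10⁻⁶, 7.2 − 10⁻⁶) and refining each sign
change with Brent's method to |ΔpH| < 10⁻⁷. The bracket excludes the
endpoints where the equations degenerate (A → 0 at pH 7.2; C → 1 at
pH 5.5). If several sign changes occur — not observed for physical
(γ, ε) pairs, where both curves are monotone — the smallest-residual
root is kept and a warning issued. Solutions with pH < 5.0 are flagged
`below_dynamic_range` (the probe is effectively dark below this);
absence of any sign change yields `no_intersection`. Genotype summaries
average only converged, non-excluded solutions.

`forward_calibration` is the exact algebraic inversion of the two
equations (γ = A(1−SF)/(1+A·SF), ε = SF(1−C+A)/(1+SF·A)); it drives the
synthetic generator and round-trip tests, which recover (pH, SF) to
10⁻⁴ over pH ∈ [5.2, 7.0] × SF ∈ [0.05, 0.9].

Two numerical readings were fixed by direct evaluation against the
reported correction factors (1.15 and 0.98):

* **pK = 7.18 everywhere.** The δ-factor paragraph of the source
  Methods states pK = 6.18, inconsistent with the value used for the
  calibration equations; only 7.18 reproduces both printed factors
  (1.1452 and 0.9750 vs 1.15 and 0.98), so 6.18 is treated as a
  typographical error. The pipeline log records the pK in use.
* **δ-ratio pairing.** "Everything else (including surface fraction)
  stays the same" is ambiguous about whose SF enters the reference δ.
  Of the four candidate pairings, only evaluating *both* δ factors at
  the mutant's SF (swapping only the pH) reproduces both printed
  factors; that pairing is implemented. The residual 0.9750 vs 0.98 is
  consistent with the printed input means themselves being rounded.

The external/cytoplasmic reference pH is 7.2 (the NH₄Cl saline's pH),
configurable via `Constants`. The equal-vesicle-count assumption behind
the δ adjustment is inherited as stated, not modeled.

## Behavior kinematics

Pixel scale defaults to 38.15/1.17 ≈ 32.607 µm/px, derived from the
stated equivalence of the track-QC speed threshold. Speed is the
Euclidean step displacement over the step duration, assigned to the
later sample. Heading is the direction of each displacement vector;
heading change is the absolute difference of consecutive headings
wrapped to [0°, 180°] per second. Stationary frames inherit the last
defined heading (a pause is not a turn); leading undefined headings
propagate NaN and are excluded from all statistics. A high-angle turn is
a change ≥ 50°/s — inclusive at the threshold, matching the "equal
or >" criterion. Turn flags are per-sample; consecutive turning samples
are not merged, since only the instantaneous criterion is defined.

Track QC keeps tracks lasting ≥ 30 s with **mean** instantaneous speed
≥ 1.17 px/s. The alternative minimum-instantaneous-speed reading would
discard essentially all real worms, which pause; the mean reading is
logged as an interpretation. Population series (mean speed, turn
probability) are computed per time point over the filtered tracks
present at that instant; turn probability is the fraction of tracks with
a defined heading change that meet the criterion. Stimulus-locked
statistics locate the population extremum within a stimulus window
(earliest on ties) and average the per-sample metric over
[t* − 15, t* + 17] s for every track spanning that window.

## Group statistics

Kruskal–Wallis H (tie-corrected) and one-way F delegate to scipy. Dunn's
post-hoc z-tests are computed from pooled mid-ranks with the standard
tie correction; p-values are two-sided normal and Bonferroni-multiplied
by the number of *requested* comparisons (the adjustment family was not
specified at the source; Bonferroni is the conservative choice and is
validated against an exact permutation enumeration at small n). Dunnett
many-to-one comparisons use `scipy.stats.dunnett`.

## Synthetic data

Noise is i.i.d. Gaussian per sample, default SD 0.02 ΔF/F — large
enough that 3-SD gating is nontrivial, small against unit-scale
responses. Response kinetics are first-order with τ = 1 s (plateau-based
measures are insensitive to the exact rise shape). Calibration
recordings carry baseline fluorescence 100 AU over a constant 10 AU
background. Worm tracks are correlated random walks at 1 s sampling:
per-step speed is the active regime's mean with 10% multiplicative
jitter, heading diffuses at 8°/√s between Poisson turn events (≥ 60°
jumps) at the active rate, and a configurable fraction of tracks start
late or end early to exercise the spanning rules. Default study
conditions for recovery tests: 50 worms, baseline 150 µm/s vs stimulus
60 µm/s, turn rates 0.05 vs 0.25 events/s, one 50 s stimulus pulse.
Chemotaxis counts are binomial; expected AI = 2·p_air − 1.

What the generators do **not** emulate: photobleaching and focus drift,
correlated (1/f) noise, perfusion-exchange kinetics, worm collisions and
track fragmentation, and posture-level behavior. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artifact of real recordings — the
exclusion rules exist precisely because real data contain artifacts the
generator injects only in stylized form.

## Problem sizes

Round-trip grids (37 × 18 pH/SF combinations), 200-seed Monte-Carlo
responder runs, 50-track kinematics, and 5000-replicate null calibration
of the Kruskal–Wallis type-I error were chosen as the package's standard
verification sizes; all complete in seconds on a laptop-class core.

## Known limitations

* The solver assumes a unique intersection; pathological (γ, ε) pairs
  from non-responding puncta can yield none (reported, not averaged).
* γ can exceed its physical bound when baseline F approaches background;
  the gates are the only guard, as at the source.
* Population statistics use filtered tracks only; whether the original
  tracker's per-instant statistics included unfiltered objects is
  unknown.
* Turn probability is per-sample at the track sampling rate; a
  per-second definition would rescale it by the sampling interval.
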