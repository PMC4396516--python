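# Methods

This note documents the models, defaults and design choices behind
alphaband, in the spirit of a package methods appendix. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Spectral processing

Recordings are re-referenced to the common average (each sample minus the
instantaneous mean over channels) *before* artifact detection, then
fragmented into consecutive, strictly non-overlapping 2-second epochs. With
a 250 Hz sampling rate a 2-s epoch gives a native FFT bin spacing of 0.5 Hz,
so the analysis grid {2.0, 2.5, …, 45.0} Hz is a pure bin selection; inputs
whose native resolution differs are rejected rather than silently
interpolated.

Per-channel power spectra are the average over kept epochs of the
Hann-windowed, mean-detrended, magnitude-squared FFT of each epoch (the
Welch estimator with non-overlapping segments). "No phase shift" is read as
plain magnitude-squared periodograms with no cross-spectral phase
manipulation. The scipy periodogram's window normalization is applied
uniformly; absolute units are declared arbitrary because every downstream
quantity is a ratio. The collapsed spectrum is the unweighted mean over
channels.

Epoch rejection replaces expert visual screening with two automated
thresholds: absolute amplitude (default 100 units) and sample-to-sample
gradient (default 50 units/sample), both configurable. These defaults are
tuned to the simulator's nominal-microvolt scale: clean simulated recordings
pass untouched, injected 500-unit transients are caught. An optional
zero-phase 4th-order 0.3–70 Hz Butterworth emulates the acquisition
band-pass for synthetic inputs and is off by default.

## Anchor detection and band derivation

IAF is the argmax of the collapsed spectrum in the extended alpha range
5–14 Hz. TF is the argmin in a search window whose default is
[3 Hz, IAF − 1 Hz]: the trough definition leaves the window open, and this
choice excludes the delta edge and guarantees TF < IAF by at least 1 Hz so
the alpha sub-bands cannot collapse. Among tied trough bins the highest
frequency (closest to the peak) wins. Both window edge and guard gap are
arguments. Quality flags record an IAF that is not a strict local maximum
(e.g. a monotone spectrum peaking at the range edge), a flat trough, and a
trough sitting on a search-window edge; flagged subjects are processed, not
dropped, and the flags propagate to pipeline reports.

Band intervals are half-open [lo, hi) except alpha3, closed at IAF + 2, and
a bin belongs to a band iff its center frequency falls in the interval —
the bin at exactly IAF belongs to alpha3. This prevents double counting at
shared edges. When TF − 4 falls below the 2 Hz floor, delta is truncated at
2 Hz and flagged (at TF = 4 it is legitimately empty). Detector output is
always on the 0.5 Hz grid, but `derive_bands` accepts off-grid anchors so
that cohort-mean anchors (e.g. 6.9/10.9 Hz) can be fed through the same
rule.

Band powers are computed on the collapsed spectrum by default, matching the
anchor definition; whether the original analyses averaged per-channel band
powers instead is not documented, and a per-channel `PowerSpectrum` input is
accepted for that variant. The risk classifier implements middle as
[1.00, 1.17): the published two-decimal rule (middle up to 1.16, high from
1.17) leaves (1.16, 1.17) unmapped, and the half-open reading makes the
partition total without contradicting any printed assignment. The
empirical-tertile splitter uses linear-interpolation quantiles at 1/3 and
2/3 with the same [lo, hi) labelling convention.

## EEG simulator

The generator emulates 5-minute, 19-channel, 250 Hz eyes-closed recordings.
The aperiodic background is white noise spectrally shaped to 1/f^β with the
shaping clamped outside 0.3–70 Hz (the emulated amplifier band). Oscillations
are band-filtered noise — alpha 1.5 Hz wide at `iaf_true`, theta 1 Hz wide at
`theta_freq` — not pure tones, so peaks have realistic width and anchor
detection is a genuine estimation problem. Each oscillation mixes a shared
source with per-channel sources (`coherence`, default 0.8 — the true
inter-channel coherence of resting rhythms is not documented, so this is an
explicit free parameter) and gets ±20% per-channel gains so the collapsed
spectrum genuinely averages distinct channels. Default amplitudes
(alpha 2.0, theta 0.8 × the unit background) give a clearly dominant alpha
peak, as in eyes-closed rest. Artifacts are half-sine transients with
per-channel gains in [0.5, 1.5]; perfectly common-mode transients would be
cancelled by the common-average reference, which is why gains vary.

What the simulator does *not* model: realistic ocular/EMG morphology,
eyes-open states, volume conduction, non-stationarity of vigilance. Passing
tests therefore demonstrate correctness of the estimation chain under a
plausible spectral model, not robustness to the full variety of clinical
artifacts.

## W-scores and the cohort generator

The W-score is fixed as (observed − age-predicted)/residual SD with the
age model fitted per ROI by OLS on normal controls and residual SD using the
n − 2 denominator; with a small control group (the study design has n = 17)
no shrinkage is applied — transparency over sophistication. Age is the only
covariate; sex can be added as an option but no default claim is made.
Controls lying on an exact line are flagged degenerate instead of producing
infinite scores. Affine invariance (adding a constant to all values shifts
the intercept, not the W-scores) is a tested property.

The cohort generator reproduces the study conditions: 14 low-risk and 13
high-risk patients (split by the ratio cutoff 1.17) plus 17 controls; ages,
MMSE, hippocampal volumes and white-matter scores drawn at the published
group means ± SDs; theta relative power and hippocampal-complex perfusion
drawn jointly with within-group correlations −0.544 (low-risk) and +0.729
(high-risk) via a location-scale transform of correlated standard normals.
Perfusion carries an age slope of −0.002/yr around a normalized level of
0.90 (SD 0.02), and the high-risk group a −0.015 hypoperfusion offset —
the published tables do not print these three scales, so they are set once
to realistic normalized-SPECT values. Theta group means 0.06/0.09 (SD 0.02)
likewise. Because the groups have opposite within-group correlations and
offset means, pooling attenuates the correlation toward zero, mirroring the
study's pooled null result qualitatively.

## Radial morphometry

Masks are voxel grids; the slicing axis defaults to the grid axis most
aligned with the foreground's longest principal axis (elongated structures
should be sliced across their length; the original scanner-plane convention
is not recoverable from a mask alone, so this is a documented divergence).
Per-slice boundaries use 4-connectivity, the 3D surface 6-connectivity;
both are stated so counts are reproducible. Distances are measured to the
piecewise-linear medial curve (segments, not vertices) to reduce
slice-discretization artifacts. Limitations are inherent to the medial-curve
construction: near a sphere's poles, or where a slice cuts a bent structure
tangentially, per-slice centroids leave the true medial axis, and distances
shrink — the cylinder and bent-tube tests restrict themselves to the
transversal regime accordingly. Group-level shape inference is reduced to
per-subject mean radial distance plus volume; vertex-wise statistical maps
with cross-subject correspondence are out of scope.

## Statistics

All tests are two-tailed. Pearson p-values use t = r√(n−2)/√(1−r²) on n−2
df; the same transform applied to a printed (r, n) pair is exposed
separately for verification of published values (|r| ≥ 1 returns p = 0 as a
flagged boundary). The independent t-test defaults to the pooled-variance
Student form (df = n₁+n₂−2), which is what reproduces the published cohort
table's p-values; Welch is an explicit option. The 2×2 chi-square applies no
continuity correction, again matching the published sex-table value. Post
hocs follow the published rule: Levene (center = mean) at α = 0.05 decides
between Games-Howell and Bonferroni. Games-Howell uses the Welch statistic
with Welch–Satterthwaite df and p = P(Q ≥ |t|√2) under the studentized-range
distribution with k groups (scipy's `studentized_range`); the implementation
is cross-checked against pingouin in the test suite. Seeded permutation
oracles (label shuffling) back the analytic p-values in calibration tests.

The published cohort-table p-values for age, education and Wahlund score are
not reproduced exactly by either the pooled or the Welch recomputation from
the printed cells (plausibly a rounding artifact of the printed summaries),
so they are not asserted anywhere; the hippocampal-volume, MMSE, sex and
correlation values are.

## Pipeline and problem sizes

The pipeline composes simulation/reading → spectra → anchors → bands →
ratio → classification → group statistics with per-subject failure
isolation, YAML config, and byte-reproducible reports under a fixed seed
(timestamps are excluded from report bodies). Stage outputs are plain
CSV/JSON so any stage can be re-fed from files.

Test and acceptance workloads use deliberately scaled problem sizes chosen
as the package's own defaults: 100 seeds × 5-minute recordings for anchor
recovery, 5 000 subjects per arm for correlation round-trips, 10 000 null
simulations for type-I calibration, 100 000 permutations for the
permutation-vs-analytic comparison.
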