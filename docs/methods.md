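# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Synthetic cohort generator

The generator emulates a developmental picture-naming EEG study: four age
groups × two word conditions × 20 subjects by default, 128 electrodes
(configurable down to 32 for speed) at 512 Hz, stimulus-locked epochs of
300 time-frames (TFs; 50 pre-onset) and response-locked epochs of 250 TFs
ending 50 TFs before vocal onset.

Each trial is simulated as **one continuous segment** from 50 TFs before
picture onset past the slowest allowed response, then windowed into both
alignments. This guarantees that stimulus- and response-locked epochs of the
same trial are sample-identical where they overlap; the response-locked cut
is regenerated from the per-(subject, condition) seed rather than stored,
so both alignments are pure functions of the design seed.

The scalp signal is a sum of planted states: unit-GFP template maps
(randomly placed dipoles in a homogeneous sphere, rejection-sampled to
pairwise |r| ≤ 0.5) times amplitude envelopes. Envelopes are raised-cosine
ramped plateaus (10 ms ramps; instantaneous switches would ring through the
band-pass filter); the P1-like state uses a single raised cosine so its GFP
peak has a well-defined latency. Stimulus-anchored states take a per-group
latency shift (defaults 60/30/10/0 ms, youngest to oldest) and amplitude
scale (1.4/1.2/1.1/1.0), emulating delayed, larger components in younger
groups; two response-anchored states precede vocal onset. The condition
factor adds +0.6 µV to stimulus-anchored states overlapping a late
300–450 ms window in the late-acquired condition — an amplitude effect, not
a topographic one, so the tANOVA condition test should stay near its
false-alarm rate while the waveform ANOVA detects it.

Noise is Gaussian, spatially smoothed by a distance kernel on the montage
(length 0.5 chord units) and re-centred to the average-reference subspace;
volume conduction makes real EEG noise spatially smooth, and unsmoothed
noise makes topographic tests unrealistically easy. Noise is white in time
(the 0.2–30 Hz filter shapes it downstream). What the generator does *not*
emulate: ocular/muscle artifact morphology (artifacts are tested with
planted amplitude spikes), 1/f temporal structure, inter-subject topography
variability beyond noise, and electrode impedance drift. Passing tests
therefore validate the algorithms' contracts and calibration, not their
behaviour under every pathology of real recordings.

RTs are truncated normal per group on [500, 2000] ms, sd 150 ms. The group
means (980/920/870/820 ms) keep every subject-level mean below the
~1074 ms ceiling at which a 300-TF stimulus epoch can still meet the exact
onset-to-(RT − 50 TF) coverage contract of the overlap removal (see
Alignment); the group ordering and a ~160 ms child–adult gap are preserved.
Accuracy is logistic with intercept 3.2 and group offsets −0.9/−0.4/−0.3/0
plus −0.5 for late-acquired words, reproducing lower accuracy in younger
groups and for late-acquired words.

## Preprocessing

Canonical order: band-pass filter → average reference → baseline (stimulus-
locked only) → artifact/error rejection → bad-channel interpolation →
average. The filter is a second-order Butterworth (0.2–30 Hz) applied
forward-backward (`sosfiltfilt`, reflection padding): acausal, zero-phase,
−12 dB/octave per pass. Baseline uses the 50 pre-stimulus TFs;
response-locked epochs are left uncorrected (there is no consensus baseline
before articulation). Artifact rejection is a deterministic ±100 µV
amplitude criterion standing in for visual inspection — configurable, since
no reproducible numeric criterion exists for the visual procedure — and
error productions are dropped so only correct trials are averaged. Bad
channels (at most 20% of the montage, a hard error beyond) are rebuilt by
spherical-spline interpolation (Perrin-style, order m = 4, regularisation
1e-5). Averages require ≥ 55 trials by default; scaled-down synthetic runs
lower this explicitly.

The montage adjacency needed by the spatial-extent criterion is built by
Delaunay triangulation of the stereographically projected cap with an
edge-length cap (1.9 × median edge) to remove spurious rim edges, relaxed
automatically if it would disconnect the graph.

## Field measures

GFP uses the 1/N (population SD) convention — stated explicitly because
N vs N−1 changes values. DISS is computed on GFP-normalised maps and
satisfies DISS² = 2(1 − r) identically. Frames with GFP ≤ 1e-9 µV have no
defined topography: they raise errors in scalar measures and are labelled
"unassigned"/untestable in segmentation and tANOVA rather than imputed.

GEV of a labelling is `Σₜ (GFP(t)·r(uₜ, T_label(t)))² / Σₜ GFP(t)²` over
assigned frames; per-map GEV partitions the numerator.

The topographic consistency test (TCT) uses the GFP of the across-subject
mean map as statistic; its null shuffles electrode assignments
independently within each subject and re-averages. Consistent topographies
survive averaging; random ones cancel.

## Point-wise waveform ANOVA

A balanced split-plot ANOVA (group between-subject, condition
within-subject with subject as blocking factor) is evaluated in closed form,
vectorised over all electrode × frame points; with one condition it reduces
to the one-way between-group ANOVA (F = t² for two groups). Significance
requires α = 0.01 sustained ≥ 10 consecutive TFs on ≥ 5 *adjacent*
electrodes, where adjacency is a connected component of the montage graph
at every frame of the run — an explicit, testable reading of "five adjacent
electrodes". No further multiple-testing correction is applied; the extent
criteria are the control, and null simulations in the test suite confirm a
familywise rate below 0.05 under the defaults.

## tANOVA

At each frame, subject maps are normalised to unit GFP; the effect size is
the mean DISS between level-mean maps and the grand-mean map (the
multi-level generalisation of pairwise dissimilarity). Randomization
respects the design: subject-to-group shuffles for the group effect;
within-subject condition-label swaps (sign flips of the difference map at
two levels) for the condition effect. For the interaction, the unit of
exchange is the within-subject condition-difference map and the null
shuffles its group assignment: the tested hypothesis is precisely that the
condition-difference topography is the same in every group, and this scheme
is exact under that null. (Sign-flipping grand-mean-aligned difference maps
— a seemingly natural alternative — re-tests the condition effect and was
measured badly anticonservative, ~39% rejections at α = 0.05 under a
300-replicate null; the group-shuffle scheme measured 4.7%.) The observed
data count as one permutation, so p ≥ 1/(n_perm + 1); permutations are
seeded and reproducible. Significance requires 12 consecutive TFs below
α = 0.01.

## Alignment and overlap removal

ms→frame conversion is round-half-away-from-zero, applied once per
quantity. Response-locked epochs **end** 50 TFs before vocal onset and span
250 TFs — the only convention consistent with combined coverage "picture
onset to 50 TFs before articulation"; it remains configurable
(`end_offset_tf`, `length_tf`). Trials whose response window would precede
picture onset (RT below ~586 ms at 512 Hz) are dropped and counted.
Concatenation keeps post-onset stimulus frames `[0, round(RT·fs/1000) −
300)` and appends all 250 response frames, giving exactly
`round(RT·fs/1000) − 50` frames. Group grand averages cut at the group mean
RT; individual ERPs at the subject's own mean RT (both supported; the
individual RT is the default for fitting). Groups with different mean RTs
yield combined ERPs of different lengths; segmentation and fitting handle
unequal lengths by construction.

## TAAHC segmentation

Frames are first **atomized**: maximal contiguous runs whose consecutive
maps correlate ≥ 0.95 form the initial clusters; atoms never span dataset
boundaries. Agglomeration repeatedly dissolves the cluster contributing
least GEV and reassigns each of its frames to the cluster of
highest-correlating centroid. Centroids are GFP-weighted means of member
maps, polarity-aligned to the member with largest GFP, re-normalised to
unit GFP. At each requested k the solution is polished by the standard
alternating reassign/recompute pass, with deterministic contiguous-split
and random restarts (best-GEV configuration wins) to escape greedy local
optima; on tiny problems every contiguous split is enumerated as a polish
seed, so the result provably dominates any contiguous labelling.

Polarity: by default correlations are signed and no inversion is applied —
the ERP convention, since component-locked maps (e.g. P1 vs N1) differ by
more than polarity. `polarity="ignore"` switches to absolute correlation
(the spontaneous-EEG convention, and the exact optimizer of the
sign-agnostic GEV objective). Ties in labelling resolve to the previous
frame's label (temporal continuity), else the lowest template index.

Post-processing merges clusters whose centroids correlate ≥ 0.95 and
absorbs label runs shorter than 12 TFs into the neighbouring label with
higher correlation, iterating until stable. Model selection returns the
smallest k whose post-processing GEV reaches 0.95 (with the full GEV-vs-k
curve); if no k reaches it, the largest-k model is returned with a warning.
Note that GEV inherits the noise fraction of the *segmented dataset*: at
10 dB single-subject SNR the ceiling is ≈ 0.92, which is why segmentation
operates on grand averages in the pipeline.

Segmentation runs jointly on all eight group × condition grand averages so
the template set is shared across cells; the merge step can fold redundant
clusters, so the selected model's template count may be smaller than its
nominal k.

## Back-fitting and fitting statistics

Within a fitting window, each frame of an individual ERP is labelled with
the candidate template of highest signed correlation; runs shorter than
12 TFs are absorbed as in segmentation. A map is *present* when its total
assigned duration reaches 12 TFs (a package decision — presence is commonly
reported in the literature without a formal definition); duration is assigned-frame
count × 1000/fs, and per-map GEV is computed within the window. The
pipeline's three fitting periods follow the emulated design: TFs 35–103
post-onset (P1), TF 100 to the end of the stimulus portion, and the
response-locked portion; candidate maps per window are those the
grand-average segmentation uses there. Fitting measures feed the same
split-plot ANOVA (group between, condition within) per map and window, plus
presence contingency tables and optional covariate (age) correlations.

## Pipeline, determinism and problem sizes

Every stage writes versioned outputs and a manifest of content hashes; all
randomness derives from the single config seed, so identical configs
reproduce identical hashes. The shipped `demo.yaml` profile (4 groups × 5
subjects × 2 conditions, 32 electrodes, 40 trials, 1000 permutations)
exercises the full chain in well under a minute on one core; the
`study_defaults.yaml` profile records every reference analysis parameter at
full scale (20 subjects/group, 128 electrodes, 60 trials, 5000
permutations). Test-suite simulations use 16–32 electrode montages, 100–300
frames and 200 replicates for calibration checks — sizes chosen so the
whole suite runs in a couple of minutes while keeping binomial confidence
intervals tight enough to detect miscalibration.

## Known limitations

- The balanced split-plot ANOVA uses weighted (observation-level) sums of
  squares; with unequal group sizes it matches the classical weighted
  analysis, not Type-III.
- The interaction tANOVA is defined for two conditions (difference maps);
  designs with more within-subject levels would need a different exchange
  unit.
- Artifact rejection is amplitude-only; no ICA or annotation-based cleaning.
- The generator's condition effect is purely an amplitude modulation;
  topographic condition effects can be planted via `template_maps` and a
  custom state sequence but are not a default.
- Spherical-spline interpolation assumes the montage covers the upper
  sphere reasonably densely; very sparse caps (< 16 electrodes) make the
  10%-of-GFP recovery guarantee unrealistic.
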