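# Methods

## Scope and data model

The pipeline starts at *source level*: per-subject region × time signal
matrices (by default the 90 AAL regions that remain after excluding
cerebellum and vermis), a cohort table (group PD/HC, sex, age, UPDRS-III,
disease duration), and a region → lobe partition. Sensor-space
preprocessing, artifact removal, and beamforming are out of scope; the
synthetic-cohort generator supplies source-level inputs directly.

## Band decomposition and phase

Signals are decomposed with a 4th-order Butterworth band-pass applied
forward–backward (`sosfiltfilt`), which doubles the attenuation and
cancels the filter's phase response — essential, since the connectivity
metric lives entirely in relative phases. The five bands are delta
0.5–4 Hz, theta 4–8, alpha 8–13, beta 13–30, gamma 30–48 (configurable;
8–13 is used for alpha where some conventions quote 8–12).

Instantaneous phase is the argument of the analytic signal (full-length
Hilbert transform, no epoching). The first and last second are flagged
and trimmed before connectivity estimation to suppress transform edge
effects; the trim length is configurable.

## Phase linearity measurement

For phases φᵢ, φⱼ the interferometric signal z(t) = exp(i(φᵢ − φⱼ)) is
formed and its two-sided periodogram taken; the PLM is the fraction of
spectral energy within |f| ≤ B, with B = 1 Hz by default. The f = 0 bin
is zeroed before integrating: a *constant* phase difference — the
signature of one source leaking instantaneously into two regions — then
contributes nothing, and the fully degenerate case (all energy at DC)
returns 0 with a warning. This is the volume-conduction guard; a flag
(`discard_dc=False`) exposes the naive variant for comparison.

Estimator choices: the default is the plain boxcar periodogram
(deterministic, parameter-free, resolution 1/T); Welch averaging is
available (`welch_segment_s`, constrained to ≥ 2/B so the integration
band is resolved) and agrees with the periodogram in rank on synthetic
cohorts. The full recording (minus edge trim) is used rather than epoch
averaging. Matrices are computed as the literal pairwise loop; entries
are symmetric in the argument order bit-for-bit (the phase-difference
sign is canonicalized before the FFT, which leaves the statistic
unchanged because the integration band is symmetric).

A floor worth knowing about: two *independent* channels that have been
band-filtered share the filter's passband, so their phase difference is
itself band-limited and the PLM between them does not vanish — for a
5-Hz-wide band and B = 1 Hz the floor is roughly 0.3. Null behavior of
the statistic should therefore be judged against phase dynamics wider
than the analysis band (free phase diffusion gives PLM ≈ 0.05), and
group comparisons are always within-band, where the floor is common to
both groups.

## Eigenvector centrality and lobe aggregation

For a symmetric nonnegative connectivity matrix A (diagonal forced to 0),
the centrality vector solves A x = λ x at the leading eigenvalue. A dense
symmetric eigendecomposition is used up to N = 256; beyond that, power
iteration (tolerance 1e-12, max 10,000 iterations, positive diagonal
shift to break ±λ ties of bipartite-like graphs). The sign is fixed to
the all-nonnegative Perron orientation, tiny negative round-off is
clamped, and scores are normalized to Σ x̃ᵢ² = 1. An all-zero matrix, or
a disconnected one whose leading eigenspace is degenerate, is rejected —
neither can occur for strictly positive PLM matrices.

Region scores are averaged (arithmetic mean) within six groups. The
shipped AAL-90 partition is a *convention*, not a reproduction of any
particular study's appendix: anterior and mid cingulate count as frontal,
posterior cingulate as parietal, Rolandic operculum as frontal;
frontal 34, insular 2, temporal 20, parietal 14, occipital 12,
subcortical 8 regions. Any alternative `region_label,group` CSV can be
supplied.

Because each subject's EC vector has unit norm, lobe values are
*compositional*: a genuine increase in one lobe necessarily depresses
the others. Group differences in the non-target lobes should be read
with that in mind.

## Group statistics

Per (band, lobe): statistic |mean(PD) − mean(HC)|; null distribution by
random relabeling, 50,000 shuffles by default. When the number of
distinct assignments is within the shuffle budget the test enumerates
all of them and reports the exact proportion (the observed assignment
included). Otherwise it samples and reports the add-one estimate
p = (1 + #extreme)/(1 + n_perm), which guarantees p > 0 and is slightly
conservative; the plain proportion is available by flag. The permutation
seed is required and logged in the outputs.

BH-FDR at q = 0.05 is applied across the six lobes *within each band*
(the multiple-testing family is genuinely a design choice; a flag
switches to a single family across all band × lobe tests). Two-sidedness
is inherent in the absolute-difference statistic; the direction is
reported separately. Sex-stratified reruns simply restrict both groups
before testing and reject if a group empties.

Pearson correlations (UPDRS-III, disease duration) are computed within
the PD group, by default only for cells flagged significant in the group
comparison — mirroring the usual follow-up practice — with BH correction
within each clinical variable across the computed cells; `all_pairs=True`
correlates every cell.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: 47 PD
+ 47 HC (30 M / 17 F per group), 90 regions, alpha-band carrier, with a
coupling increase planted in the frontal-lobe regions of the PD-like
group and pseudo-UPDRS-III scores generated as an affine function of the
planted effect plus Gaussian noise (truncated at 0; HC scores are 0).
Defaults use 60 s at 256 Hz per subject — chosen desk-scale (the
emulated recordings are minutes at ~1 kHz); everything is configurable.

Phase model per region:

    φᵢ(t) = 2π (f_c + δᵢ·(1−kᵢ)) t + ψ(t) + ηᵢ(t)
    dηᵢ  = −pull_rate·kᵢ·ηᵢ dt + phase_noise_sd·(1−kᵢ) dWᵢ

with ψ a shared slow random walk (cancels in every pairwise difference),
δᵢ ~ N(0, detuning_sd) a per-region carrier detuning, and ηᵢ the
region's private deviation from the shared driver. The coupling kᵢ ∈
[0, 1) acts as a linearized pull toward the driver: it sets the
restoring rate, quenches the private noise, and pulls the region's
frequency toward the carrier — without ever removing the residual
detuning, so a coupled pair's interferometric line sits *near* but not
*on* the DC bin that the PLM discards. Signals are cos(φᵢ) plus 1/f
background noise. Hub regions of PD subjects get k = base_coupling +
effect_realized, where effect_realized ~ N(effect_size, effect_sd)
truncated at 0 per subject (and exactly 0 when effect_size = 0, so the
null is a true null — both groups then follow the identical law).

Parameter defaults and why:

| parameter        | default | meaning |
|------------------|---------|---------|
| base_coupling    | 0.4     | background synchrony level of all regions |
| effect_size      | 0.35    | planted hub-coupling increment (PD frontal) |
| effect_sd        | 0.10    | between-patient effect heterogeneity; drives the EC–score correlation |
| score_noise_sd   | 4.0     | pseudo-UPDRS noise (score = 8 + 50·effect + ε) |
| phase_noise_sd   | 9.0 rad/√s | free-diffusion amplitude at k = 0 (null PLM ≈ 0.05) |
| pull_rate        | 5.0 /s  | driver pull at k = 1; keeps the coupled pedestal inside B |
| detuning_sd      | 2.0 Hz  | carrier spread; keeps coupled lines off DC and base carriers in-band |
| background_amp   | 0.3     | 1/f noise relative to the unit-RMS oscillation |

The nuisance defaults were calibrated once, at design time, so that the
generator meets its own contracts (uncoupled cohorts near the PLM noise
floor; a strongly coupled pair dominating its matrix; the planted
frontal effect recoverable at reduced cohort sizes) and were not
revisited. Per-subject random streams are spawned from the cohort seed
(`SeedSequence` children in subject order), so cohorts are reproducible
subject by subject, byte for byte.

What the generator does *not* emulate: sensor-level physics, artifacts,
cross-frequency structure, spatially correlated noise, realistic
region-specific spectra, or any empirically matched between-subject
variance (the emulated study reports none). Passing tests on these
cohorts demonstrates that the pipeline recovers known ground truth under
its own assumptions — not that it would behave identically on real MEG.

## Test problem sizes

Monte-Carlo checks run at reduced scale, chosen as the smallest sizes
that keep the relevant statistics stable: null calibration uses 600
cohorts of 10+10 subjects, 20 s at 128 Hz, a 12-region toy atlas (two
regions per lobe group), alpha band only, 1,999 shuffles per test;
planted-effect recovery uses 100 cohorts of 12+12 subjects at the same
signal scale. The full 90-region, five-band path is exercised end-to-end
by the pipeline smoke tests and the study-sized cohort-table checks.

## Numerical notes and degenerate inputs

- Permutation ties are counted with a relative 1e-12 tolerance so exact
  ties rank as "at least as extreme".
- p-values entering BH must lie in (0, 1]; zeros are rejected (the
  add-one permutation estimate cannot produce them).
- Correlation requires n ≥ 3 and nonzero variance in both variables.
- Constant channels are rejected by name at phase extraction; non-finite
  signals are rejected at container construction.
- CSV outputs are written with a fixed `%.12g` float format, comma
  separator, UTF-8 and `\n` line endings, so identical (config, seed)
  reruns are byte-identical.

## Known limitations

- The PLM passband floor (above) means absolute PLM levels depend on the
  analysis band width; only within-band contrasts are interpretable.
- The lobe partition is a convention; cingulate and operculum
  assignments differ between labs and shift lobe means slightly.
- The exact multiple-testing family (per band vs global; whether
  correlations join the same family) is a design choice; both are
  implemented, per-band is the default.
- Power iteration is exposed for cross-checking but dense decomposition
  is always used at the sizes this pipeline encounters.
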