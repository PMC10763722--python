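# Methods

## Structural model

Each sarcomere is represented by a mirror-symmetric layout about its
M-line at `SL/2`: Z-disks at 0 and `SL`, full-length MIR epitopes at
`M ± L_A(SL)/2`, A170 epitopes at `M ± d_TK(SL)`. Both `L_A` (apparent
A-band titin length, MIR-to-MIR) and `d_TK` (M-line-to-titin-kinase) are
affine in sarcomere length over the working range 1.6–3.0 µm, anchored at
the slack length of 1.8 µm. The model is purely kinematic: no
force–extension mechanics (worm-like-chain or Ig-domain unfolding) is
simulated, only the positional consequences that such mechanics produce.

Genotype defaults (all configurable per genotype):

| parameter | TTNtv⁻ | TTNtv⁺ | control | units |
|---|---|---|---|---|
| `L_A` at slack | 1400 | 1400 | 1444 | nm |
| `L_A` slope | 236 | 150 | 236 | nm/µm |
| `d_TK` at slack | 70 | 80 | 70 | nm |
| `d_TK` slope | +25 | −12 | 0 | nm/µm |
| truncation fraction | 0 | 0.5 | 0 | — |
| truncated-MIR Z-ward shift at slack | — | 30 | — | nm |
| shift relaxation with stretch | — | 35 | — | nm/µm |

The TTNtv⁻ values are the measured structural constants of the system the
generator emulates: a 140 nm A170 doublet separation and ~70 nm `d_TK` at
slack, a ~20 nm `d_TK` excursion between SL 1.8 and 2.6 µm, and a
236 nm/µm A-band extension rate. The control genotype differs by a 44 nm
`L_A` intercept offset and a flat `d_TK`. For TTNtv⁺, the halved
full-length complement (truncation fraction 0.5, i.e. ~3 truncated
molecules per half thick filament under heterozygosity) and the ~10 nm
`d_TK` offset at slack are likewise fixed by the emulated system; the
reduced `L_A` slope (150 nm/µm), the negative `d_TK` slope (−12 nm/µm)
and the truncated-MIR shift law (30 nm at slack, closing at 35 nm/µm,
clamped at zero) are this package's own quantifications of effects that
are only reported directionally ("significantly reduced", "negative
slope", MIR broadening at slack that relaxes with stretch); they are
single choices made once, not fitted quantities.

## Synthetic STED generator

Per profile, `n_sarcomeres_per_profile` (default 4) sarcomeres are laid
end to end with a half-sarcomere margin on each side (so edge sarcomeres
lack a neighbour and drop out of the assignment grammar naturally). Each
half-sarcomere draws 6 titin molecules; in TTNtv⁺ each molecule is
truncated by an independent Bernoulli(0.5) draw ("randomly distributed").
A truncated molecule contributes a Z-ward-shifted MIR fluorophore and no
A170 fluorophore. Every epitope position receives independent Gaussian
registration jitter (SD 15 nm). Jitter is drawn per *epitope*, not per
molecule: the two epitopes of one molecule are ~700 nm apart and their
local registration errors (antibody linkage, local lattice disorder) are
treated as uncorrelated.

Channels are rendered as sums of 1D Gaussian point-spread kernels
(FWHM 40 nm — the tested resolution of the emulated instrument) on a
10 nm pixel grid (Nyquist-safe), scaled so that a fully-labelled,
perfectly-registered band peaks at ~400 photon counts, then Poisson shot
noise is applied. The per-fluorophore amplitude is fixed by the full
complement (peak/6), so channel intensity is proportional to
labeled-molecule count — halving the A170-bearing complement halves the
expected A170 signal with the MIR signal unchanged. A 2D image mode tiles
the noiseless trace across transverse rows with independent Poisson draws
per pixel, for exercising thick-line profile extraction.

Pixel size, photon scale, and labeling efficiency are not documented for
the emulated acquisitions; the defaults above are realistic for
STED imaging of cardiac cryosections and are configurable. What passing
tests show is therefore that the *measurement chain* is unbiased under a
faithful generative model of band formation — not that real tissue, with
its labeling heterogeneity, deconvolution artefacts and patient-level
variation, would yield the same precision.

## Profile analysis

**Peak detection.** Candidate peaks are local maxima whose prominence
exceeds `k = 3` times a noise scale. Shot-noise-limited traces are
strongly heteroscedastic, so the scale is the *larger* of a local
estimate (rolling median of |first differences| over 150 nm, scaled to
SD) and a global robust estimate, with a floor of 2% of the largest
prominence so that single-count fluctuations on an empty baseline never
qualify. Candidates closer than 250 nm are fitted jointly.

**Fitting.** Each cluster is fitted by unweighted least squares as a sum
of Gaussians plus a constant baseline (the background-correction method
of the emulated workflow is unspecified; a constant per fitted
neighbourhood is the least committal choice). Initial centres are the
detected maxima; amplitudes are bounded non-negative, centres confined to
the cluster window. Fitted components below the significance floor are
discarded. A single-component fit whose FWHM exceeds 1.6× the nominal
PSF FWHM is refitted with two components, and the split is kept only when
an F-test on the residual variance passes at α = 0.01 — unresolved
doublets are otherwise rejected downstream rather than force-deconvolved.
Non-converged clusters are excluded, logged, and reported through the
diagnostics channel, never silently dropped.

**Sarcomere grammar.** Measurements come from the pattern
`[MIR, A170, A170, MIR]`: a pair of adjacent MIR peaks (no MIR between)
bounding an A170 doublet whose separation falls in a 60–260 nm window.
A170 peaks below 10% of the tallest A170 peak between the MIR pair are
ignored as residual noise components. When several doublet pairs qualify,
the one whose midpoint is nearest the MIR midpoint wins; overlapping
matches resolve by smallest MIR span, then leftmost. The M-line is
estimated as the A170 doublet midpoint (the actin/phalloidin channel is
not modelled, and the doublet midpoint uses only the two labelled
channels the analysis needs); SL is the distance between consecutive M
positions, interior sarcomeres averaging their two neighbour gaps. A
profile needs at least two complete matches to yield any measurement,
since one M position alone fixes no SL.

**Quality control.** For each channel the across-the-M-line fluctuation
is `|h_left − h_right| / mean(h_left, h_right)`; a sarcomere fails if
either the MIR or the A170 pair exceeds 0.20. The A170/MIR intensity
ratio is the mean of the two A170 heights over the mean of the two MIR
heights, using baseline-corrected fitted amplitudes.

**FWHM reporting.** Epitope widths are reported in nm; a
`fwhm / height` column is also emitted for workflows that normalise
widths by peak height, since either reading of "FWHM normalised to peak
height" is defensible.

**A known estimator property.** Height-based intensity ratios are
calibrated (ratio = labeled-molecule fraction) only while band *shapes*
match across channels. Under the full TTNtv⁺ defaults the truncated-MIR
shift broadens the MIR band, lowering its height and inflating the
recovered A170/MIR ratio above the molecule-count fraction (≈0.76
instead of 0.5 at slack); integrated intensities do halve. This is a
property of height normalisation itself and a reason such ratios deserve
cautious interpretation; the tests pin both facts.

## Gel densitometry

Lanes are OD traces on a uniform migration grid. Mobility calibration is
a least-squares line of migration vs log₁₀(MW), invertible in both
directions. In auto mode, bands are prominent maxima of the lightly
smoothed trace; windows tile the lane at midpoints between band groups.
Two adjacent bands merge into one group when the valley between them
exceeds 20% of the smaller peak (the N2BA/N2B pair at default MWs);
merged groups share one baseline chord and split at the interior valley,
so cross-talk between N2BA and N2B cancels inside T1 = N2BA + N2B.
Baseline edge levels are the mean OD over a 0.3 mm margin at each window
edge — a pointwise minimum would be biased low on a noisy trace and
systematically inflate every area. Areas are trapezoidal above the
chord; band MW estimates use the OD-weighted centroid restricted to the
contiguous core above 10% of the band maximum (wide windows would
otherwise let baseline noise drag the centroid). Labels are assigned to
detected bands by nearest log-MW against the lane template
(N2BA 3300 > N2B 3000 > T2 2200 > MyHC 223 kDa); an unassigned band
counts as truncated titin only if its calibrated MW matches a predicted
truncated mass within 10% — band position alone is never sufficient.
A run of ≥5 samples at the lane maximum flags saturation.

The default TTNtv⁺ lane composition sets the truncated-band quantity to
0.19 × T1 (the mean relative expression of truncated protein in the
emulated system) with a truncated MW of 1555.4 kDa, which is exactly the
average-mass prediction for a truncation at residue 14,000 — so the
densitometry → mass-prediction matching loop closes on consistent
numbers.

## Truncated-mass prediction

With a sequence available, the truncated mass is the sum of average
residue masses over residues 1..r plus one water; without one, it is
`r × 111.1 Da + 18.02 Da`. The 111.1 Da default is the
natural-abundance-weighted mean residue mass (a uniform draw over the 20
amino acids would average ~119 Da); both modes agree within 2% on
natural-composition sequences, and the table-based mode is verified
against an independent reference implementation in the tests. Region
classification uses inclusive, contiguous residue intervals with
boundary residues owned by the earlier region; the packaged map places
the Z-disk/I-band boundary at residue 2,100 so that every antibody
epitope range (T12 2,174–2,437; MIR 15,968–16,348; A170 33,496–33,784;
M8M10 35,553–35,991) lies inside exactly one region.

## Cohort summaries

Counting is per sample: a sample is TTNtv⁺ if it carries at least one
TTN variant whose consequence class is truncating (frameshift, nonsense,
splice — parsed from HGVS-protein-like strings, with `fs` taking
precedence over a trailing `Ter`) and whose pathogenicity label
qualifies (pathogenic, likely pathogenic, or novel truncating);
DCM-gene-positive if it carries at least one qualifying variant in the
configurable DCM gene set. The packaged fixture is synthetic: 127
samples, 19 TTNtv carriers (8 frameshift, 11 nonsense; one I/A-junction,
one M-band, the rest A-band), 18 further DCM-gene variants on 16 samples
(two samples carry two, so the sample-level DCM-gene count is 35), and
9 samples with only non-DCM-gene findings. Variant-level gene tallies
exceed the sample-level counts by construction, because per-sample
counting is the reported quantity.

## Statistics

Two groups: Shapiro-Wilk on each; if both are compatible with normality
(p ≥ 0.05) a Student t-test, Welch-corrected when Levene's test rejects
equal variances, otherwise Mann-Whitney U. Three or more groups: one-way
ANOVA when all normal, else Kruskal-Wallis. Constant-valued groups are
treated as compatible with normality (Shapiro-Wilk is undefined there).
Length regressions are ordinary least squares of a per-sarcomere metric
on SL restricted to 1.8–2.6 µm, QC-failed points excluded and counted.
Slope equality is tested with a pooled dummy-coded interaction model
(`y ~ SL + group + group:SL`, SL centred at slack so the group main
effect is the intercept difference at 1.8 µm); its type-I error is
verified at the nominal 5% by Monte-Carlo in the test-suite. Sarcomeres
are pooled across profiles (no mixed-effects modelling of section- or
patient-level clustering — a limitation when transferring conclusions to
clustered real data), and no multiple-testing correction is applied;
reports carry an explicit `multiple_testing_correction: none` field.

## Problem sizes and numerical choices

The acceptance script uses 200 profiles per slack condition, 50 per
sarcomere length in the stretch series, and 50 gel lanes; the test-suite
uses 15–70 profiles per condition. These sizes put the standard error of
each recovered quantity well below the effect sizes of interest (e.g.
±0.4 nm on the 140 nm doublet separation at 200 profiles). Master seeds
drive every stage; series members use `seed + index`. Fit tolerances are
scipy defaults with a 20,000-evaluation cap; the QC threshold comparison
is strict (`> 0.20` fails, exactly 0.20 passes), and a threshold of 0
therefore rejects any height asymmetry.

## Known limitations

- 1D axial model: no 3D PSF, depletion-beam physics, chromatic
  registration error, or photobleaching kinetics; deconvolution is not
  simulated (profiles represent post-processing input).
- Ensemble band fitting, not per-molecule localization.
- Height-normalised intensity ratios are biased when band shapes differ
  between channels or genotypes (see above).
- The A-band width definition follows the doublet-bounded MIR-pair
  reading; an alternative reading ("across the Z-disk") exists for the
  emulated workflow and is deliberately not implemented.
- Gel band identification assumes the standard titin lane inventory;
  co-migrating contaminants would be mis-assigned.
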