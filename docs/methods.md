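# Methods

## Polar localization classification

Each cell is scored from a single fluorescence channel and three
user-supplied pixel regions: two pole regions and one cytoplasmic
reference region of identical pixel count. The corrected pole intensity is
the integrated (summed) signal over the pole region minus the integrated
signal over the cytoplasmic region; with matched areas this subtracts the
cytoplasmic contribution without any scaling, and the operation is exact
in integer photon units. Cells whose two pole regions have unequal pixel
counts (e.g. from mask clipping) are rejected rather than area-scaled,
since the correction assumes matched areas.

Classification uses the corrected-intensity ratio r = max/min:
r ≤ 2.0 bipolar symmetric, 2.1 ≤ r ≤ 10.0 bipolar asymmetric, r ≥ 10.1
unipolar. These printed one-decimal boundaries leave raw-ratio gaps
(2.0, 2.1) and (10.0, 10.1); r is therefore rounded to one decimal before
the rules apply, which closes the gaps so the three intervals tile
[1.0, ∞). Rounding is half-away-from-zero and operates on the float's
shortest decimal representation (via `decimal.Decimal`), so a computed
ratio of 5.05 rounds to 5.1 even though the nearest binary double sits
fractionally below 5.05 — plain `floor(10r + 0.5)` gets this wrong.

"Diffuse" has no numeric definition in common usage; here a pole carries a
cluster when its corrected intensity exceeds a presence floor (default 0
photons; for noisy data set it to k·σ of the cytoplasmic background,
k ≈ 3). Neither pole above the floor → diffuse; exactly one → unipolar.
Which pole is leading or lagging requires motion information and is out of
scope: the classifier reports magnitude asymmetry only. Per-strain
summaries report counts and percentages per class; the field convention is
n > 200 cells per strain.

## Reversal detection and statistics

Tracks are centroid positions plus long-axis orientation per frame,
uniformly sampled (default 30-s frames, 15-min window — 30 intervals,
31 frames). Each between-frame displacement is projected onto the cell's
long axis; a frame moves +/− when |projection| ≥ `min_step` (default
1 px), else it is paused. A reversal is scored when a run of ≥ `min_run`
moving frames of one sign follows a run of ≥ `min_run` frames of the
opposite sign, with pauses and sub-threshold jitter permitted in between.
`min_run` defaults to 2 frames (one minute of sustained movement), which
suppresses jitter-induced sign flips in noisy data at the cost of missing
direction changes shorter than two frames; for low-noise or synthetic data
`min_run=1` detects every observable sign change and recovers planted
rates without bias. Both parameters are exposed on the CLI. Detection is
invariant to global translation and rotation of the track and to playing
the track backwards. A stop without resumption of movement is not counted
as a reversal.

Per-cell counts over the window are summarized box-plot style: mean,
10/25/75/90th percentiles, and outliers defined as counts strictly outside
the [p10, p90] whiskers (consistent with whiskers at the 10th/90th
percentiles). The percentile definition is linear interpolation between
order statistics (the common spreadsheet/statistics default), stated in
the output metadata. Tracks covering less than 80% of the window are
excluded and logged; partial tracks above that threshold are normalized to
reversals per window. Strain comparison orders strains by mean and flags
hyper-/hypo-reversing phenotypes when means differ from a designated
reference strain by more than a configurable factor (default 2); no
hypothesis testing is performed.

## Colony expansion

Colony diameter is the mean of two chords through the mask centroid,
default at 0° and 90° — a reproducible stand-in for measuring a plate "at
two positions" with callipers; the choice of two orthogonal chords is this
package's convention. Chord lengths are found by walking from the centroid
in sub-pixel steps (0.25 px) under nearest-pixel membership until first
exit, which is accurate to within one pixel for convex colony outlines.
Expansion is diameter(24 h) − diameter(0 h) per colony, reported as mean ±
sample SD (ddof = 1, matching the "± standard deviation" convention at
n = 3 replicates). Shrinkage is allowed but logged; a single replicate
reports SD 0 with a warning.

## Sequence and genome tabulations

**Logo information content.** For an alignment column with non-gap count n
and residue frequencies f_a: R = log₂20 − (H + e_n), H = −Σ f_a log₂ f_a,
e_n = (20−1)/(2·ln2·n); letter heights are f_a·R. The small-sample
correction is on by default (the standard logo convention); R is clamped
at 0 since the correction can push sparse columns negative. Gaps (`-`,
`.`) are excluded from n; ambiguity codes (B, J, Z, X) are rejected by
default or optionally treated as gaps; all-gap columns are flagged and
excluded from the logo.

**Composition by physicochemical class.** Residues pooled across
sequences, fractions per class. No single canonical partition of the 20
amino acids exists; the default map is hydrophobic AVLIMFWYC, polar
uncharged STNQ, acidic DE, basic KRH, special GP, and any residue → class
TSV can be substituted. Results obtained with the default map should be
labelled as such.

**Domain-architecture resolution.** Overlapping domain hits (1-based
inclusive coordinates, as in standard domain tables) are resolved greedily:
repeatedly accept the highest-scoring remaining hit and discard hits
sharing any residue with an accepted one; score ties break by earlier
start, then lexicographic domain name. This is deliberately the greedy
rule, not a maximum-weight interval-scheduling optimum — it reproduces the
standard "highest scoring domain model wins" convention. The output is
disjoint, sorted by start, and idempotent under re-resolution.

**Co-occurrence patterns.** A genome × marker boolean table collapses to
(bit-pattern, count) rows, ordered by count descending with ties broken by
bit-pattern descending (ordering is configurable; pattern counts always
sum to the genome count). Conditional queries count genomes carrying a
required marker set and, of those, the ones also carrying a further marker.

## Synthetic data

The generators produce every input with known ground truth; identical spec
and seed give byte-identical output.

**Cells** are axis-aligned capsules (rectangle plus semicircular caps),
the simplest shape with unambiguous poles, over a uniform integer-photon
cytoplasmic background (default 100 photons/pixel). Pole regions are discs
(default radius 5 px) centred on the cap tips and clipped to the mask,
truncated to equal pixel counts; the cytoplasmic reference is the
equal-count disc at mid-cell. Planted corrected intensities are spread
over the pole-region pixels so that the noiseless region sum equals the
planted value plus background exactly. Noise is per-pixel Poisson (or
Gaussian with stated σ); real camera noise, PSF blur, cell crowding and
drift are not modelled, so passing tests demonstrate correctness of the
measurement arithmetic and classifier, not robustness to real micrograph
artefacts. Default sizes (cell 70 × 14 px in a 64 × 96 image) are free
imaging parameters chosen to resemble a rod cell at typical magnification.

**Tracks** move along a fixed random axis at constant speed (default
3 px/frame) with i.i.d. Gaussian positional noise (default 0.2 px). A
reversal is an observable change of direction between consecutive steps,
so events are planted on the frame grid at the n−1 interior frame
boundaries, each independently with probability λ/(n−1): the per-track
count is Binomial(n−1, λ/(n−1)) with mean exactly λ, at most one event per
boundary, and every planted event produces a sign change of the noiseless
displacement series. A continuous-time Poisson draw was rejected because
two events falling in one 30-s interval cancel and are physically
invisible at the sampling rate, biasing any detector low by construction;
planting on the grid keeps "planted" and "observable" identical. Rates
with mean inter-reversal time under two frames trigger a warning
(undetectable at the sampling rate). Defaults are the field-standard
15 min / 30 s / 50 cells per strain.

**Alignments** are drawn i.i.d. per column from user-specified 20-simplex
profiles; `conserved_region_profiles` builds a profile set emulating a
conserved protein region with invariant Trp/Pro columns and Glu-enriched
columns over a Dirichlet background.

**Presence/absence tables** contain exactly the requested number of
genomes per planted bit-pattern, row-shuffled by seed. The default planted
counts are engineered so the marker set (MglA, MglB, RomR-REC, RomR-C,
Frz, Glt, T4P) reproduces the canonical co-occurrence structure of these
polarity markers: 60 genomes with both MglA and MglB, 26 of those with an
intact RomR, 10 of those with a Frz system, five partial-RomR genomes
lacking MglA/MglB, 70 MglA and 31 RomR genomes in total.

## Problem sizes and verification

The test suite verifies: classifier boundaries by exhaustive one-decimal
grid sweep; intensity measurement against brute-force per-pixel summation
on 100 random synthetic cells (exact in integer photons); reversal-rate
recovery on 500 tracks per rate λ ∈ {0, 2, 4, 8} within 3·√(λ/500)
(detection at min_run = 1 under the low-noise generator defaults, where
every planted event is observable); box-plot statistics against a
sort-and-interpolate oracle on 1,000 random count lists; logo closed forms
(log₂20 for an invariant column, 0 for uniform, monotone decrease along
point-mass→uniform mixtures); co-occurrence count conservation on 200
random tables plus exact planted-pattern recovery; greedy-oracle
equivalence, disjointness and idempotence of architecture resolution on
500 random hit sets; and colony geometry against analytic disc/ellipse
chord lengths within one pixel. These sizes run the whole suite in a few
seconds.

## Known limitations

Cell segmentation and pole-region detection from raw micrographs are out
of scope — regions are inputs. Reversals are inferred from motion, not
from fluorescent cluster pole-switching. The chord-walk diameter assumes a
convex, singly-connected colony mask. The physicochemical class map and
the two-chord diameter convention are package defaults, not universal
standards, and both are overridable.
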