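# polarity-lapse

Quantitative analysis of cell polarity and motility in rod-shaped gliding
bacteria such as *Myxococcus xanthus*, for microbiologists scoring
fluorescence micrographs, time-lapse movies and agar plate assays of
polarity mutants (MglA/MglB/RomR/Frz pathway strains and the like).

The package covers four measurements and the synthetic data needed to test
them:

1. **Polar localization classification.** For each cell, the integrated
   fluorescence over two pole regions is background-corrected by
   subtracting an equal-area cytoplasmic region, and the ratio
   *r* = max(I₁, I₂)/min(I₁, I₂) of the corrected intensities (rounded to
   one decimal) assigns the pattern:

   | corrected ratio r | class |
   |---|---|
   | r ≤ 2.0 | bipolar symmetric |
   | 2.1 ≤ r ≤ 10.0 | bipolar asymmetric |
   | r ≥ 10.1 | unipolar |

   A cell with no pole above the cluster-presence floor is *diffuse*; with
   exactly one, *unipolar*. Per-strain summaries report the percentage of
   cells in each class.

2. **Reversal frequency.** Single-cell tracks (default 30-s frames over
   15 min) are projected onto the cell's long axis; a reversal is a
   sustained change of direction of travel. Per-cell counts are summarized
   box-plot style: mean, 10th/25th/75th/90th percentiles (linear
   interpolation), with points outside the 10–90 whiskers as outliers.

3. **Colony expansion.** Colony diameter is the mean of two chords through
   the mask centroid (default orthogonal); motility is the increase in
   diameter over 24 h, reported as mean ± sample SD (mm) across replicate
   colonies.

4. **Sequence and genome tabulations.** Per-column alignment information
   content *R* = log₂20 − (H + e(n)) with letter heights *f·R* (sequence
   logo data, with the small-sample correction e(n) = 19/(2·ln2·n));
   amino-acid composition pooled by physicochemical class; resolution of
   overlapping domain hits by keeping the highest-scoring model; and
   collapsing genome × marker presence/absence tables into co-occurrence
   patterns with counts and conditional queries.

## Worked example

Simulate 50 cells tracked for 15 min at 30-s intervals with an expected
4 reversals per window, then analyze the tracks:

```sh
echo '{"reversal_rate": 4.0, "n_cells": 50}' > tracks.json
polarity-lapse simulate tracks --config tracks.json --seed 7 --out sim
polarity-lapse reversals --tracks sim/tracks.csv --min-run 1 --out rev
```

prints `50 cells, mean 4.06 reversals per 15 min -> rev` and writes
`rev/summary.json`:

```json
{
  "mean": 4.06,
  "n_cells": 50,
  "p10": 2.0, "p25": 3.0, "p75": 5.0, "p90": 6.0, ...
}
```

The detected mean 4.06 equals the generator's planted mean exactly
(`sim/true_reversals.csv`) and is within sampling error of the requested
rate 4. The same pipeline quantifies localization:

```sh
echo '{"pole_intensities": [500, 100], "n_cells": 3}' > cells.json
polarity-lapse simulate cells --config cells.json --seed 1 --out cells
# manifest.csv lists image_path,cell_id,region_path per cell
polarity-lapse quantify --manifest cells/manifest.csv --out quant
```

`quant/measurements.csv` then reads

```
cell_id,I_pole1,I_pole2,ratio,pattern
c0,500.0,100.0,5.0,bipolar_asymmetric
...
```

i.e. the planted corrected intensities (500, 100) are recovered exactly on
noiseless images, the ratio is 5.0, and each cell is classified bipolar
asymmetric per the table above.

The library mirrors the CLI one-to-one, e.g.:

```python
from polarity_lapse import classify_localization
classify_localization((505, 100))   # ratio 5.05 -> 5.1 -> bipolar_asymmetric
```

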