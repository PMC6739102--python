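# Methods

This note documents the model behind `maldiderep`, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## The dereplication model

The package treats a MALDI-TOF fingerprint as two coupled views of the same
measurement: a raw intensity trace on a shared m/z grid and a list of peak
centroids with signal-to-noise ratios. Redundancy between two spectra is
decided feature-by-feature, not by a global similarity score: a peak of
spectrum *A* is a *unique spectral feature* (USF) relative to spectrum *B*
when the local Pearson correlation between the two raw traces around that
peak falls below a threshold. Directional USF counts make the comparison
asymmetric on purpose — a low-information spectrum can be explained by a
rich one without the reverse holding — and the reference-selection walk
exploits exactly that asymmetry: spectra are ranked by total USF count and
a spectrum founds a new operational isolation unit (OIU) only if it shows
at least one USF against everything ranked before it.

Assumptions worth stating explicitly:

- All raw spectra sit on one identical m/z grid. Grid identity is enforced
  at load time (tolerance 1e-9 Da); drift must be fixed by regridding, not
  silently absorbed, because the local correlation compares index-aligned
  windows.
- Intensities are non-negative and comparable in shape, not in absolute
  scale. Pearson correlation is affine-invariant, so spotting and
  ionization efficiency differences cancel; no intensity normalization is
  applied anywhere.
- Peak lists may be imperfect. A peak missed by the caller on one side is
  recovered by a high local correlation; a spurious ppm-window match of a
  genuinely shifted peak is dissolved by a low one. Consequently the final
  USF call depends only on the local correlation; the explicit peak
  matching is retained for the Dice rescue step and for diagnostics.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `ppm_window` | 700 | ppm | mass-accuracy window for centroid matching (CLI `-d`) |
| `local_ppmc_threshold` | 0.50 | fraction | USF call: peak is unique iff local r < threshold (CLI `-l`, percent); 0.20 groups at roughly species level |
| `ppmc_halfwidth_factor` | 2 | — | local-correlation window half-width = factor × ppm_window at the peak m/z |
| `snr_threshold` | 30 | — | "strong" peak cut for quality control (strictly >) |
| `min_good_peaks` | 5 | count | strong peaks required for a good-quality (green) spectrum |
| `dice_threshold` | 0.70 | fraction | low-quality rescue: matched iff Dice strictly above |
| `compare_to` | `evaluated` | — | reference-selection pool (see below) |

The correlation window must cover any shift the ppm window deems matchable
plus enough flanking shape for the correlation to be informative; twice the
matching window is the smallest factor that guarantees both, and the window
is centered on the evaluating spectrum's own centroid, consistent with the
per-spectrum USF semantics. A window with fewer than 3 grid points is an
error (the grid is too coarse for the chosen ppm window).

`compare_to` resolves a genuine ambiguity in the selection rule: "at least
one USF against everything evaluated before" can pool all previously
visited spectra (the literal reading, our default) or only the previously
selected references. The two coincide whenever redundancy is transitive and
differ only on intransitive USF structures; under the literal reading an
intransitive structure can leave a spectrum with no zero-USF reference,
which the assignment step reports as an explicit error rather than guessing.

## Preprocessing

**Regridding.** Each output grid point takes the inverse-distance weighted
average of the two bracketing raw samples — algebraically identical to
linear interpolation, which is how the "weighted average onto a fixed axis"
convention is implemented. Grid points outside the measured range get
intensity 0: the instrument recorded nothing there and inventing signal
would bias edge windows. The operation is exact on inputs already sampled
on the target grid and linear in the intensities.

**CWT peak calling.** The caller convolves the trace with L2-normalized
Ricker (Mexican-hat) wavelets over a dyadic scale ladder (1, 2, 4, …, 64
grid points), links per-scale coefficient maxima into ridge lines from the
largest scale down (per-scale matching radius ≈ scale/4, gap tolerance 3),
and keeps ridges that span ≥ 5 scales. Wavelet kernels are forced to odd
length so a symmetric apex produces a unique maximum rather than a
two-point tie. Per-peak S/N is the maximum |ridge coefficient| over scales
≤ `snr_scale_max` (default 16) divided by the local noise floor — the 95th
percentile of |scale-1 coefficients| in a 500-point window (floored at
1e-12). Capping the strength scale matters: smoothed noise develops broad
coherent bumps at the largest scales that can creep past an S/N of 3,
whereas genuine peaks reach their best coefficient at a scale comparable to
their width; with the cap, 100/100 pure-noise spectra (10,000 points,
folded Gaussian noise) yield zero peaks while real peaks keep an S/N on the
scale of amplitude/noise, which is what the quality-control cut of 30
expects. Peaks are reported at the ridge position at the smallest scale
reached (the most accurate localization) and additionally require apex
intensity ≥ 1e-4 of the spectrum maximum; detection S/N ≥ 3.

## Postprocessing conventions

- Reference-to-reference distance: directional USF counts are symmetrized
  by arithmetic mean (unbiased between directions; `max` would weight the
  richer spectrum) and scaled by the maximum over all reference pairs. The
  complementary value 1 − d is reported as a similarity; clustering uses
  the distance.
- UPGMA merges at half the merged distance (the standard ultrametric
  convention) with size-weighted mean updates; ties are broken toward the
  lexicographically smallest member id, so the tree is independent of input
  order. Newick branch lengths are height differences; names containing
  reserved characters are single-quoted.
- Precision counts only assigned non-reference good-quality spectra
  (references are the answer, not samples); the dereplication ratio divides
  the number of ground-truth groups present by the number of references.
- Low-quality spectra may exceed the Dice threshold against several
  references; all are recorded, and abundance is reported both ways
  (counted toward every match, and toward the best match only).

## The synthetic generator

`synthdata` emulates replicate whole-cell fingerprints of a set of taxa:
each taxon is a template of 12 Gaussian peaks on 2–20 kDa, of which a
fraction (default 25 %) is shared by all taxa and the rest are exclusive
(≥ 2 per taxon, so distinct taxa always present discriminating features).
Replicates jitter centroids by 50 ppm (calibration drift between
acquisitions), jitter amplitudes lognormally with CV 0.15, and add a
folded-normal noise floor of 0.5 intensity units against peak amplitudes of
60–200 (noise < 1 % of the weakest peak). Peak width scales with mass,
σ = m/z / 1800 (≈ constant resolving power of ~770 FWHM, as in linear-mode
TOF): with mass-proportional widths a ppm-scale jitter moves a peak by the
same *fraction of its width* everywhere on the axis, which is the regime
the ppm-based matching window is designed for. A constant absolute width
would instead let high-mass jitter span several peak widths — a detector
that sharp would resolve the shift as two peaks, not a correlation failure.
All randomness flows from one integer seed through independent
counter-based streams per (taxon, replicate), so any subset of a dataset is
reproducible. Degraded spectra reuse a template with amplitudes rescaled so
only 2 peaks exceed S/N 30 (orange quality).

Ground-truth peak lists (jittered centroids, S/N = amplitude / noise scale)
are emitted alongside the raw traces so the comparison machinery is
testable in isolation; an end-to-end test re-derives peak lists with the
CWT caller instead and checks that dereplication still recovers the taxa.

What passing on this generator does **not** show: robustness to baseline
drift, detector saturation, isotope structure, matrix peaks below 2 kDa,
correlated (non-white) noise, or chimeric colonies — real acquisitions
contain all of these and the generator none. The synthetic results
demonstrate the algorithm's contracts (selection/assignment invariants,
threshold monotonicity, parameter recovery under stated noise), not
instrument-level performance.

## Problem sizes

Default test and acceptance runs use 10 taxa × 5 replicates (50 spectra,
18,001-point grids), 100 independent seeds for the parameter-recovery rate
in the test suite and 25 seeds in the acceptance script, 200 random pairs
for the brute-force oracle comparison, and 100 seeds for the pure-noise
peak-calling check. These sizes give stable rates while keeping a full run
in minutes on one CPU.

## Known limitations

- The local-correlation window extent and the wavelet scale range are
  conventions of this implementation (documented above and configurable);
  other implementations of the same scheme may place thresholds slightly
  differently.
- Under `compare_to="evaluated"` an intransitive USF structure aborts with
  an explicit error instead of producing a best-effort partition; switch to
  `compare_to="references"` for a total assignment.
- Proprietary vendor formats are not read; inputs must be exported to
  plain-text two-column spectra (or one-intensity-per-line plus a grid
  file) and CSV peak lists. mzML is not ingested.
- UPGMA is quadratic-to-cubic in the number of references; fine for
  hundreds of references, not for tens of thousands.
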