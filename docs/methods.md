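# Methods

This note documents the models, estimators and design choices behind
`sonoscape`, in the order data flows through the pipeline.

## Synthetic soundscapes

The generator emulates a space-for-time recovery study: plots placed on a
regular 0→1 gradient `g` (binned for reporting into Pasture/Cacao for
g<0.1, early regeneration for g<0.5, late regeneration for g<0.9, and
old-growth above), with random planar coordinates used only by the
spatial-independence check.

**Occupancy.** Each species occupies a plot with probability
`P(g) = logistic(slope · (g − mid))`. Guild fixes the sign of `slope`:
open-land species decline with recovery (slope ∈ −[6, 14]), old-growth
species increase (+[6, 14]), generalists are near-flat (±2), nocturnal
insects increase (+[4, 10]) with early midpoints — they recover quickly.
The default pool (40 species: 45 % open, 15 % generalist, 30 % old-growth,
10 % nocturnal insect) therefore produces total richness that declines in
expectation along `g` while old-growth-affiliated richness rises. The
ground-truth community cell is a Binomial(n_visits, P) count — the
synthetic analogue of "frequency per plot" (number of files containing the
species). No quantitative occupancy model exists for the real communities,
so these effect sizes are the package's own study conditions; downstream
checks are parameter-recovery exercises, not value matching.

**Acoustic traits.** Guilds also differ acoustically, mirroring the
qualitative soundscape shift reported along recovery gradients (event
rates and amplitude fluctuation highest in open land; spectral coverage
broadest in old growth): open-land species emit short (0.3–0.8 s), loud,
narrow-band calls at high rates (14–24/min); old-growth species emit long
(1.2–2.4 s), quieter, wide-band calls at low rates (4–9/min); nocturnal
insects stridulate at high rates inside a night-time diel window that
wraps midnight. Without this trait structure the indices respond only to
aggregate call density and carry little compositional information.

**Rendering.** A recording is the sum, over species present at the plot
and active at the start time, of Poisson-onset linear chirps spanning the
species band under a Hann envelope, plus Gaussian noise shaped to a 1/f
amplitude spectrum at −45 dBFS RMS (configurable; `None` disables it).
Chirps with Hann envelopes are analytically band-limited and cheap. The
waveform is peak-normalised only if it would clip. Frequency niches are
laid on an even grid with bandwidths below twice the grid spacing, so
centres are separated by at least half a bandwidth; placement fails
explicitly when the requested pool cannot fit under Nyquist. Per-recording
random streams are spawned from (master seed, plot id CRC, start time), so
regeneration is byte-for-byte reproducible, file by file.

**Desk scale.** The default schedule is 2-minute files every 2 h for
2 days per plot at 22.05 kHz — a downscaled stand-in for the field
protocol of 2 min every 15 min over two weeks at 44.1 kHz; both interval
and rate are configuration fields, and the full field schedule is
reachable by config alone. Rain and microphone directionality are not
modelled; an optional broadband-burst contaminator exists for robustness
experiments.

What passing tests on this generator do **not** show: robustness to rain
and wind, to vocalisation structure richer than chirps (syllables,
harmonics, duets), to diel confounding between recording schedule and
species activity, or to sound attenuation differences between habitats.

## Acoustic indices

The substrate is an amplitude spectrogram from 512-sample Hamming windows
with no overlap, scaled so a full-scale sine reaches ≈1 in its bin
(2/Σwindow). Background removal estimates, per frequency bin, the modal
amplitude of the quietest 50 % of frames from a 100-bin histogram
(lightly smoothed — a 5-bin moving average — because the raw histogram
mode is quantisation-jittery), subtracts it and truncates at zero; the
profile is retained for activity decisions.

Index conventions, where the defaults matter:

* ACI uses 60-s sub-windows, averaged; all-zero bins contribute 0.
* Saturation and the ADI/AEI activity mask call a cell active when its
  noise-removed amplitude exceeds the background profile by 12 dB. A
  cell-level margin must clear the spread of Rayleigh-distributed
  background amplitudes (interquartile range ≈ 5.6 dB); small margins of
  a few dB mark roughly a third of pure-noise cells active and drown the
  biological signal, so the default sits well above that spread. The
  margin is a configuration field.
* Events/second smooths the per-frame RMS envelope (5 frames), takes the
  modal envelope dB as background, and counts upward crossings of
  background + 6 dB.
* BI sums the mean dB spectrum above its in-band minimum over a 2–8 kHz
  band (units dB·bins).
* Digital silence yields H_t = H_f = 1 (a flat envelope/spectrum), zero
  for the activity indices, and a `SilentRecordingWarning` — silent files
  must not masquerade as complex via NaN propagation.
* Plot summaries are arithmetic means over *all* recordings of the plot.

H_t, H_f and ACI are amplitude-ratio quantities and are invariant to
rescaling the waveform; saturation and events depend on their dB margins
only through the background estimate, which rescales with the signal.

## Multi-label detection

The frontend resamples clips to 16 kHz, takes an STFT with a 0.1-s window
and 0.025-s hop, projects onto 224 triangular mel filters spanning
50 Hz–8 kHz and log-scales with a 1e-10 floor; a 3-s clip yields 117
frames. Training data follows the single-positive regime: per clip, one
class's presence/absence is known and all other classes are assumed
absent. Max-blend augmentation pairs every sample A with a random batch
mate B, cropped in frequency to B's labelled band and blended in with an
element-wise maximum, labels combined the same way. Classes with fewer
than 10 positives are dropped; the rest are resampled to 200 positives
and 50 negatives.

The default backbone is a deliberately small numpy network: average
pooling of the log-mel features over time, per-feature standardisation,
one 64-unit ReLU layer, dropout 0.2, and a dense sigmoid output — trained
with binary cross-entropy and Adam (lr 0.001, batch 16), keeping the
weights of the epoch with the best class-wise mean average precision on a
fully-labelled validation set. The scorer contract (`ModelInput → [0,1]^C`)
is the module boundary; any stronger backbone can be plugged in, and the
pipeline's scientific claims do not depend on backbone capacity at desk
scale. Loss is computed on the full assumed label vector, not masked.
Dropout and the log floor are free parameters of this package.

Synthetic training clips deliberately include Poisson-many (mean 3)
co-occurring distractor calls drawn from the whole diurnal pool: field
windows are busy, and a detector trained on clean single-call clips
collapses on rendered soundscapes (false positives from spectrally
neighbouring species). Song classes are drawn guild-balanced from species
whose bands lie above 400 Hz, keeping them out of the 1/f noise floor.

Files are scored on every 3-s window at a 1-s hop (a shorter file gets
one zero-padded window; tail windows are zero-padded, a convention this
package fixes). A class is present in a file if any window reaches the
0.8 threshold; "frequency per plot" counts positive files. AP follows the
recall-change-weighted definition over descending score thresholds, which
handles ties exactly; mAP excludes (with a warning) classes without
positives; precision is 0 by convention when nothing is predicted.

## Community statistics

Bray–Curtis distances are computed on the plots × species counts
(all-zero plots are an error naming the plot). NMDS uses non-metric
SMACOF from 20 random starts (300 iterations, tolerance 1e-6, k = 2); the
best configuration is centred, PCA-rotated so axis 1 carries maximal
variance, and rescaled by a least-squares factor so embedded distances
sit on the dissimilarity scale. The reported stress is Kruskal stress-1
re-evaluated on the returned configuration with an isotonic fit under
primary tie handling (tied dissimilarities pre-sorted by embedded
distance). Axis 1 is mirrored when its correlation with the recovery
covariate is negative, so ordinations always read left-to-right as
pasture→old-growth; a zero-variance covariate leaves the axis unchanged
with a warning.

Old-growth richness counts, per plot, only species observed in at least
one old-growth reference plot. Index models are OLS with intercept on the
five predictors; richness responses are natural-log transformed (log(y)
when all counts ≥1, else log1p with a warning) to keep adjusted R²
comparable across responses; condition numbers above 1e10 are rejected as
collinear. The spatial check bins residual pairs by inter-plot distance
and computes a Moran-style standardised cross-product per bin, compared
against a permutation envelope (199 permutations, 95 %); it answers the
same falsifiable question as a full cross-correlogram — are residuals
spatially independent — without reproducing any particular package's
estimator. A ±2-SE interval at the study's size (n = 43, 5 predictors)
has nominal coverage P(|t₃₇| < 2) ≈ 94.7 %, which is what the
regression-recovery check verifies.

## OTU post-processing

Cleaning thresholds (<0.01 % of the sample total, strict) are computed
from the incoming table before any zeroing, so the rule is idempotent.
The negative-control rule is read literally per cell: the per-OTU maximum
across control samples zeroes any smaller real cell (equal counts
survive); the stricter whole-OTU removal is available behind a flag
because the prose rule is ambiguous. Cleaning precedes the control rule,
matching the order the steps are narrated. Reference filtering keeps
records by country list (14 South American names), closed bounding box
(lat −58.4..17, lon −85.8..−30.3), or Costa Rica, then requires a
non-empty, non-hyphen, IUPAC-only sequence, a COI-5P marker code, and a
BIN — except records of species wholly BIN-less in the dataset.

BIN assignment aligns each OTU to every reference with a global pairwise
aligner (match +1, mismatch −1, gap open −2, extend −0.5) and takes the
uncorrected p-distance over columns where both sequences hold unambiguous
A/C/G/T; at least 100 comparable sites are required, otherwise the OTU is
reported unassigned with the reason. Distances below 3 % adopt the
reference BIN as an identified species; 3 % exactly and above produce a
genetic morpho-species `MSP_<otu>` annotated with the nearest reference's
genus and family (the boundary is strict-below by construction). Ties are
broken by lexicographic BIN id and logged. Global alignment approximates
the local-alignment identity used by BLAST-style workflows; divergent
sequence ends can be absorbed as end gaps rather than counted as
mismatches, so p-distances here are a lower bound near the ends — with
curated, full-length barcode references the difference is immaterial, and
precomputed distances can be supplied instead by bypassing
`p_distance`.

## Problem sizes

Tests and the acceptance script run the desk-scale defaults: 20 plots ×
40 species with 24 two-minute files per plot for the index chain; 6 song
classes × (40 positive + 20 negative) clips, 30 epochs, and 12 scored
files per plot for the detector; 500 replicates for regression recovery;
≤10-point configurations for the exact oracles. These sizes were chosen
so a complete run stays comfortable on a single CPU while every
statistical claim retains enough replication to be meaningful.
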