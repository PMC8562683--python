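# Methods

This note documents the models, parameter choices and numerical decisions
behind `m6ascope`, and what the synthetic-data tests do and do not
demonstrate about real microscope data.

## In-vitro transcription model

Control transcripts are modelled as T7 run-off products: transcription
starts at the first base after the 17-nt promoter `TAATACGACTCACTATA`
(which must occur exactly once in the template) and runs to the template
3′ end. With an m⁶ATP substitution fraction *f* in the nucleotide pool,
each templated adenosine is methylated independently with probability *f*,
so the modified count per transcript is Binomial(n_A, f) with expectation
n_A · f. The bundled 197-nt validation template has a 167-nt run-off
transcript containing 24 adenosines, hence an expected 12 m⁶A bases at
f = 0.5. The enzymatically added polyA tail uses unmodified ATP and is
excluded from modification.

## Image formation and noise

Spots are rendered as pixel-integrated isotropic 2D Gaussians: the photon
count in a pixel is the product of error-function differences along rows
and columns, scaled so the `amplitude` parameter is the continuous peak
height. The camera model is the standard CCD chain — constant background,
Poisson shot noise on the expected photon image, then additive Gaussian
read noise — with defaults (background 100 counts, read noise 10 counts,
gain 1) giving a peak SNR around 10 for a median-amplitude spot. Spot
amplitudes are log-normal (median 150 counts, shape 0.35), the usual shape
of single-fluorophore intensity distributions. The PSF sigma defaults to
1.3 px at a 100 nm pixel, i.e. a ~300 nm FWHM, typical of a 60× TIRF path.

The simulator places each well's molecules uniformly in the interior
square of its field of view (a thin blank frame separates FOVs, matching
the grid-of-dense-squares appearance of a sealed nanowell array), with a
best-effort minimum spot separation (default 4 px; the end-to-end recovery
conditions use 5 px). Fiducial beads are rendered at 10× the median spot
amplitude in a dedicated channel and are constant across rounds up to the
per-round stage offsets recorded in the ground truth.

What the simulator does **not** model: optical aberrations, evanescent-
field intensity decay, photobleaching, chromatic shifts beyond rigid
translation, autofluorescence structure, or non-specific surface binding.
Passing round-trip tests therefore demonstrates the correctness of the
algorithms under the stated noise model, not robustness to every real-world
artefact; thresholds and gates will need tuning on real data.

## Spot detection

The detection chain is rolling-ball background subtraction (radius 3 px),
Gaussian blur (σ = 1.1), local maxima strictly above a pixel threshold,
then a least-squares isotropic Gaussian fit (amplitude, centre, σ, constant
offset) in a 7 × 7 window around each maximum. Decisions:

- The pixel threshold is a required parameter of the method; when not
  supplied it is estimated as median + 5·MAD of the preprocessed image,
  a robust floor that adapts to background level.
- Maxima are found on the blurred image (suppressing single-pixel noise),
  but the fit runs on the unblurred background-subtracted image so the PSF
  stays narrow and neighbouring spots bleed less into the fit window.
- Maxima closer than 2 px are merged to the brighter one before fitting.
- The 7 × 7 window covers ≥ 3σ for σ ≈ 1.3 px; at borders the window is
  clipped (min 3 × 3).
- Fit failures are reported as flagged spots (`status="failed"`), never
  silently dropped; downstream counts use `ok` spots only.
- Coordinates are 0-based (row, col) with the origin at the centre of the
  top-left pixel.

On noiseless renders the fitted centre is exact to < 0.05 px despite the
model mismatch between the sampled Gaussian used in the fit and the
pixel-integrated render (the mismatch is symmetric, so it inflates σ
slightly but does not bias the centre). At peak SNR ≈ 10 the median centre
error stays below 0.5 px.

## Colocalization and round alignment

A molecule is called modified when an antibody-channel spot centre lies
within 1 px (~100 nm) of a molecule-channel spot centre; antibody
validation mode uses 2 px. Matching is one-to-one: candidate pairs within
the radius are sorted by ascending distance and accepted greedily, which
pairs mutual nearest neighbours first and is deterministic and symmetric.
Detection rate = matched reference spots / total reference spots;
with ground-truth labels, sensitivity is the rate on truly modified spots
and specificity one minus the rate on truly unmodified ones.

Rounds are aligned on the bead channel by phase cross-correlation with
50× upsampling; the recovered translation is **added to spot coordinates**
rather than applied by image resampling, avoiding interpolation artefacts.
Alignment quality is the Pearson correlation between the reference and the
integer-shifted moving image; below a floor of 0.05 (an essentially
uncorrelated, e.g. blank, round) alignment fails loudly with the round
named.

## Matrix registration

The RDM (per-FOV total molecule counts) is compared against every
contiguous same-shape subset of the COM (per-well cell counts) by Pearson
correlation; missing FOVs are excluded pairwise rather than zero-filled.
The full correlation map is computed with FFT cross-correlations of the
masked sums (validated against a naive double loop to 1e-10), so the
default 91 × 331 offset search costs a handful of FFTs. The best offset
must be an outlier of the map's distribution — z-score ≥ 5 by default.
Correlation uses raw counts (not binarized occupancy) to preserve the
doublet signal. No rotations or flips are searched: the physical coverslip
transfer preserves orientation.

The z-threshold is an instance-size-dependent quantity: with the full-size
grids the true-offset correlation is an extreme outlier (z ≫ 5), while on
the very small grids used in some unit tests the offset distribution is too
short for a z of 5 to be attainable, so those tests pass an explicitly
lower threshold through the config. The scaled-down end-to-end conditions
(30 × 45 COM, 8 × 10 RDM) clear the default threshold.

Only wells whose registered COM entry is exactly 1 are linked to their
molecular readouts; empty wells and doublets are excluded. Cell phenotypes
come from rectangular intensity gates in dye-channel space; gates must not
overlap, and cells outside every gate are `unassigned` (in simulation these
are mostly unresolved doublets, and their exclusion from per-phenotype
statistics is intentional).

## Quantification

Single-cell m⁶A level = modified / total counts per well (undefined for
empty wells). Per-gene levels apply the reliability filter: report
modified/total only when total ≥ 10 **or** log-mean expression ≥ 0.02. The
sign of the expression threshold is exposed (`log_expr_threshold`), with
+0.02 the default and −0.02 selectable.

seqFISH decoding is one gene per round (9 genes / 9 rounds in the default
design): the per-well count for a gene is the spot count of its round, and
coupling each round's spots against the pre-seqFISH m⁶A spot map with the
1-px rule yields per-(gene, cell) modified counts.

Normalization: counts are divided by the cell's total captured molecules,
log₂-transformed, and gene rows are mean-centred. Zeros are handled with a
pseudocount defaulting to 1/total per cell (one fractional molecule);
it is configurable because the choice is not canonical. Cells with zero
total are excluded with a warning. Embedding uses t-SNE with perplexity 10
and a fixed seed (requires ≥ 3 × perplexity cells). Housekeeping QC
(GAPDH, ENO1, EEF2) passes a cell when at least `min_detect` (default 1)
of them have nonzero counts; the threshold is exposed because no canonical
value exists.

## Probe design

All rules are deterministic and re-checkable: windows of 25–30 nt,
GC ∈ [45, 70] % inclusive, no run of ≥ 5 identical bases, no ambiguous
bases; selected left-to-right greedily with ≥ 2 nt of clear sequence
between adjacent probe footprints ("≥ 2 nt distance" is read as gap
between footprints — the start-to-start reading would permit overlapping
probes and is rejected). Where several window lengths are viable at a
start, the one with GC closest to 55 % wins (shorter on ties).
Cross-hybridization: any probe sharing an exact substring of ≥ 17 nt
(either strand) with an earlier-scanned probe is dropped — a k-mer index
replaces BLAST, which for ungapped exact seeds of this length is equivalent
and deterministic. Sets above 32 probes lose their farthest-from-55 %-GC
probes (ties → larger start). Readouts (20 nt) are dropped on any exact
contiguous match of ≥ 15 nt to the reference transcript set, either
strand. Primary oligos are `revcomp(window) + "TA" + revcomp(readout)`
(the hybridizing portion must anneal to the mRNA sense strand). Sets
below 20 probes are emitted but flagged undersized; 31–32-probe sets are
flagged as exceeding the 20–30 design target while passing the trim cap.
`verify_probe_set` re-checks every rule (including an all-pairs dynamic-
programming longest-shared-substring search) independently of the design
path. Multi-isoform consensus building is out of scope; the consensus
sequence is an input.

## Problem sizes and numerical conventions

- The full-scale grids (121 × 381 COM, 31 × 51 RDM) are used directly in
  the registration tests; image-level end-to-end runs use scaled grids
  (30 × 45 COM, 8 × 10 RDM, 128 × 128 px FOVs, ~200–260 molecules/cell)
  — enough wells for the outlier statistic while keeping a full run around
  twenty seconds.
- All randomness flows through `numpy.random.Generator` seeds; identical
  (config, seed) pairs reproduce outputs bit-exactly, including the run
  manifest.
- Degenerate inputs fail loudly: a promoter absent or duplicated in a
  template, a constant RDM (undefined correlation everywhere), overlapping
  phenotype gates, a round with no gene mapping, modified counts exceeding
  totals.

## Known limitations

- Modification calling is binary per molecule (one or more m⁶A sites →
  one positive call); stoichiometry per transcript is not measured.
- Translation-only registration: chromatic or non-rigid distortions
  between rounds/instruments are not corrected.
- The greedy left-to-right probe selection is not guaranteed to maximize
  probe-set size (it is deterministic and near-optimal in practice).
- The simulator's phenotype intensity model is a simple log-normal spread
  around per-channel means; real immunostaining distributions are broader
  and overlapping, so gate placement on real data is a user decision.
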