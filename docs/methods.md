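# Methods

`cytoprep` implements the standard preprocessing chain for mass cytometry
(CyTOF) data: concatenation and arcsinh transformation, bead-based
correction of time-dependent signal drift, single-cell debarcoding of
multiplexed samples, spillover compensation, cell/live gating,
quantile-scaling batch correction, and cross-experiment quality control.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Data model

Events are rows, channels are columns. A `CytofFrame` holds any number of
equally-shaped assays; the pipeline's naming convention is `counts`/`exprs`
(raw dual ion counts and their arcsinh), then `normcounts`/`normexprs`
after drift correction, `compcounts`/`compexprs` after compensation, and
`bccounts`/`bcexprs` after batch correction, so stages compose by assay
name. Each stage takes an `overwrite` flag; the default `False` retains all
assays, the memory-saving `True` replaces `counts`/`exprs` in place.

The variance-stabilizing transform is `asinh(x / c)` with cofactor
`c = 5`, the standard choice for CyTOF dual counts. The cofactor is stored
once per frame and reused by every later transform, so compensated and
batch-corrected expressions are always on the same scale as the input.

Channel names are parsed into metal symbol and mass number
(`Pd102Di -> (Pd, 102)`, `208Pb -> (Pb, 208)`); masses outside 75-215 amu
and bookkeeping channels (`Time`, `Event_length`) parse to "no mass" and
are never rescaled by any stage. `Event_length` and Gaussian-discriminator
channels are carried through but not used by any stage.

FCS I/O is a purpose-built reader/writer covering FCS 2.0/3.0/3.1 list-mode
files with float or uniform-integer data (read) and FCS 3.0 float32
(write). Channel names and markers round-trip through the standard
`$PnN`/`$PnS` keywords; other keywords are not preserved.

## Bead normalization

Instrument sensitivity decays during acquisition (cone contamination, mass
calibration drift, detector aging). Lanthanide-doped polystyrene beads
spiked into the sample track this drift. Stages:

1. **Tagging.** Events are assigned to a two-row binary key over the DNA
   and bead channels — cells are DNA-positive/bead-negative, beads the
   converse — by maximizing the separation min(positive channels) − max
   (negative channels) on arcsinh data. This reuses the debarcoding
   machinery in its general-key form.
2. **Cell-bead doublets.** Tagged beads are scaled to their population's
   95th percentile and those with separation below `sep_cutoff`
   (default 0.35) are demoted to doublets. Under this scaling, anything
   carrying DNA caps near ≈ 0.3, while bead singlets sit near 0.9-1.0 on
   clean data and no lower than ≈ 0.4 even when oxide spill (e.g.
   Lu175 + 16 into Ir191) puts bead-derived signal into the DNA channels;
   0.35 sits in that gap in both regimes. Over-trimming here is harmless:
   beads are only used to fit slopes.
3. **Remaining doublets.** Non-bead events exceeding the lower bound of
   bead-singlet signal in *every* bead channel are flagged for removal
   (bead-bead and bead-cell doublets that were tagged as cells).
4. **Outlier trim.** Bead events outside median ± `trim`·MAD (default
   `trim = 5`; MAD with the 1.4826 normal-consistency constant, applied
   per channel on arcsinh intensities, intersection over channels) are
   dropped from the singlet set but stay removed.

Bead-singlet counts, ordered by acquisition time, are smoothed with a
running median of `window_k = 500` bead events (forced odd; the window
shrinks rather than pads at the edges). At each bead timepoint the slope
of an intercept-zero least-squares fit maps the smoothed signal onto the
baseline:

    slope_t = Σ_k baseline_k · smoothed_tk / Σ_k smoothed_tk²

The baseline is either internal (the mean of the smoothed bead
intensities over the run) or the per-channel mean raw counts of a
reference bead file from an earlier experiment — the latter puts
independent experiments on a common sensitivity scale. Slopes for
non-bead events are assigned by constant interpolation keyed on the
preceding bead's time (binary search; the first bead's slope applies
before the first bead). All channels with a parsed mass — including DNA —
are multiplied by the slope.

## Debarcoding

Samples are multiplexed with binary palladium mass-tag barcodes described
by a key `B ∈ {0,1}^(n×m)` (no duplicate or all-zero rows). The main path
requires constant row weight `k`; mixed-weight keys are rejected with a
clear error.

**Preliminary assignment.** Each event's `k` highest barcode-channel
intensities are declared positive; the induced word is matched against the
key (no match, or all-zero intensities, → ID "0"). Ties in the top-k
selection break by channel order (stable sort).

**Scaling and separation.** For each preliminary population, the 95th
percentile of its *positive* barcode-channel intensities (pooled across
that population's positive channels) is a single scale factor for all of
its barcode channels; scaled values are clipped to [0, 1]. This brings
populations to a comparable scale while leaving negative channels small,
so the separation δ — the k-th highest minus (k+1)-th highest scaled
intensity, i.e. lowest positive minus highest negative — is a bounded
confidence score in [0, 1]. (Scaling each channel by its own
population-channel percentile instead would divide negative channels by
their own small quantiles and inflate them toward 1, destroying the
separation; this was verified on synthetic data and is why the scalar
per-population convention is used.) Populations with fewer than 2 events,
and unassigned events, fall back to a global factor.

**Cutoff estimation.** For each barcode, the yield — the fraction of its
preliminarily assigned events with δ ≥ c — is evaluated on the grid
c = 0, 0.01, …, 1. Two models are fitted to yield versus cutoff:

- an ordinary least-squares line; its estimate is the cutoff where the
  fitted yield drops to half the intercept, `c_lin = −β₀ / (2β₁)`;
- a three-parameter log-logistic `f(x) = d / (1 + exp(b (ln x − ln e)))`
  (upper asymptote `d`, inflection `e`, slope `b`; initialized at
  `d = max yield`, `e = grid median`, `b = 5`, fitted with
  Levenberg-Marquardt). Its estimate targets the end of the plateau: the
  smallest grid cutoff where the relative decline `|f′(x)|/f(x)` exceeds
  0.1. Two alternative readings (argmin of `|f′|`, or of `|f′|/f`, over
  grid points with `f > 0.1`) are switchable but degenerate to the left
  edge of the plateau on realistic curves.

The final estimate is the goodness-weighted mean
`c = w·c_lin + (1−w)·c_ll` with `w = RSS_ll / (RSS_ll + RSS_lin)`. A
non-convergent log-logistic fit falls back to the linear estimate; a
non-declining linear fit (β₁ ≥ 0) falls back to the log-logistic one (or
the grid midpoint). Estimation never changes assignments.

**Final filtering.** An event is unassigned when δ falls below its
barcode's cutoff (global scalar or per-barcode), or when its Mahalanobis
distance — computed from the mean and covariance of the scaled barcode
intensities of its separation-filtered preliminary population — exceeds
`mhl_cutoff` (default 30, on the non-squared distance; a permissive
outlier trim). Separation filtering precedes the Mahalanobis trim.
Singular covariances are ridge-regularized with λ = 10⁻⁶·trace/m.

## Compensation

Spillover between mass channels (abundance sensitivity M±1, oxide
formation M+16, isotopic impurities) is modeled linearly: observed
intensities are `J = I·SM` with `SM` non-negative and unit-diagonal
(spill relative to the channel's total signal). Recovery is either the
exact inverse `I = J·SM⁻¹` ("flow"; can produce negative ion counts) or,
by default, per-event non-negative least squares solved with the
Lawson-Hanson algorithm. NNLS runs in chunks purely to bound memory; the
result is independent of chunking. Compensation, like estimation, operates
on count-scale data — spill is linear in counts; arcsinh is only for
display.

Estimation uses single-stained controls deconvoluted by the debarcoding
path with an identity (k = 1) key. For an emitting channel i and
receiving channel j, background medians `m_i⁻, m_j⁻` come from assigned
events that are negative in i and j and not assigned to any channel
interacting with either. The default estimator takes the median over
cells c in i⁺ of `(J_j(c) − m_j⁻) / (J_i(c) − m_i⁻)` (cells with
non-positive denominator dropped); the classic estimator uses
background-subtracted population medians (or trimmed means — the trimming
fraction is exposed since no standard value exists). Estimates are
restricted to the chemistry mask (diagonal; M±1; M+16; natural isotopes of
the emitter's metal, from an embedded, overridable table covering the
lanthanides and Pd/Pt/Ir/Cd/In/Sn/Ba/Y/Rh/As/Pb/Bi) unless
`interactions="all"`; entries below `th = 10⁻⁵` are zeroed and negative
estimates clipped to 0. A pre-acquired matrix is aligned to the panel by
`adapt_sm` (identity rows/columns for missing channels; extraneous
channels dropped).

## Gating

**Cell gate.** Per sample, a single bivariate Gaussian (mean, covariance)
is fitted to the two DNA-channel arcsinh expressions, with one round of
outlier-trimmed re-fitting: the 2% of events farthest by Mahalanobis
distance are dropped and the moments re-estimated, then the covariance is
divided by the truncated-chi-square(2) consistency factor
`(2 − (t+2)·α) / (2(1−α))` with `t = χ²₂(1−α)` and α the trim fraction, so
the trimmed estimator is unbiased under the Gaussian model. Events inside
the Mahalanobis ellipse at the χ²(2 df) quantile `q = 0.98` pass. This
replaces heavier t-mixture/Box-Cox cluster fits; with a single cluster and
a fixed quantile the plain trimmed Gaussian is equivalent in practice and
was verified on synthetic data.

**Live gate.** In (DNA, cisplatin) space the columns are z-scored with the
gated sample's own mean/SD; with `z = Φ⁻¹(q)` events are retained when the
bivariate standard-normal density at their standardized coordinates
strictly exceeds the density at `(z, z)` (equivalently `r² < 2z²`) *and*
they fall strictly below the line `i + s·x₀[0] > x₀[1]`. The gate is the
convex hull of the retained points on the original scale; membership uses
a point-in-polygon test with the boundary counting as inside. Defaults
`q = 0.99, i = 0.9, s = 0.4`; parameters are adjustable per sample through
the pipeline config, which is the intended workflow when the default line
clips a sample's dead-marker background tail (raising `i` to ~1.2 is a
typical adjustment). Standardization makes both criteria invariant to
affine rescaling of the inputs.

Gate yields are reported as percent of the parent population; an empty
parent yields a missing value.

## Batch correction

Every experiment in a long-running study carries the same reference
samples (group "R"). A reference table stores the 98th expression
percentiles of each target over prior experiments (arcsinh scale). For
each channel in the table, the correction factor is the current run's
98th percentile of compensated counts over pooled reference events,
divided by the mean over prior experiments of the back-transformed
reference quantile (`sinh(q)·c`). Channels absent from the table keep
factor 1 — operationally this exempts DNA/viability channels. Counts are
divided by the factors and re-transformed; quantiles use linear
interpolation (type 7) so factors are reproducible across
implementations. The 98th percentile (rather than the median) is used
throughout QC so that rare positive populations register.

Because the quantile is positively homogeneous, recomputing factors on
corrected data returns exactly 1, and two batches differing by channelwise
gains align their 98th percentiles exactly; with independently sampled
batches the residual disagreement is quantile-estimation noise.

## Synthetic experiments

The generator emulates a multiplexed acquisition: 15 samples under a
6-choose-3 palladium scheme (the five unused barcodes are "empty"); DNA-
positive cells; 7.5% calibration-bead events (high in the five bead
channels Ce140/Eu151/Eu153/Ho165/Lu175, near-zero DNA), matching the bead
share observed after identification in a typical run with a 10% bead
spike; 2% doublets formed by summing the mass channels of random event
pairs; 10% dead cells with high Pt194; an exponential sensitivity decay
reaching −20% at the end of a 10-minute acquisition, applied
multiplicatively to all mass channels; and optional linear spillover with
entries drawn uniformly in [0, 0.04] on the chemistry mask. Counts are
Poisson draws around lognormal signal levels (zero-inflated at low
signal, realistic for dual counts); the dead channel's negative population
has a nonzero background (median ~2 counts) emulating nonspecific
cisplatin uptake. Barcode positives default to ~300 counts (high SNR); the
acceptance run of the debarcoder uses a broader setting (~120 counts,
σ_log = 0.65) that places the cell separation mode near 0.5 and the
doublet mode near 0.1, so that cutoff estimation faces a non-trivial
valley. A separate helper simulates single-stained controls for spillover
estimation. Everything is reproducible from a single seed.

What passing synthetic tests shows: the algorithms recover the generating
parameters (drift curve, spillover entries, barcode identities, gate
coverage) under the declared noise model. What it does not show:
robustness to features real data have and the generator lacks —
correlated marker populations, acquisition artifacts (flow instability,
air), barcode staining gradients, non-multiplicative drift, and heavier-
tailed count noise. Problem sizes in the tests (50k-100k events) were
chosen as the smallest at which quantile and median estimates are stable;
real runs of ~400k events use identical code paths.

## Numerical choices and degenerate inputs

- Running-median edges shrink the window; even widths are bumped to odd.
- Quantiles everywhere are type-7 (linear interpolation).
- Top-k ties break by channel order; all-zero barcode events get ID "0"
  and δ = 0.
- The log-logistic is evaluated as its limit `d` at x = 0 (for b > 0) and
  exponent arguments are clipped to avoid overflow; the c_ll argmin is
  grid-evaluated (no continuous optimizer).
- Empty positive populations in spillover estimation leave identity rows;
  non-positive denominators are excluded from medians.
- A frame with zero events is valid and round-trips through FCS.
- Degenerate live-gate regions (fewer than 3 retained points, or collinear
  points) raise an error advising parameter adjustment rather than
  producing a sliver gate.

## Known limitations

- FCS keyword preservation is limited to channel names/masses; no
  GatingSet/flowWorkspace interchange.
- Only constant-k barcoding schemes are deconvoluted.
- The Mahalanobis cutoff convention (distance, not squared distance) makes
  the default 30 a very permissive trim; lower it for aggressive cleanup.
- Batch correction is anchored on pooled references; per-reference-sample
  correction is not attempted.
- Cluster-based (CytoNorm-style) and RUV-based batch correction, and
  automated flow-anomaly detection, are out of scope.
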