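# Methods

This note documents the models, the synthetic ground truth, the numerical
choices, and what the test suite does and does not establish.

## Time-frequency features

Power is estimated with complex Morlet wavelets on a fixed 52-frequency
grid: 27 frequencies at 1-Hz spacing from 3 to 29 Hz with cycle counts
rising linearly from 3 to 6, and 25 frequencies at 5-Hz spacing from 30 to
150 Hz with cycles rising from 6 to 12. The grid is configurable but the
default is the only partition consistent with the canonical per-band counts
(theta 6, alpha 4, beta 17, low gamma 9, high gamma 16; 52 in total, with
75 Hz assigned to high gamma). Wavelets are L2-normalized and truncated at
±3.5 σ_t; samples within half a wavelet of an epoch edge are flagged invalid
rather than zero-padded, so no window containing them is ever analyzed —
this avoids spurious low-frequency similarity at epoch boundaries.

Power is z-scored across trials within each recording session, pointwise per
(channel, frequency, time sample). The pointwise reference is the natural
reading of "mean activity across all trials" and matches common practice in
intracranial RSA; zero-variance cells are set to 0 and counted. Z-scoring is
idempotent up to numerical tolerance.

Bipolar re-referencing maps an N-contact depth electrode to N−1 virtual
channels by adjacent-contact subtraction, deeper minus shallower (the sign
convention is arbitrary but fixed and carried in the virtual channel
labels). Electrodes are processed independently; single-contact electrodes
yield nothing and a warning.

## Representational similarity

Feature vectors concatenate channels × in-scope frequencies × 5 time points
of a 500 ms window stepping by 100 ms (a window covering [t, t+0.5 s) is
labeled t+0.25 s). The high-temporal-resolution variant steps by 10 ms and
averages the 50 samples per (channel, frequency), giving channel × frequency
vectors. Similarity is always Spearman's ρ with average ranks for ties;
constant feature vectors have undefined correlations, which are recorded as
missing and excluded. Items are kept in canonical stimulus-id order so
neural and model RSMs align by id, never by position.

For model-based analyses, power is first averaged across repetitions of each
item (the item model, which needs repetitions, uses the repetition-resolved
path instead). The contributing trial ids per item are retained: in the
category contrasts, different-category item pairs whose contributing trial
sets intersect are excluded after repetition averaging, removing
autocorrelation-driven similarity. The exclusion set is a label-independent
property of the presentation schedule and is therefore held fixed under
label permutations.

## Group inference

Model fits are Fisher z-transformed per subject (|ρ| clipped to 1−1e−6) and
tested against zero with a one-sample t per (window, frequency) cell.
Multiple comparisons are corrected by cluster-based permutation: cells
significant at the two-sided cluster-forming alpha (0.05) form connected
clusters (adjacency in 1-D, 4-neighborhood in 2-D — no diagonals), the
cluster mass is the summed t, and the null is the distribution of maximal
|mass| across label shuffles. Positive and negative clusters are formed
separately. Corrected p uses (r+1)/(n+1) and can never be 0. Shuffle
strategies: stimulus-label (permute the model's item labels, not the neural
data) for model fits and category contrasts; condition-label (equivalently
per-subject sign flips) for paired designs; region-label for between-region
comparisons, which use Welch's t because subject sets differ. Bonferroni
correction across layers or bands is applied by the caller on top of the
cluster correction.

Onset latency is defined as the first time point of the earliest
corrected-significant positive cluster of the within-minus-between category
time course; the definition is a package choice (the underlying studies
report onsets without stating a rule).

## Representational geometry

CCI is mean within-category minus mean between-category correlation over the
upper triangle (diagonal excluded); its permutation test shuffles the item
category labels (equivalently permutes rows and columns jointly) and calls
the observed CCI significant above the null's 95th percentile, one-sided.
Slopes regress each item pair's correlation on layer index (last timepoint
per layer) by least squares; within/between slope distributions are tested
against zero with a two-sided t whose analytic p is floored at the smallest
positive float, never reported as 0. Stacks are compared by paired t on
matched pairs. MDS uses metric SMACOF on 1−ρ distances (clipped at 0) with a
classical-MDS (Torgerson) initialization plus random restarts (4 by
default), reporting stress-1 computed directly from the embedding; when item
counts differ between conditions, items are subsampled to the smaller count
and the embedding repeated (100 times by default) and averaged.

## Synthetic ground truth

The generator emulates a retro-cue working-memory experiment: 6 categories
× 10 exemplars (60 stimuli), trials encoding 3 items from 3 distinct
categories, per-stimulus presentation counts balanced within a session up to
a difference of one, a 50/50 single-item/multi-item cue split, and simulated
correctness (defaults 0.80 single / 0.75 multi, the reported behavioral
levels). Epochs default to −2..7 s at 1000 Hz (raw mode).

Category structure is injected as channel-amplitude templates drawn once per
category per subject — fixed across repetitions, because the analyses
presuppose stable patterns that repetition averaging strengthens — inside a
configurable frequency band and time window, scaled by `effect_snr`; an
item-unique template scaled by `item_effect_snr` can be added. In `tf` mode
the templates are added directly to z-scale power on the 52-frequency grid;
in `raw` mode they scale band-limited oscillatory bursts (trapezoidal 25 ms
ramps, random phase per epoch) on top of 1/f background noise (exponent 1 by
default, the standard electrophysiology surrogate — the source studies never
characterize their noise). Softplus maps zero-mean templates to non-negative
burst amplitudes in raw mode. With all SNRs zero the output is pure noise.

Maintenance-phase templates mix the encoding template with an independent
one via `maintenance_mix`: 1 reproduces encoding patterns after the cue (a
reinstated, sensory-like regime), 0 makes them fully transformed (an
executive-control-like regime) while still category-structured. This lets
the suite demonstrate the dissociation between pattern reoccurrence (EMS)
and geometry fit (model RSA) in both directions.

Layered model-RSM stacks are simulated from a geometry schedule: per-layer
target within/between-category correlations plus symmetric Gaussian jitter,
unit diagonal, clipped to [−1, 1]. Falling between-category targets with
flat within-category targets reproduce the hallmark of deep-network
hierarchies (rising CCI driven by between-category separation). Externally
computed activations (e.g. of feedforward or recurrent convolutional
networks) can be ingested from HDF5 + JSON manifest instead; the package
never runs a network itself.

What the generator does **not** emulate: eye movements, epileptiform
artifacts, electrode geometry, volume conduction, non-stationary noise, or
any image-computable feature content. A green recovery test therefore
establishes that the pipeline detects the stated class of band- and
window-limited, channel-patterned category structure at the stated SNR — not
that it is robust to every artifact of real intracranial data.

## Calibration and scale choices

The acceptance suite fixes a calibration SNR of 1.2 (z-units per unit
template amplitude, tf mode) for the recovery runs — a level at which the
category effect is reliably detectable with 12 subjects and 8 channels —
chosen once before the seeded runs. Analysis configurations are scaled to a
single-CPU budget: recovery uses tf-mode injection and encoding-span
windows; family-wise-error calibration uses reduced map sizes (1-D length
40, 2-D 10×15, generalization 6×6 over 12 items) with 500 Monte-Carlo runs
and 100–200 permutations per run, using the vectorized sign-flip path
(sign flips leave per-cell sums of squares unchanged, so permuted t maps
follow from permuted means alone); the latency recovery uses 6 categories ×
3 exemplars at 10 ms resolution over −0.8..1.4 s. Generator defaults are
never changed by tests.

## Known limitations

- The EM_1S variant (first maintenance period) is expressible as
  `category_contrast` with phase B set to that period's windows, but its
  exact span is a user choice; no default is asserted.
- Cross-phase pairing of repetitions in the item-model path uses all
  cross-trial presentation pairs; alternative pairings are not implemented.
- SMACOF stress-1 is a local optimizer; the classical-MDS initialization
  plus restarts makes small-problem results match exhaustive search to 1e−3,
  but global optimality is not guaranteed in high dimensions.
- The 2-D cluster connectivity (4-neighborhood) and the bipolar sign
  convention are fixed package choices where the field has no single
  standard.
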