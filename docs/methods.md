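# Methods

## Problem and model

`eegcl` estimates a continuous consciousness level from multichannel EEG in
patients with disorders of consciousness (coma, VS/UWS, MCS), where no
behavioural ground truth is available at fine time scales.  The working
hypothesis is that conscious periods show, simultaneously: elevated θ
(4–8 Hz) and β (12–30 Hz) relative power, a 95% spectral edge frequency
above the α band, higher signal complexity, and stronger linear and
non-linear θ-band inter-channel coupling.  Seven features tracking these
signatures are extracted per analysis window, soft-clustered into two
clusters (conscious / unconscious), and the conscious-cluster memberships
from two independent clustering methods are averaged into the final trace
P(conscious) ∈ [0, 1].

## Pipeline

1. **Preprocessing.** Band-pass 0.5–45 Hz, third-order Butterworth, per
   channel; no artifact rejection.  The filter is applied forward–backward
   (zero phase) by default so that feature timestamps stay aligned with the
   behavioural scoring; the defining description names only the filter, not
   its phase handling, so a causal single-pass mode is exposed as an
   option.  The signal is then segmented into 3-s windows sliding 1 s at a
   time; a trailing partial window is dropped because every feature is
   defined on fixed-length segments.

2. **Features** (per window, per channel, averaged across channels; pair
   features averaged across all unordered channel pairs):
   - *θ and β relative power*: Welch PSD (Hamming sub-windows of 1/8 the
     segment length, 50% overlap), band sum divided by the 0–45 Hz sum.
     Sums are discrete grid sums, not trapezoidal integrals, matching the
     defining ratio of PSD sums; a bin is in-band when its centre lies in
     [f1, f2] inclusive.  With 1500-sample windows the Welch sub-window is
     187 samples (≈ 2.67 Hz resolution), so the θ band spans ~2 bins; this
     coarseness is accepted as faithful to the stated estimator settings.
   - *SEF95*: smallest grid frequency whose cumulative power reaches 95% of
     the total (0 to fs/2) power, normalised by 45 Hz.  First-bin-crossing
     convention, no interpolation, consistent with the discrete-sum
     definition.
   - *Poincaré ERR*: SD1/SD2 with τ = 1 sample, SD1 = (√2/2)·SD(x(t) −
     x(t+τ)), SD2 = sqrt(2·SD(x)² − SD1²).  ≈ 1 for exchangeable signals,
     0 for a ramp; NaN when SD2 degenerates.
   - *LZC*: the window is binarised at the mean of |x_h| (x_h the Hilbert
     transform; ties → 0, so an all-zero window maps to all-zero bits) and
     parsed with the exhaustive LZ76 scheme; the reported value is the
     normalised complexity c(n)·log₂(n)/n.  The binarisation thresholds
     |x_h| itself, not the analytic-signal envelope |x_a|, following the
     defining binarisation rule as printed; the envelope variant and an
     LZ78 dictionary parse are available as options.  Whether the raw or
     normalised count enters the feature vector is not specified by the
     source description; the normalised form is used (features are min–max
     scaled afterwards, so the choice only affects numerical conditioning).
   - *iCOH (θ)*: imaginary part of coherency from Welch auto-/cross-spectra
     (same estimator settings), aggregated as the mean of |Im| over θ-band
     bins.  Magnitude aggregation is a deliberate choice: signed averaging
     across pairs would cancel opposite lead/lag relations, and the method's
     output is a single positive coupling index.
   - *wSMI (θ)*: ordinal patterns of k = 3 samples spaced τ = 16 ms apart
     (8 samples at 500 Hz; `round(τ·fs)` with a warning when the rounding
     error exceeds 10%), tie-broken by temporal order.  The weighted MI
     between the two symbol streams is normalised by log(k!).  Weights are
     0 for identical and sign-opposite pattern pairs and 1 otherwise — the
     convention of the measure's source method, which discounts
     common-source/volume-conduction coupling.  A consequence is that two
     *identical* signals score 0, not 1; the informal statement that
     "completely dependent" signals score 1 holds for dependent but
     non-identical, non-opposite couplings (a deterministic relabelling of
     the patterns scores exactly 1).  The empirical weighted sum can dip
     marginally below 0 on independent signals because the (largest,
     positive) diagonal terms are excluded while sampling noise remains in
     the off-diagonal cells; estimates are floored at 0 to respect the
     measure's defined range.  wSMI is computed on the broadband-filtered
     signal; θ selectivity comes from τ, with no extra θ pre-filter.

   Degenerate windows (zero power, constant signal) yield NaN in the
   affected feature; NaN rows are excluded from clustering and reinstated
   as NaN in the output trace.

3. **Clustering.** Features are min–max normalised per column to [0, 1]
   (constant columns are set to 0.5 with a warning).  Two soft partitions
   with N = 2 clusters are fitted:
   - *Fuzzy c-means*, fuzziness m = 2, at most 1000 iterations, absolute
     objective improvement tolerance 1e-5.  Initialisation is a seeded
     uniform-random row-normalised membership matrix (the source method
     does not state its initialisation); the best of 5 restarts by final
     objective J_m is kept, which stabilises the cluster labels.  A data
     point coinciding with a centroid receives membership 1 to that cluster
     (the standard resolution of the update singularity).
   - *Gaussian mixture by EM*, full covariances with a 1e-6 diagonal ridge,
     5 seeded k-means++-style initialisations, same iteration/tolerance
     budget.  The scikit-learn backend is driven one EM step at a time so
     the per-iteration log-likelihood trace is recorded and its
     monotonicity is testable.
   The tolerance is interpreted as an *absolute* improvement of the
   objective (J_m, resp. log-likelihood), matching "minimum improvement in
   the objective function".

4. **Labelling and ensemble.** All seven features are hypothesised to rise
   with consciousness, so for each method independently the cluster whose
   centroid is higher in the majority of the 7 coordinates is labelled
   conscious; ties fall back to the higher SEF95 coordinate, then the
   higher centroid mean.  The final trace is the element-wise mean of the
   two conscious-membership traces.

5. **Evaluation.** Spearman correlations between each feature and each
   trace quantify feature contributions (p > 0.05 flagged); cluster
   separation is the Euclidean distance between centroids over all features
   or any feature pair; agreement with eyes scoring binarises the trace at
   thresholds 0.3–0.7 (values at or above a threshold count as 1), maps O
   epochs to 1 and C to 0, excludes O/C and NA epochs, and reports
   (TP+TN)/(TP+TN+FP+FN).  The temporal alignment between the 1-Hz trace
   and 5-min epochs is not specified by the source description; each
   epoch's prediction is taken as the majority binarised value of the
   windows starting inside it (a per-sample comparison is a one-line
   variant on the returned tables).

## Synthetic data

Clinical DoC recordings are restricted, so the `synth` module generates
surrogate recordings with a known state schedule.  Each channel is a sum of
unit-variance band-limited filtered-noise components (δ 0.5–4, θ 4–8,
α 8–12, β 12–30 Hz) plus a white broadband component; state switches are
instantaneous (crisp ground truth; windows straddling a boundary inherit
the majority state).  `broadband_frac` sets the fraction of signal variance
contributed by the white component, which controls LZC, ERR and SEF95
together.  θ coupling injects a shared θ-band source into every channel
with channel-specific delays of 1–10 samples; zero-lag sharing would carry
no imaginary coherency (it would look like volume conduction), so the
delays are essential for the iCOH contrast.  Default state parameters
(band-weight vectors δ/θ/α/β = 0.5/1.0/0.6/0.8 conscious vs
1.5/0.4/0.8/0.2 unconscious; broadband fraction 0.5 vs 0.15; θ coupling
0.7 vs 0.1) give an awake-like broadband θ/β-rich state against a
δ-dominated narrowband state — contrasts a clinical neurophysiologist
would consider clearly separated.  The spectral and complexity feature
orderings hold with wide margin; the connectivity contrast is present but
subtler, because the conscious state's larger broadband fraction dilutes
the coupled θ component (wSMI and iCOH both increase monotonically with
the coupling parameter when the other parameters are held fixed).

What the generator does **not** emulate: 1/f spectral shaping, artifacts,
non-stationarity within a state, sleep micro-structure, volume-conduction
mixing beyond the shared-source construction, or aetiology-specific
signatures.  Passing end-to-end tests on this data therefore shows the
pipeline recovers states *whose statistical signatures match the method's
hypotheses*; it says nothing about patients whose EEG violates those
hypotheses (documented in the source material as the method's main failure
mode).

The eyes-scoring generator emits one label per 5-min epoch: O if the epoch
is majority-conscious, C if majority-unconscious, O/C on an exact tie, with
a seeded fraction of labels replaced by NA.

## Numerical choices and degenerate inputs

- Discrete grid sums everywhere in spectral quantities; inclusive band
  edges.
- Relative-power denominator starts at 0 Hz as defined, although the
  acquisition filter passes from 0.5 Hz; implemented literally.
- The Hilbert transform is taken over the whole 3-s segment; edge effects
  are accepted (segments are long relative to θ/β periods).
- FCM/GMM seeds derive from a single integer via `SeedSequence`; all
  stochastic stages (synthesis, initialisations) are reproducible
  bit-for-bit for a fixed seed.
- Samples exactly at a binarisation threshold count as 1 ("at or above").

## Problem sizes

The end-to-end validation uses a 50-min alternating schedule (ten 300-s
blocks, six channels at 500 Hz), chosen as the smallest schedule with
enough 5-min epochs (10) to make a ≥ 90% epoch-level agreement target
meaningful while keeping the full pipeline comfortable on a single CPU.
Reference quantities (wSMI independence limit, white-noise ERR) use 10⁵
samples, where the estimators' small-sample biases are far below the
reported tolerances.

## Known limitations

- The Welch sub-window rule (1/8 of a 3-s segment) gives ≈ 2.67 Hz
  resolution, coarse relative to the θ band; relative powers are therefore
  leakage-sensitive.  This mirrors the stated estimator settings.
- wSMI's zero-weight convention makes the measure blind to strictly
  identical coupling, and the floor at 0 truncates (tiny) negative
  estimates.
- The conscious-cluster rule assumes the majority of features follow the
  stated hypotheses; recordings where most features invert (documented for
  some patients) will flip the labelling.
- EDF files are read through the optional MNE dependency; there is no EDF
  writer — the plain-CSV dialect is the package's text interchange format.
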