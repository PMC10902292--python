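# Methods

`gammaens` re-implements, as a tested pipeline over synthetic ground truth, an
analysis of transient hippocampal gamma activity: individual theta cycles of
the LFP host short-lived gamma "elements" whose amplitude, frequency and
theta-phase vary broadly, and this variability — rather than being noise —
carries information about navigation behavior.  The package covers signal
decomposition, element detection and parameterization, behavioral decoding,
information decomposition, and a spiking-network model of how such diversity
arises.

## Signal decomposition

Band filtering uses ensemble empirical mode decomposition (EEMD) rather than
passband filters.  Each channel is sifted into 10 intrinsic mode functions
(IMFs: cubic-spline envelope means subtracted until approximate symmetry, up
to 10 siftings, mirrored boundary extrema), repeated on copies perturbed by
white noise of 0.3 x signal SD, and averaged IMF-wise.  A band composite
(theta 4-12 Hz, gamma 30-250 Hz, infra-theta 1-4 Hz) is the sum of IMFs whose
mean Hilbert instantaneous frequency falls in the band; the mean is taken over
the central 90% of samples to avoid edge artifacts (median available via
`freq_stat`).  The residual is defined as signal minus the IMF sum, so
reconstruction is exact by construction.

The ensemble size defaults to 2000 realizations, the value used for the in
vivo recordings this emulates.  The decomposition quality on the synthetic
material saturates far below that, so the analysis scripts and tests run 8-16
realizations; this is a precision parameter of the estimator, not a property
of the data-generating process.

## CSD, spectrograms, theta cycles

The current source density is the negative second spatial difference of the
gamma composites across the probe, divided by the squared contact spacing
(0.05 mm); it exists for interior channels only and cancels volume-conducted
components that are linear in depth.  Amplitude spectrograms use complex
Morlet kernels, 15-200 Hz in 5 Hz steps (38 rows), 0.5 s support, with the
cycle count growing linearly from 6 at 15 Hz to 20 at 200 Hz; kernels are
normalized so a pure cosine of amplitude A yields amplitude ~A, and boundary
columns are renormalized by the in-signal kernel mass.  The hippocampal
fissure is located as the peak of a Gaussian fit to the per-channel theta
power profile (4-12 Hz zero-phase FIR, then a 1-14 Hz Morlet bank with 2-4
cycles and 2 s support), possibly between contacts; a flat or monotone
profile falls back to the argmax with a warning.

Theta cycles are segmented peak-to-peak on the fissure theta composite
(minimum inter-peak distance 80 ms, just below the shortest admissible
cycle).  The trough is the minimum between peaks and the flanks the
half-amplitude crossings; phase is piecewise-linear over the quadrants (peak
0, descending flank 90, trough 180, ascending flank 270, next peak 360 deg),
which respects waveform asymmetry better than Hilbert phase.  A cycle is
accepted when its duration lies in 83-250 ms, the theta envelope
(analytic-signal magnitude) exceeds the infra-theta envelope at the start,
temporal midpoint and end (the "mid" point is switchable to the trough), and
a behavior sample falls inside the cycle.  Per accepted cycle the CSD
spectrogram is averaged into 36 phase bins of 10 deg (38 x 36 snippet); bins
left empty by fast cycles are filled by circular linear interpolation.

## Gamma elements

Patches of locally elevated power are found by scanning a decreasing
binarization threshold from the snippet maximum over the exact grid of
distinct amplitude values; supra-threshold cells form 4-connected components.
Components that would fuse as the threshold drops keep their pre-merge
extents as separate patches (a merged blob contains multiple distinct power
peaks), and the scan stops once four components are identified — at most four
elements per theta cycle.  Internally the sweep is a persistence-style
union-find over cells in decreasing amplitude order; equal-amplitude cells
are processed as one batch, which is exactly equivalent to thresholding, and
the whole procedure is verified cell-for-cell against a brute-force
binarize-and-label sweep.  Components touching a cycle edge are resolved on
the concatenated previous/current/next snippets and assigned to the cycle
holding the largest share of their power, so nothing is counted twice.  Rows
below 30 Hz (the gamma composite floor) do not participate by default
(`min_freq_hz`).

Each element carries six features: mean patch amplitude, power-weighted mean
frequency, power-weighted circular mean phase, and the host cycle's
amplitude (mean trough-to-peak difference), frequency (inverse duration) and
asymmetry (rise/decay duration ratio).  Ties among candidate patches are
broken by higher mean amplitude, then earlier phase, then lower frequency.
Element tables are filtered per trial and channel by trimming gamma
amplitudes outside the strict 1st-99th percentile band and dropping cycles
with running speed above 100 cm/s.

The slow/medium gamma balance of a frequency pdf is
(gamma_M - gamma_S)/(gamma_M + gamma_S), where each mass is the probability
in the contiguous region around a genuine local mode inside 25-50 Hz
(gamma_S) or 60-100 Hz (gamma_M) where the density stays at or above half the
mode; a band without a local mode contributes zero mass.  Distributions are
compared by a bootstrap Kullback-Leibler procedure (resampled histograms with
half-count smoothing); significance is judged against the 95th percentile of
the label-shuffled divergence distribution — the calibrated permutation form
of the test, under which a true null is flagged at the nominal rate.

## Decoding

Maze location (four sections: reward field, target arm, other reward fields,
everything else) is decoded from single elements by a boosted ensemble of
decision trees with per-iteration random undersampling (RUSBoost-style):
each round draws an exactly class-balanced subset, fits a tree limited to
500 splits, and accumulates SAMME votes at learning rate 0.01 with up to 500
learners.  Balancing makes 1/n_classes the correct chance level.  Evaluation
is 4-fold cross-validation whose folds partition theta cycles, never
elements, with a leakage audit on every run; per-element held-out
predictions support quartile-conditioned performance (by any feature or by
cycle-mean speed) and bootstrap CIs (1000 replicas over elements).
Cross-classification applies a trained model directly to another table;
learning windows group consecutive trials to a target cumulative element
count (3000 by default), and the early/late split balances cumulative counts
around a pivot trial.  Matrix summaries report the relative percent
difference between upper and lower triangles and layer-block means under a
3/4-of-trials membership rule.  The alternative-arm labeling demotes the
target arm to "other" and promotes the arm opposite the target.  Tests and
scripts use 60-100 learners; the boosting is far into diminishing returns on
the synthetic tables at that size.

## Information decomposition

Features are discretized into sample quartiles (lower-closed bins, ties to
the lower bin; phase is treated linearly like every other feature, with a
circular variant available), which maximizes single-variable entropies for a
four-letter alphabet and makes all estimates invariant to monotone feature
transforms.  Mutual information is the plug-in estimate from joint frequency
histograms, normalized by the location entropy H(L).  The partial information
decomposition uses the minimal-mutual-information ansatz: redundancy is
min[I(f;L), I(g;L)], the less informative source has zero unique information,
and synergy is I(f,g;L) - I(f;L) - I(g;L) + Red, so the parts are nonnegative
and sum exactly to the total.  No small-sample bias correction is applied;
bootstrap CIs quantify uncertainty.  Redundancy of a feature with running
speed is I(f;V)/H(f).

## Synthetic data

The generator emulates the study conditions: an eight-arm radial maze (55 cm
arms, 26 cm center platform) with a goal-directed random walk sampled at
20 Hz — four departure arms two or three positions from the target, a
day-dependent number of detour arms so latency falls across the ten training
days, an Ornstein-Uhlenbeck speed profile (mean 15 cm/s, capped at 90 cm/s),
and speed recomputed from positions by central differences and a 0.5 s moving
average.  The 1 kHz multichannel signal is a theta carrier (8 Hz by default)
whose per-cycle waveform is a time-warped sinusoid with a rise/decay ratio
parameter, a Gaussian amplitude depth profile peaking at the designated
fissure channel with a 180 deg sign flip superficial to the pyramidal
channel, plus white noise.  Gamma bursts are Morlet-like windowed cosines
(Gaussian envelope, 5 cycles by default — matching the analysis kernel so
recovery tolerances are predictable) injected per channel at theta phases,
frequencies and amplitudes drawn from configurable distributions, optionally
modulated by the maze section at injection time; burst counts per cycle are
Poisson, or exact for recovery studies.  Every burst is logged (channel,
cycle, time, frequency, phase, amplitude, section).

Real recordings differ in ways the generator does not emulate: no volume
conduction beyond the laminar profile, no spiking or ripple contamination, no
theta harmonics or frequency drift, stationary burst statistics within a
section.  Passing recovery and decoding tests therefore demonstrates the
correctness of the machinery under known ground truth, not its in vivo
performance.  Burst rates per cycle per layer are free parameters (the
source recordings do not constrain them); defaults are one burst per cycle.

## Network model

The model is a theta-driven quadratic integrate-and-fire network: n = 2000
neurons (80% excitatory), membrane equations
tau_m dv/dt = v^2 + I_j + I_theta(t) + delta-pulse synapses, with
tau_m = 10 ms (E) / 4.5 ms (I), a spike and reset at +/-v_b = 100 (the
escape-time correction is omitted; v_b is configurable and the tonic-rate
error it induces is under 1%), Gaussian excitabilities (mean 0.3 (E) / 0.25
(I), SD 0.1 x mean (E) / mean (I)) scaled by sqrt(K), couplings g_0/sqrt(K),
quenched Gaussian in-degrees within populations (mean K = 20, SD 2K (E-E) /
0.2K (I-I), truncated to valid counts — the final-value reading of the
heterogeneity parameters) and all-to-all cross-population coupling.  The
theta drive is 0.042 sqrt(K) cos(2 pi 10 t).

The recurrent couplings are g_0^EE = 0.27, g_0^IE = g_0^EI = 0.01 and
g_0^II = 1.44 x g_0^EI = 0.0144.  The alternative reading g_0^II = 1.44 is
available (`gii_reading="large"`), but it produces dense excitatory firing
(~43 Hz mean at the working point, i.e. every 100 ms window contains a
spike, and near-zero theta phase concentration), under which spike-presence
decoding is degenerate; the default reading instead yields the sparse
(~16 Hz), strongly heterogeneous, theta-phased firing regime that the model
is meant to exhibit at the fringe of synchrony, where the excitatory rate
stays below the dominant gamma frequency.

Integration is explicit Euler at dt = 0.001 ms; the tonic rate of an
uncoupled neuron matches the closed form sqrt(I)/(pi tau) within 2% at that
step and within 10% at dt = 0.01 ms, and the population rate at the working
point changes by well under 2% between the two steps, so the desk-scale runs
use dt = 0.01 ms.  The model LFP is the sum over E neurons of |AMPA| + |GABA|
currents with double-exponential kinetics (rise 0.4/0.25 ms, decay 2/5 ms)
driven through the same connectivity, high-pass filtered at 1 Hz (4th-order
Butterworth); because I-to-E coupling is all-to-all the GABA current is
common to all E neurons and is integrated once.  A stand-alone synthesizer
propagates the kinetics exactly between impulses and reproduces the
closed-form impulse response at machine precision.

Regime indicators over 25-125 Hz at 0.1 Hz resolution (boxcar Welch
segments of 10 s): normalized spectral entropy; r_gamma = (P_low - P_high) /
(P_high + P_low) over 25-50 / 50-100 Hz, implemented exactly as printed even
though the surrounding prose implies the opposite sign convention; the SD
over time of the mean inhibitory membrane potential; and the mean binary
entropy of per-gamma-cycle firing (p = rate / dominant gamma frequency,
clipped with a warning), E neurons only.  Simulations discard the first
second as transient.

Gamma elements are extracted from the model LFP by the same
wavelet/snippet/patch pipeline, with theta cycles taken from the known 10 Hz
forcing phase (the model has no fissure channel); the wavelet bank's 15 Hz
floor acts as the high-pass, so no EEMD step is needed for the
already-broadband model LFP.  Spike trains are binarized at bins of one
median-gamma period, and a per-neuron balanced boosted-tree classifier
predicts spike presence in a ~100 ms chunk centered on each element's time
from the element's six features, cross-validated over forcing cycles.
Neurons whose labels are single-class (dense firers under this window, or
silent neurons) are flagged and excluded from evaluation rather than scored.
The decodable subgroup is segmented at TP > 0.6 and TN > 0.6; at the desk
scale used here (60 s of activity, 40-150 sampled active neurons) the
subgroup is small but present, outperforms the rest on both TP and TN, and is
distinguished by much higher theta phase concentration.  The full-scale
version of this experiment (hours of simulated activity) is the setting in
which decodable fractions around a quarter of the population were originally
reported; the desk-scale fraction among evaluable neurons lands in the same
range but rests on few neurons.

## Problem sizes

Desk runs use: 60 s recordings at 7 channels with bursts on one interior
channel, EEMD with 8-16 realizations, boosting with 60-100 learners,
network simulations of 20-60 s at dt = 0.01 ms with n = 500 (regime
contrasts) or n = 2000 (working point), and 40-150 sampled active neurons
for spike decoding.  Library defaults keep the full-scale values (2000
realizations, 500 learners, dt = 0.001 ms).

## Known limitations

Waveform-phase landmarks are quantized to 1 ms samples (~2-4 deg at theta
frequencies).  EEMD mode mixing can split low-frequency gamma bursts across
IMFs at small ensemble sizes, which is the dominant recovery-failure mode.
Patch extents depend on the stopping threshold and hence on background
texture; power weighting keeps the feature estimates stable but wide, merged
backgrounds bias weakly toward the grid center.  The alternative-arm labeling
needs arm identity, which only the synthetic behavior provides.  The
membrane-potential SD indicator averages raw potentials, so occasional
near-threshold excursions add noise at small populations.
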