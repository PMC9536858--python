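# Methods

## Response quantification

Net responses subtract the spike count of a matched prestimulus window
(10-s artificial-saliva rinse for taste; an equal-length spontaneous window
immediately before the train for 2-s mouth-light series, since the rinse
does not flow then) from the stimulus-window count, averaged across trials.
Baselines are computed per light condition because activating the
inhibitory network also lowers spontaneous firing. Negative nets are kept
as negative (suppression is real signal, e.g. a cell silenced by sucrose).

The response criterion is the conjunction of a rate clause (net ≥ 1 Hz,
i.e. 10 spikes per 10-s window) and a variability clause (net ≥ 2.5 × the
across-trial sample SD of the baseline counts). "SD of the baseline" is
read as the across-trial SD of prestimulus-window counts, pooled over all
trials of the condition; a per-stimulus variant is available
(`net_response` operates per stimulus group). A single trial leaves the SD
undefined; evaluating the criterion then requires an explicit fallback SD
and otherwise raises — it never passes silently. Documented exceptions
(e.g. a clearly delayed response) are supported only through a
`manual_override` flag recorded in the output, never set automatically.

The multiunit measure integrates binned counts (10-ms bins) through a
first-order exponential filter with a 0.1-s time constant, sums the area
under the integrated trace in each window, and subtracts the baseline AUC
scaled to the stimulus-window length; group normalization divides by the
maximum control response. The operation is linear in the counts and nets
to zero for stationary activity.

## Optotagging

Latency is first-spike time within a half-open 10-ms window from pulse
onset, computed from raw timestamps (no binning). Jitter is the sample SD
of latencies (defined with ≥ 2 followed pulses); the follow fraction
counts pulses with ≥ 1 spike in-window. Repeated trains at the same
nominal frequency are averaged unweighted.

No numeric thresholds are published for calling a unit opsin-driven, so
the classifier defaults are set far inside the reported distributions of
tagged cells (~96% following at 1 Hz, jitter < 1 ms, latency ~6 ms):
follow ≥ 0.75, latency ≤ 10 ms, jitter ≤ 2 ms, evaluated at the lowest
tested frequency (faithful following at 1 Hz is the diagnostic regime).
All three are configurable and the margins to each threshold are recorded
so borderline calls are auditable. Whether entrainment should be required
at every tested frequency was an open choice; the lowest frequency was
chosen because high-frequency following degrades even in genuine
opsin-expressing cells.

## Breadth of tuning, clustering, ensembles

Entropy uses K = 1.43 with log base 10, which maps a uniform five-stimulus
profile to ≈ 1 (1.43 ≈ 1/log₁₀5). Responses ≤ 0 are replaced by
10⁻⁶ × (sum of positive responses) before forming proportions; the factor
is configurable. The noise:signal ratio floors negative responses at zero
and takes its exclusion list (the umami cocktail, whose sodium and
glutamate constituents make a sideband reading inappropriate) from the
panel, not from code.

Clustering uses 1 − Pearson r distances with average linkage
(scipy's implementation; verified against a direct O(n³) agglomeration in
the tests). Constant profiles have no defined correlation and are excluded
with a logged record. The number of clusters is a user choice informed by
the scree of amalgamation distances; a largest-gap heuristic is provided
but nothing is cut automatically by default.

The ensemble analysis correlates stimulus vectors across neurons within
and between light conditions and embeds 1 − r distances by classical
(Torgerson) MDS — a deterministic eigendecomposition, preferred over
stress-minimizing variants because downstream comparisons need exact
reproducibility. Coordinates are centered and each axis's sign is fixed by
requiring the first stimulus nonnegative. Profile correlations use net
responses; with the fixed 10-s window this is equivalent to using rates.

## Gain decomposition

Control responses are sorted descending (ties broken by panel order and
recorded), the light-condition vector is permuted by that same control
ordering — never re-sorted on its own — and both are divided by the
maximum control response. Ordinary least squares of light on control then
gives the divisive component as the slope and the subtractive component as
the intercept. The population-mean scope normalizes and orders each neuron
first, averages the vectors pointwise, and fits the averaged curve; this
is the headline analysis for both taste profiles and mouth-light frequency
series. Per-neuron fits are reported alongside. Points are unweighted (no
per-point SEM propagation). p-values for slope ≠ 1 and intercept ≠ 0 come
from standard linear-model t statistics but are labeled descriptive:
ordered, averaged points are not independent observations.

Negative nets entering normalization are retained by default. An optional
clip-at-zero mode mimics the physiological firing floor; clipping raises
the weakest light-condition responses and therefore flattens the low end
of the curve, biasing the fitted slope *downward* relative to the true
divisive factor and the intercept upward — the tests pin this direction.

## Lick analysis

The modal ILI is the center of the tallest 5-ms bin of the interlick
histogram restricted to a 50–250 ms within-burst band (ties to the smaller
bin); band and bin width are configurable — the band excludes pauses and
double-cranks, and 5-ms bins balance resolution against per-bin counts. At
least 100 in-band ILIs are required. The standardized lick ratio divides
trial licks by access-duration/modal-ILI; sessions where any stimulus was
sampled on fewer than two trials are excluded with a log entry. Aversive
stimuli use the water-relative ratio (per-concentration mean licks over
the session's mean water licks; zero water licks flags the ratio
undefined).

Logistic fits use multi-start nonlinear least squares: Min/Max start at
the data extremes, LogEC50 on a grid spanning the tested range, Hill
slopes of both signs; the best residual wins and total failure returns a
convergence flag instead of raising (some stimuli genuinely cannot be
fit). Group-mean curves are fit by default (per-mouse fitting is a
caller-side option). Bonferroni-adjusted paired t tests per concentration
are thin orchestration over standard routines.

## Synthetic data

Spike generation is piecewise-homogeneous Poisson (the minimal model
consistent with count-based analysis), with an optional 1-ms refractory
pass (default on). Defaults are calibrated to the study conditions:
G−TASTE spontaneous ≈ 1.2 Hz (the rinse-period firing scale) with best
evoked rates lognormal around 5 Hz (CV 0.4) on chemosensitive templates
mixed 24:14:13:3 (sweet/umami, sodium, electrolyte-generalist, bitter);
G+TASTE cells at 0.37 × those rates; G+UNR cells silent to taste with
near-zero spontaneous rate. ChR2 units follow each brain pulse
independently (follow 0.96) spiking at Normal(5.9, 0.72) ms. Brain light
multiplies evoked rates by g (default 0.5, matching ~50% suppression of
best responses) and optionally subtracts an offset β, clamping at zero
with a warning; spontaneous rates are suppressed by a separately
configurable gain (default = g). Light spans the prestimulus window by
default since light-condition baselines are measured separately; a flag
restricts it to the stimulus window. Mouth-light entrainment uses a
per-pulse follow probability p(f) = p_max / (1 + (f/25)²), so entrained
counts rise with frequency, saturate near 10–20 Hz and decline above.

Lick sessions draw per-trial target lick ratios from the mouse's logistic
(sucrose-like defaults: Min 0.05, Max 0.95, EC50 228 mM saline / 252 mM
CNO, Hill 1.5 — steepness is not published; 1.5 is a typical brief-access
value) plus Gaussian noise (SD 0.05), convert to counts via the modal ILI
(default 115.5 ms, SD 12 ms), and lay timestamps at Normal ILIs truncated
above 50 ms with optional pauses.

One master seed drives per-unit/per-mouse substreams
(`SeedSequence(entropy=seed, spawn_key=…)`), so identical inputs are
byte-identical and adding a neuron does not perturb the others.

**What the generator does not emulate:** bursting and serial dependence
within spike trains, adaptation across the 10-s window, response latency
dynamics, correlated noise across simultaneously recorded units,
stimulus-order effects, and session drift in lick rhythm. Passing recovery
tests therefore demonstrate correctness of the analysis chain under the
assumed count statistics, not robustness to every structure present in
real recordings.

## Problem sizes in the checks

The simulation-based checks use 100 replicate datasets of 40 neurons for
divisive recovery, 40 replicates for subtractive recovery (evoked rates
spaced ~3 noise-SD apart so the control ordering is stable, keeping the
construction purely subtractive), 500 units for optotag accuracy, 1,000
simulations per operating-characteristic bound, and 200 replicate lick
studies (6 concentrations × 4 trials) for EC50 recovery — sizes chosen so
medians and rates are stable while the whole suite runs in well under a
minute of simulation time.

## Known limitations

- The criterion's variability clause depends on baseline rate; its
  false-positive rate is bounded, not constant, across spontaneous rates.
- Ordering by noisy control responses induces a small selection bias in
  the population-mean gain fit when response spacing approaches the noise
  scale; recovery tolerances account for it.
- Classical MDS embeds 1 − r dissimilarities, which are not generally
  Euclidean; negative eigenvalues are truncated at zero.
- The G+MECH class is a label stub: oral-somatosensory responses are
  flagged by the caller, not simulated.
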