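# Methods

## Problem and protocol

The target event is an acute hypotensive episode (AHE): a 30-minute window
of a minute-sampled mean-arterial-pressure (MAP) series with at least 27
values ≤ 60 mmHg. Detection scans every 30-minute window left to right
(stride 1 minute) and reports the earliest qualifying window; windows with
any missing minute are skipped so the 27-of-30 count keeps its exact
meaning. Per-second inputs are reduced to minute means; empty minutes stay
missing and are never interpolated. Note a block of 30 consecutive low
minutes first qualifies three minutes early (27 lows + 3 leading normals),
so a detected onset is the first *window start*, not the first low sample.

Records are truncated strictly before their first detected onset, then
filtered: at least 360 present minutes of MAP, and (for positives) onset no
earlier than minute 300. Windows are half-open, 0-based minute intervals.
For positives the anchor is the onset; for negatives it is the record end
by default (a seeded-random alternative exists for simulation studies, as
the source protocol does not pin this down). The prediction window is
`[anchor−P, anchor)`; observation and test windows (lengths O and T) both
end at `anchor−P`. A window mean is usable when at least 90% of its minutes
are present (`coverage_floor=0.9`, chosen to mirror the 90% spirit of the
episode definition); placement fails for records shorter than
`P + max(O, T)` before the anchor.

Online rounds beyond the first assign each patient successive
non-overlapping observation windows. These step *backward* in time
(round r covers `[anchor−P−rO, anchor−P−(r−1)O)`), because stepping forward
from the canonical window would intrude into the prediction window; a
patient drops out of rounds its record cannot accommodate.

## The classifier

Per vital, training data are per-patient observation-window means `y_A`,
`y_NA`. Class statistics use the population convention (divisor n)
throughout and are maintained by single-pass recurrences

```
μ(n) = μ(n−1) + (x − μ(n−1))/n
ν(n) = [(n−1) ν(n−1) + (x − μ(n−1))(x − μ(n))]/n
```

so an incremental pass over any partition of the data reproduces the batch
statistics to ~1e-9 (tested over random ≤10-round partitions).

The boundary multiplier κ must satisfy `μ_A + κσ_A < μ_NA − κσ_NA`
(strictly), i.e. κ < κ_max = (μ_NA − μ_A)/(σ_A + σ_NA). The objective
n₁+n₂+n₃+n₄ (misclassified-by-boundary plus inside-the-interval counts,
with *strict* inequalities: a value exactly on a boundary is neither
misclassified nor inside) is piecewise constant in κ, changing only where a
boundary crosses a data value. `fit_kappa` therefore evaluates it on every
plateau — all breakpoints, all plateau midpoints, plus a 201-point equally
spaced grid — using sorted-array counting, O((K+n) log n), and returns the
exact global minimiser with ties broken toward the smallest κ. A fixed
grid alone was measured to miss narrow optimal plateaus on ~1% of Gaussian
instances, which is why the plateau enumeration is the default; the
equally-spaced grid size remains a parameter (`kappa_grid_size`) for
continuity with the simple heuristic. When both σ vanish, κ_max is capped
at 10⁶ and the tie-break yields κ* = 0. When μ_A ≥ μ_NA no κ ≥ 0 is
feasible; the model is flagged degenerate and every prediction takes the
distance path.

Classification of a test-window mean z: below the lower boundary → episode
region, vote A; above the upper boundary → non-episode region, vote NA;
otherwise (including exact boundary hits) the uncertainty region, where

```
d_A = n_A[(z − μ_A)² + ν_A],   d_NA = n_NA[(z − μ_NA)² + ν_NA]
```

and the vote is NA iff d_A > d_NA (ties → A). This closed form equals the
explicit sum Σ(z − x_i)² over all stored class coordinates (an algebraic
identity, tested to 1e-9). The count factors bias the comparison toward
the larger class; a count-free variant (`distance="mean"`, the per-point
mean squared deviation) is available but not the default — the summed form
is the more precise statement of the source equations, whose prose says
"mean squared deviation" while the displayed algebra is the sum. Two
printed-source inconsistencies are resolved class-consistently: the
distance for class A uses ν_A (not ν_NA), and the NA-class spread is
computed from the NA vector.

Multi-vital models train one classifier per vital and combine votes by
simple majority, ties broken by the MAP vote; MAP is mandatory. κ* is
refit after every online round (the alternative — freezing it — is not
supported; refitting needs the coordinate multiset, which the model
retains alongside the 7-tuple precisely for this purpose, while prediction
uses only the summaries).

## Evaluation protocols

Sensitivity = TP/(TP+FN) with class A positive; specificity = TN/(TN+FP);
accuracy = (TP+TN)/n. Offline evaluation is stratified 5-fold
cross-validation (seeded fold assignment) pooling confusion counts over
folds. The online protocol draws a seeded initial training subset —
`round(fraction·n)` patients split between classes at a given ratio with
nearest-integer rounding, at least 2 per class — then streams the
remaining patients in seeded random order, classifying each from its test
window *before* revealing its label and updating the model with its
observation window (default batch size 1, i.e. one online round per
arrival). The grid runner evaluates every [O, P, T] triple of the default
grids O,T ∈ {20,40,…,120}, P ∈ {5,10,…,120} (864 settings) independently
and reports across-settings mean and SD, labelled as such (dispersion
across settings, not across patients or folds). Region-wise breakdowns
attribute each prediction to the MAP model's region (the tie-break vital),
since a patient-level region is undefined under multi-vital voting.

## Synthetic cohorts

The generator emulates the structure the classifier exploits, not
physiology. Each patient's MAP is Gaussian noise (sd 6 mmHg) around a
personal baseline (85 ± 2 mmHg). Episode-bound patients run ~10 mmHg lower
throughout (emulating the markedly lower pre-event window means seen in
real episode patients) and decline linearly (0.5 mmHg/min) from a drift
onset ≥ minute 360 to a 45-mmHg plateau, producing a sustained sub-60
stretch; drift onsets are late enough that truncated records still pass
the 6-hour and 5-hour filters. A configurable fraction (default 15%) of
"fluctuators" in both classes ride a ±21 mmHg sinusoid (period 50 min)
around a 6-mmHg-lowered baseline: they dip below 60 transiently — never 27
of 30 minutes — and their window means land near the decision boundaries,
populating the uncertainty region. Auxiliary vitals (HR, PUL, RR, OSAT)
are class-uninformative noise by default, so adding them degrades the
majority vote as in the source study; an `informative_shift` knob creates
the opposite regime. Class labels come from running the episode detector
on the generated series, not from the generator's intent (intent is
available separately), so label consistency is guaranteed by construction
and detector/generator agreement is itself tested (≥95% of intended
positives are detected).

What passing tests on these cohorts show: the pipeline's bookkeeping,
boundary learning, online equivalence and protocol logic are correct under
a data-generating process satisfying the classifier's assumptions
(class-separated window means with a boundary-adjacent subpopulation).
What they do not show: performance on real ICU data, with its artifacts,
irregular sampling, non-Gaussian noise and heterogeneous baselines.

A behaviour worth knowing: when class window means overlap smoothly (no
density gap between classes), the objective's interval-count terms drive
κ* toward κ_max and the uncertainty interval collapses to near-zero width,
so few cases reach the distance rule. With bimodal-gap structure the
interval survives. Both regimes occur across the default grids.

## Problem sizes and numerics

Default test/acceptance sizes: 500-patient cohorts for recovery checks,
200 patients for the full 864-setting grid (seconds of runtime), 1,000
random series for detector–oracle equivalence, 100 instances for the κ
oracles. Incremental-vs-batch and distance-identity checks use absolute/
relative tolerance 1e-9; boundary membership is exact (strict
inequalities); model JSON round-trips at double precision bit-stably.

## Limitations

- The mixed-integer exact formulation for κ is out of scope; the exact
  plateau enumeration minimises the same count objective but over the
  continuous κ range, which is equivalent here.
- Baseline classifiers (SVM/RF/KNN/AdaBoost/mean-threshold) and
  significance testing between classifiers are out of scope.
- Windows are time-based only; measurement-count windows are not
  implemented.
- No artifact cleaning beyond minute resampling; waveform-level data are
  out of scope.
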