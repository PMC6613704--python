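# Methods

This note records the model as implemented, the defaults and why, the
numerical conventions, and what the synthetic-data experiments do and do
not show.

## Agents, signals, perception

A population holds `N` presenters and `N` detectors, `N` equal to the
(possibly replicated) feature count. Presenters split into two subtypes
by the detector digit (1/2) they prefer; detectors split evenly by the
digit they display. Feature values map to presenter signals through the
affine map onto `[i, i+1)` with the training-set extremes; `ε` is the
machine epsilon scaled by the training range, so the maximum maps just
below `i+1`. Values outside the training range clip into the presenter's
interval; their empirical CDF evaluates to 0 or 1, so every detector with
`v > 0` on the matching side perceives them as rare — out-of-range values
are exactly the "signals never displayed during training".

The empirical CDF is right-continuous, `F(x) = #(train ≤ x)/n`, and tail
tests use strict inequalities (`F < v` left, `F > 1−v` right). Each
(detector, presenter) edge draws its own tail probability
`v ~ Uniform(0, v_max)` and side; replicated feature columns share one
CDF fit (copies are identical) but get independent perception draws,
which is what makes replication informative: one outlying feature is
examined by several independent detector ensembles.

Feature replication tiles the columns the smallest *even* number of times
`k` with `k·N_f > 32` (tables already wider than 32 are left alone). Below
roughly 32 presenters the pairing dynamics can lock into stable
matchings, which would blind the detector; evenness keeps presenter
subtypes balanced across the replicas of every feature.

## Pairing dynamics

One global iteration visits all `2N` agents in a fresh uniform random
order (the update order is otherwise unspecified; a fresh permutation
avoids any systematic presenter-before-detector bias). Each visited agent
draws one uniform counterpart from its interaction set — a detector one
of its `C` presenters, a presenter one of the detectors covering it, the
current partner not excluded (a self-draw fires no branch). The decision
rule has exactly four branches: both alone → pair; one paired → switch
only on the paired agent's strict preference for the newcomer; both
paired → switch only on mutual strict preference. Ages of all broken
pairs reset to zero; every intact pair then ages by one, so a pair formed
in an iteration has age 1 after it. Presenters rank only the displayed
digit, so two detectors with the same digit are indistinguishable to
them and can never poach from one another.

Detector ILists order the `2C` frequent/rare tokens of their connected
presenters. Rare tokens of opposite-subtype presenters are pinned to the
bottom ranks and never educated: were they educable, the absence of a
frequent signal could be compensated by its rare twin and detection of
absences would be blunted.

## Training

The education loop follows the adaptive-threshold schedule: `τ_n` starts
at the window length `W_τ`; every `T_S` iterations a uniformly drawn
training sample is displayed (uniform redraw rather than a fixed cycle,
so corrections depend on many samples); after each iteration every
detector paired for `τ ≥ τ_n` is educated and unpaired; at the end of a
window with no educations, `τ_n` tightens to the window's maximum
observed pairing age (a running maximum over the window). `τ_n` is
therefore nonincreasing. Both stopping rules are exposed: a window budget
`t_max` and an optional threshold target `τ_target`.

IS education re-permutes the educable region uniformly; AIS draws a rank
uniformly from those strictly below the offending token (within the
educable region) and swaps the two entries, so the offender strictly
loses rank on every call. In the degenerate case where the offending
token already sits at the last educable rank, no swap is possible and the
unpairing alone removes the stable pair. Educated detectors re-enter the
dynamics immediately. A repertoire is `N_pop` educations of the same
connectivity and perception maps from independent RNG streams and fresh
random initial ILists.

## Detection

Monitoring fills each detector slot with a uniformly drawn repertoire
member and runs the sweep with anergy: any pairing reaching age `τ_A` is
terminated, both members' counters increment at `τ_A`, and the slot is
refilled by a fresh random member. Counter semantics: each paired agent
increments `c` at its current age and then ages, so `c(0)` counts contact
events, `c(t)` contacts surviving at least `t` iterations, and
`c̃ = c(τ_act)/c(0)` is a survival fraction in `[0,1]` (defined 0 for a
presenter that never paired). Only presenter-side counters enter the
response; detector-side counters are kept for diagnostics.

Calibration normalizes first and takes quantiles second, so thresholds
are dimensionless like the response requires. All descending quantiles
use the 1-based index `x = ⌈count · fraction⌉`, uniformly for the
calibration fraction `f` and the operating `FPR`; anomalous samples count
as detected when strictly above the threshold score. Each test sample is
monitored with a fresh repertoire draw and RNG substream.

A structural note on calibration: with per-presenter thresholds at the
`f`-quantile, each presenter exceeds its own threshold on a fraction
≈ `f` of calibration samples *by construction*, but the response is a
union over presenters. Unless the same few samples dominate every
presenter, far more than a fraction `f` of calibration samples end up
with `R > 0` (measured ≈ 0.8 at the desk-scale defaults). A small
positive response is therefore ordinary; only the upper tail of the
normal response distribution is meaningful, which is why accuracy is
always reported at a fixed FPR on held-out normal samples.

## Parameters

| symbol | default | meaning |
|---|---|---|
| `v_max` | 0.05 | cap of the per-edge rare-tail probability; 0 detects nothing rare, large values blur frequent/rare |
| `N_pop` | 12 | repertoire size; more members raise the chance some IList ranks a never-seen token high |
| `C` | 20 | detector connectivity (capped at `N`); moderate values balance ordering quality against interaction dilution |
| `W_τ` | 10⁴ iter | education window; also the initial `τ_n` |
| `T_S` | 100 iter | sample-change period; `W_τ/T_S ≈ 100` bases corrections on many samples |
| `W_d` | 10⁴ iter | monitoring window per sample; controls counter statistics |
| `τ_A` | 5 iter | anergy time; ≥ 2 or no kinetic proofreading happens |
| `τ_act` | `τ_A` | survival age entering the response |
| `f` | 0.1 | calibration quantile fraction |
| `FPR` | 0.1 | operating false-positive rate |

## Synthetic data

The generator draws normal samples from per-feature marginals (Gaussian
or uniform) coupled by a Gaussian copula with configurable pairwise
correlations, and produces anomalies by three mechanisms: a single
feature pushed beyond the normal empirical range (`outlier`),
`⌈N_f/4⌉` features moved simultaneously into their 2% marginal tails
(`excess_absence`), and independent permutation of the second member of
each correlated pair (`broken_combination`), which preserves marginals
exactly while destroying co-occurrence.

Defaults: 4 features (an iris-shaped table, replicated ×10 to 40
presenters), 600 normal samples (400 train / 200 test), 100 anomalous,
two correlated pairs at ρ = 0.9, outlier magnitude 0.5 × range. Two
constraints shaped these numbers. First, replication is what gives a
single outlying feature measurable weight, as with the narrow real
tables the method targets; a wide table of independent features dilutes
one outlier to 1/N_f of the evidence, and measured outlier recovery
falls from ≈ 0.85 TPR at 4 features to ≈ 0.25 at 40. Second, the rate
at which *normal* test samples naturally exceed the training range
(≈ `2·N_f/n_train`) must stay well below the operating FPR, otherwise
the 90th-percentile normal sample is itself an outlier-bearing sample
and single-outlier anomalies are indistinguishable at that operating
point by construction.

What passing synthetic tests do *not* show: real data have dependent,
heavy-tailed, non-stationary features; the copula tails here are thin
(a Gaussian copula has no asymptotic tail dependence), so the
`broken_combination` mechanism produces only weak rare-token
co-occurrence at `v_max = 5%`. At desk scale the response to such
anomalies is statistically indistinguishable from the normal response
(measured presenter-level survival differences of < 2% between seen and
novel tail combinations), and the counting-rule baselines sit at or
below the nominal FPR on them for a separate reason (integer count ties
at the threshold). Claims of combination-specific detection should rest
on data with strong tail co-occurrence, which these defaults do not
provide.

## Desk-scale choices

Tests and the acceptance script run everything at reduced problem sizes,
stated here as package choices: education windows `W_τ = 2000` with
`τ_target` 100–180 and window budgets of a few hundred (detection
pipelines) to a thousand (the IS/AIS timing comparison, whose IS runs are
right-censored at the budget and reported as such); monitoring windows
`W_d = 2000`; repertoires of 4 populations; 2–3 Monte-Carlo folds. The education-theory simulators use 10⁴ replicates. The IS list
simulator draws replacement lists from an unlimited item pool (each
position equally likely either type) — the reading under which the
binomial education chain is exact, and the immunological one (a new cell,
not a reshuffle); a `finite_pool` variant permutes the fixed half-and-half
list and is biased upward at small `N` (hypergeometric top compositions).
The AIS chain uses the printed 1/2-approximation for the education-state
split; the explicit finite-list simulator is the finite-`N` reference,
with relative bias of order `n/(N−n)`.

## Known limitations

- Two-sided detectors (rare on both tails simultaneously) are not
  implemented; each edge is one-sided.
- The education theory covers a single IList; interacting ILists in a
  population are handled only empirically by the training module.
- Combination-break (mechanism 3) sensitivity is weak at the default
  tail sizes; see above.
- `decide`/`iterate` are exposed per-agent for inspection and testing,
  but trajectory-scale work goes through the batched kernels; per-call
  Python overhead makes long pure-Python loops impractical.
- The anomalous class never influences training or calibration, but the
  ROC evaluation assumes a held-out normal test set is available to set
  the score threshold.
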