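# Methods

## Analysis chain

Each trial is a set of sorted spike timestamp sequences, one per
recording site, over a common duration (3 min by default).  The
connectivity workflow proceeds per trial:

1. **Binning.** Spikes are counted on a half-open grid
   `[k·w, (k+1)·w)` with `w = 0.1 s` by default; only complete bins
   are kept (`n_bins = floor(duration/w)`, float-tolerant) and spikes
   past the last complete bin are discarded with a logged count.
2. **Active sites.** Channels with mean firing rate ≥ 0.1 Hz
   (boundary inclusive).  The threshold is configurable; active-node
   filtering precedes all pairwise statistics.
3. **Synchrony.** Sample Pearson correlation between binned count
   vectors of active channel pairs.  Counts (not waveforms) are the
   standard reading for sorted spike data.  Pairs involving a
   zero-variance channel are *undefined* and carried as NaN, never as
   zero; they can never become edges.
4. **Functional graph.** An undirected edge for every pair with
   `r ≥ 0.3` (configurable).  The raw coefficient is used: no
   significance filter, and negative correlations are not treated as
   functional connections.  Isolated active channels remain nodes.
5. **Communities.** Louvain maximisation of weighted modularity at
   resolution γ = 1.  The implementation alternates seeded local
   moving (shuffled visit order; a move is taken only for a strictly
   positive gain; ties keep the current community, else the lowest
   community index) with graph aggregation, asserting that Q never
   decreases across passes.  Because greedy local moving can stall in
   shallow local optima on small graphs, the public `louvain()` runs
   10 deterministic restarts seeded from sub-streams of the user seed
   and returns the best-Q partition; the result is a pure function of
   (graph, γ, seed).
6. **Affiliation sequences and similarity.** Community labels are
   arbitrary, so each partition is canonicalised by scanning channels
   in a fixed lexicographic order and assigning `A` to the first
   community encountered, `B` to the second, and so on; channels
   inactive in a trial receive the reserved symbol `-`, keeping the
   sequence length constant across trials.  Network similarity between
   a trial and its immediate predecessor is
   `1 − levenshtein(a, b)/max(|a|, |b|)` with unit edit costs, which
   equals `1 − d/n_channels` under constant length.  Label-permuted
   partitions map to identical sequences by construction.

The firing-pattern workflow computes, per trial: per-channel rates and
the network mean firing rate (silent declared channels count as 0 Hz);
the joint ISI histogram — consecutive interval pairs
(ISI_k, ISI_{k+1}) pooled over channels on log10-spaced edges (1 ms to
10 s, 50 bins per axis); short-interval metrics; burst metrics; and
the synchrony summaries plus the activity index (edge count × mean
edge weight, 0 for an edgeless graph).

**Short-interval convention.** "Spikes within 50 ms" is
operationalised as joint-ISI pairs whose *both* coordinates are
≤ 50 ms (the return-map reading); `mode="single"` switches to counting
individual ISIs ≤ 50 ms.  The pair reading is the default because it
ties the count to the joint ISI distribution from which it is
reported.

**Burst criterion.** Fixed-threshold run method: a maximal run of
spikes whose internal ISIs are all ≤ 100 ms, kept when the run has
≥ 3 spikes.  Burst spike rate is the fraction of all spikes (pooled
over channels) inside bursts.  Both parameters are configurable and
are echoed with every report; the metric is monotone (non-increasing
in the minimum run length, non-decreasing in the ISI threshold), which
the tests sweep.

**Baseline recovery.** Two recordings compare as recovered when
`|MFR_post − MFR_base| ≤ 0.2 · MFR_base` (boundary inclusive); the
ratio is reported alongside the verdict.

## Exact small-sample statistics

Experiments of this kind compare 3–6 trials or electrodes per group,
so the rank tests use exact null distributions rather than asymptotic
approximations:

* **Mann–Whitney U** (independent samples): `U = min(U_x, U_y)`, the
  exact null of U_x by the classical count recurrence for
  `n1 + n2 ≤ 25`; with ties, an exact permutation enumeration over
  group assignments (up to 10^5 arrangements) on mid-ranks, tails
  taken on the unfolded U_x; beyond both limits, the normal
  approximation with a logged notice.
* **Wilcoxon signed-rank** (paired): zero differences dropped,
  |differences| mid-ranked, `W = min(W+, W−)`, the exact null of W+
  over all 2^n sign patterns (n ≤ 20; mid-ranks doubled to keep tied
  rank sums integral).
* The two-sided p is twice the smaller tail probability, capped at 1.
* `Z` uses the min-statistic with neither continuity nor tie
  correction (both available by flag), and the effect size is
  `r = |Z|/√N`.

These conventions jointly reproduce the two worked examples the module
is validated against: complete separation at n = 5 per group gives
U = 0, p = 2/252 ≈ 0.008, r = 0.83; three same-sign pairs give W = 0,
p = 2/8 = 0.25, r = 0.93 (|Z| is invariant to using W+ = 6 or W− = 0).

## Stimulation safety

For a voltage-controlled biphasic pulse the per-phase charge is
estimated from the scalar impedance magnitude, `Q = (V/Z)·t_phase`
(the charge-balanced second phase recovers it), the geometric density
is `D = Q / (π(d/2)²)`, and the Shannon criterion
`k = log10(D in µC/cm²) + log10(Q in µC)` is compared against the 1.5
damage threshold (verdict boundary inclusive).  No electrode
equivalent-circuit fitting is attempted.  Note that the reference
pulse (0.3 V, 9 kΩ, 200 µs, 30 µm) yields k ≈ 0.80 from its own Q and
D; the report always prints all three quantities so the arithmetic is
auditable.

## Synthetic recordings

No public recordings exist for the study designs this package
analyses, so a doubly-stochastic (Markov-modulated Poisson) generator
stands in for them.  It was chosen because it produces the two
features the analyses need — bursts and tunable pairwise synchrony —
with closed-form expected rates.

Each of K communities carries a two-state on/off continuous-time
Markov modulator (on-rate λ_on = 0.2/s, off-rate λ_off = 2/s, i.e.
~9% duty cycle with 0.5 s mean bursts); one global modulator is shared
by all channels.  Channel i fires as an inhomogeneous Poisson process,

    r_i(t) = base · rate_mult · (1 + a_within · sync_mult · m_c(i)(t)
                                   + a_global · g(t)),

sampled exactly by thinning against the analytic maximum; modulators
are simulated event by event, never time-discretised.  Defaults:
60 channels in 4 equal contiguous communities, base rate 1 Hz,
3-minute trials, a_within = 12 (within-community synchrony ≈ 0.35 at
100 ms bins, so control trials produce a connected functional graph at
the 0.3 threshold), a_global = 0.5.  All defaults are invented and
documented here; the package's claims rest on directions and built-in
monotonicity, not on these magnitudes.

**Stimulation effects** enter as multipliers on the base rate, the
within-community coupling, and the modulator on-rate.  For 40 Hz,
`mult(N) = max(floor, 1 − g78, 1 + g40 − c40·log10(N/100))` with
defaults g40 = 0.5, c40 = 0.4, floor = 0.7; for 7.8 Hz the constant
`1 − g78 = 0.7`.  Clamping the 40 Hz curve at the 7.8 Hz level makes
the between-frequency gap non-increasing in the pulse count for every
parameterisation — the adaptive-convergence behaviour is guaranteed by
construction and verified as a property test.

**Disrupt/stabilize series** (control, 3× disrupt, 3× stabilize,
control): disrupt trials lower the within coupling to 4 and add a
strong global modulator (a_global = 14), yielding many weak
correlations spread over all pairs (r ≈ 0.35, ~1500+ edges) and
unstable partitions; stabilize trials raise the within coupling to 20
with no global term, yielding fewer, stronger within-community edges
(r ≈ 0.5, ~420 edges) and reproducible partitions.  These couplings
were fixed in a design-phase pilot to realise the two qualitative
regimes; the tests assert only directions across seeds, never the
magnitudes.

**What the generator does not emulate:** spike-sorting artefacts,
electrode cross-talk and volume conduction, non-stationary development
of the culture across a session, inter-trial history effects (trials
are conditionally independent given their condition, although the
recovery intervals of the real protocol imply carry-over), refractory
periods, and biophysical burst shapes.  Passing the directional tests
therefore shows that the analysis chain detects these effects when
present in the assumed model class — not that real cultures behave
this way.

## Problem sizes and numerical choices

* Simulation studies: 50 seeded disrupt/stabilize series, 30 seeded
  rhythmic series (paired across frequency and pulse level within a
  seed), directional claims tested with one-sided sign tests at
  α = 0.05 plus a ≥ 90%-of-seeds margin.  The whole suite runs in
  about half a minute on one CPU.
* Planted-partition recovery: adjusted Rand index of Louvain-recovered
  vs planted communities at weak coupling (a_within = 1.5) on 50
  runs.  At 3-minute trials this coupling is information-limited: the
  Pearson estimates' sampling noise, not the algorithm, caps recovery
  (mean ARI ≈ 0.83 across reasonable bin widths).  The recovery check
  therefore uses 600 s recordings with 0.5 s bins and a positive-
  correlation graph, isolating algorithmic recovery from finite-sample
  noise; there recovery is essentially perfect (ARI ≥ 0.9 in ≥ 90% of
  runs).
* Ties and degenerate inputs: zero-variance channels give NaN
  correlations (warned, excluded from means and edges); an edgeless
  graph is an error for Louvain and modularity (Q undefined), reported
  with the trial id; fully tied rank-test data yield p = 1 rather than
  an error.
* Tolerances: modularity oracle agreement at 1e−10; Louvain
  near-optimality at 1e−9 of the enumerated maximum; exact-p oracle
  agreement at 1e−12; Q-monotonicity asserted per pass at 1e−9.
* Determinism: simulation output is byte-identical per seed after
  canonical writing; Louvain and the pipeline are pure functions of
  their seed; every report row embeds a hash of the analysis
  configuration (excluding the output directory) so artefacts from
  different configurations cannot be silently mixed.

## Known limitations

* The Pearson-on-counts synchrony is sensitive to the bin width; 100 ms
  is a convention, not a recovered constant, and all outputs record
  the width used.
* The edge threshold (0.3) has no significance calibration; edge
  counts are therefore comparable only within a fixed configuration.
* Louvain is a heuristic: even with restarts it can miss the global
  modularity optimum (observed on ~2–5% of tiny adversarial graphs),
  and modularity itself has a resolution limit at γ = 1.
* Exact tests fall back to the normal approximation beyond
  n1 + n2 = 25 (Mann–Whitney) or n = 20 nonzero pairs (Wilcoxon).
* The affiliation-sequence construction (node order, inactive symbol,
  normalisation) is a declared convention; other conventions would
  change similarity values, though not the disrupt/stabilize ordering
  the tests assert.
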