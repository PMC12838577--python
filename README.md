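# meanet

Spike-train network plasticity analysis for multi-electrode array (MEA)
cultures.

Cultured neuronal networks on MEAs (~60 recording sites) reorganise
their functional connectivity under patterned electrical stimulation:
low-frequency asynchronous pulses disrupt existing connectivity, while
high-frequency synchronous pulses stabilise it, and rhythmic
stimulation at theta (7.8 Hz) versus gamma (40 Hz) frequencies modulates
firing patterns with effects that converge as the pulse count grows.
`meanet` packages the analysis chain needed to quantify these effects
from spike timestamps, for electrophysiologists and network
neuroscientists working with sorted MEA recordings.

## What it computes

Given per-trial spike tables (`channel,time_s` CSV) and an ordered
trial manifest:

1. **Synchrony** — binned spike counts (default 100 ms bins), pairwise
   Pearson coefficients `r_ij` over active channels (mean firing rate
   ≥ 0.1 Hz), and a functional graph with edges where `r_ij ≥ 0.3`.
2. **Subnetworks** — weighted-modularity Louvain community detection,
   maximising `Q = Σ_c [Σ_in(c)/2m − γ(Σ_tot(c)/2m)²]` with seeded
   deterministic restarts.
3. **Network similarity** — each partition becomes a canonical
   *affiliation sequence* (symbols assigned by first appearance in a
   fixed channel order; inactive channels get `-`), and consecutive
   trials are compared by normalised Levenshtein distance:
   `similarity = 1 − d(a, b)/max(|a|, |b|)`.
4. **Firing patterns** — joint ISI (return-map) histograms on log
   bins, 50 ms short-interval pair counts and proportions, per-channel
   rates and network MFR, fixed-threshold burst detection (ISI ≤ 100 ms,
   ≥ 3 spikes) with burst spike rate, and an MFR baseline-recovery
   check.
5. **Activity index** — number of functional connections × their mean
   synchrony coefficient, summarising overall network state.
6. **Exact statistics** — small-sample Mann–Whitney U and Wilcoxon
   signed-rank tests with exact two-sided p (doubled smaller tail of
   the enumerated null) and effect sizes `r = |Z|/√N`.
7. **Stimulation safety** — charge per phase `Q = (V/Z)·t`, geometric
   charge density `D = Q/area`, and the Shannon criterion
   `k = log10(D) + log10(Q)` against the 1.5 damage threshold.

A Markov-modulated Poisson generator (`meanet.synthetic`) produces
multichannel recordings with planted community structure, bursts and
stimulation-condition effects, so the whole chain is testable without
access to recordings.

## Worked example

Simulate the eight-trial disrupt/stabilize design and run the
connectivity workflow:

```python
from meanet import synthetic, run_connectivity_series, mann_whitney_exact

gt = synthetic.generate_ground_truth(n_channels=60, k_communities=4, seed=1)
trials = synthetic.generate_disrupt_stabilize_series(gt, seeds=range(8))
report = run_connectivity_series(trials)
cols = ["trial_id", "n_edges", "mean_edge_weight", "similarity_to_previous"]
print(report.per_trial[cols].to_string(index=False))
```

```
   trial_id  n_edges  mean_edge_weight  similarity_to_previous
  control_1      301          0.349282                     NaN
  disrupt_1     1560          0.351895                0.183333
  disrupt_2     1493          0.352705                0.233333
  disrupt_3     1643          0.355681                0.533333
stabilize_1      420          0.522165                0.166667
stabilize_2      420          0.506611                1.000000
stabilize_3      420          0.520164                1.000000
  control_2      333          0.355484                1.000000
```

Disrupt trials flood the network with many weak links (≈1500–1650
edges at mean weight ≈ 0.35) and the community layout keeps
reorganising (similarity ≈ 0.2–0.5); stabilize trials consolidate a
streamlined set of stronger links (420 edges at ≈ 0.51–0.52) whose
partition is reproduced exactly from trial to trial (similarity 1.0).

Exact statistics and pulse safety from the shell or Python:

```python
res = mann_whitney_exact([877.4, 890.0, 860.1, 871.3, 880.8],
                         [9.3, 8.1, 10.2, 7.7, 11.0])
print(f"U = {res.statistic:g}, exact p = {res.p_value:.3f}, r = {res.effect_size_r:.2f}")
# U = 0, exact p = 0.008, r = 0.83
```

```
$ meanet safety --amplitude-mv 300 --impedance-kohm 9 --width-us 200 --diameter-um 30
charge/phase = 6.67 nC; charge density = 0.943 mC/cm^2 (Q in uC and D in
uC/cm^2 enter the Shannon sum); Shannon k = 0.798 vs limit 1.5 -> SAFE
```

Two completely separated groups of five yield the minimal statistic
U = 0; the exact two-sided p is 2/252 ≈ 0.008 with a large effect size
even at this tiny n. The reference biphasic pulse (±300 mV, 200 µs
phases, ~9 kΩ electrode, 30 µm site) stays well below the Shannon
damage threshold.

The CLI also provides `meanet simulate`, `meanet connectivity`,
`meanet rhythmic` and `meanet stats`; see `meanet --help`.

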