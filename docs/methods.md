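# Methods

This note documents the models and procedures implemented in `cultnet`,
the choices behind their defaults, and what the synthetic benchmark does
and does not establish.

## Scope and data flow

The package analyzes spontaneous activity of in vitro neuronal cultures
before and after physical damage.  The analysis chain is

    fluorescence traces -> dF/F -> Schmitt binarization -> event raster
      -> network bursts (IBI, activity A, ratio Phi)
      -> transfer-entropy effective connectivity (directed, unweighted)
      -> graph metrics (degree, global efficiency, modularity, betweenness)
      -> damage protocols (targeted attack / failure; diametral cut)

Real recordings enter as per-ROI trace matrices (CSV or HDF5, 50
frames/s by convention).  Because no public recordings accompany the
studies this pipeline targets, a synthetic culture simulator generates
inputs with the relevant collective dynamics; all downstream stages are
agnostic to the source of the traces.

## Synthetic cultures

**Aggregated cultures** place ~100 aggregates (one ROI each) inside a
6 mm disc.  Aggregates belong to equal-sized modules whose members
scatter (sd 0.7 mm) around spatially separated centers.  A directed
coupling is drawn with probability `p_within` (same module, default
0.35) or `p_between` (default 0.02), both attenuated by
`exp(-d / 1.5 mm)`; weights are log-normal around 1.  The spatial
attenuation matters: it makes burst cascades engage overlapping
neighborhoods instead of one frozen block, which is what gives
betweenness-central aggregates a genuine routing role.  These defaults
are calibrated (at the default size of 100 aggregates) so bursts engage
10-20% of the network.  The connection probabilities set the mean
degree, so desk-scale variants at smaller n keep the cascade
supercritical by raising `p_within` accordingly (the protocol benchmarks
use n = 50, `p_within` = 0.6, `p_between` = 0.06).

**Homogeneous cultures** tile the 7.1 mm field of view with a square ROI
grid (default 40x40); tiles outside the inscribed circle are dropped
(~1257 ROIs remain, matching the ~1300 of real gridded recordings).
Tiles on the 6 mm disc are `disc`, the outermost disc ring is the
`contour` (the wall population the scalpel cannot reach), off-disc tiles
are the `surroundings` on the glass.  Any two ROIs within 2.4 tile
spacings are coupled; disc-surroundings couplings scale with the disc
height h: full strength at h <= 0.7 mm, exactly zero at h >= 3 mm,
linear in between.  The two anchors reflect the experimental designs
(connected at 0.7 mm, fully disconnected at 3 mm); the interpolation is
a modeling choice.

## Cascade dynamics

Activity is a stochastic branching process, not a biophysical neuron
model: only burst-level statistics feed the downstream analysis.  Each
live ROI initiates spontaneously at a Poisson rate (default
0.0015 Hz/ROI aggregated; 1.2e-4 Hz/ROI homogeneous — roughly 0.15
network ignitions/s, IBI ~ 7 s).  A spike transmits along each outgoing
coupling with probability `1 - exp(-beta w)` (beta = 0.26 aggregated,
0.36 homogeneous) after a delay = distance / conduction velocity
(default 1 m/s, i.e. negligible for direct axonal links; slow wave
fronts in monolayers emerge from chains of synaptic hops) plus 2-10 ms
synaptic jitter.  An absolute refractory period of 0.5 s enforces one
spike per ROI per burst without affecting the seconds-scale IBI.  The
spontaneous rate is treated as a per-network quantity: desk-scale
aggregated runs at n < 100 scale the per-ROI rate as 0.15 Hz / n, and
homogeneous rates are defined per ROI at the reference 40x40 tiling and
scale with tile area, so the network ignition rate — the physically
observed quantity — is independent of culture size and analysis grid.

## Fluorescence model

Each spike adds a causal difference-of-exponentials transient (time to
peak 0.1 s, decay constant 1.0 s, GCaMP6s-like) of 20 %dF/F peak;
summed transients saturate at 300 %dF/F.  Traces ride on an arbitrary
baseline (100 a.u.) with additive Gaussian noise of sd 2% of baseline.
Frames are sampled at 50 /s.  These are tunable conventions, not claims
about indicator photophysics.

## Signal layer

F0 per ROI is the 10th percentile of the trace (optionally a running
window); dF/F(%) = 100 (F - F0)/F0.  The Schmitt trigger switches on at
the high threshold and off below the low one.  Automatic thresholds are
the per-ROI trace median + 4 sigma (high) and + 1 sigma (low), where
sigma is a robust noise scale (MAD of the first difference / sqrt 2).
Two details matter.  The median centering compensates the positive
offset a low-percentile baseline leaves in dF/F.  And the high threshold
is 4 sigma rather than the 3 sigma a single-trace analysis would
suggest: at 50 frames/s across >= 100 ROIs, a 3 sigma threshold fires
~7 false onsets per network-second, which the burst chaining rule (below)
occasionally assembles into spurious "network bursts"; 4 sigma pushes the
false-onset rate below one per network-second while remaining far below
the 10 sigma single-spike amplitude.

## Bursts and activity

Event onsets (0->1 transitions) are chained while consecutive onsets are
<= 0.2 s apart; a chain is a network burst when it engages at least
`min_fraction` of live ROIs (0.5 homogeneous, 0.1 aggregated — the
"substantial group" thresholds are conventions, exposed in config).
IBI is onset-to-onset; activity A = 1/mean(IBI); the damage ratio
Phi = A_after / A_before.  Removed ROIs leave the denominator.  For
region-wise analysis of cut cultures, burst detection runs independently
within each region and A is reported as a burst count per recording.

## Effective connectivity

Transfer entropy uses the plug-in (histogram) estimator over binary
words of Markov order 2 with instant feedback (the source word shifted
one bin forward, the calcium-imaging convention), bin width one frame,
no bias correction, negatives clipped to zero, degenerate targets
assigned TE 0.  Significance per ordered pair pools all TE values
sharing the pair's target (column) or source (row) — the pair's own
value counted once — and computes z = (TE - pool mean)/pool sd;
connections with z >= 1 form the directed unweighted effective network.
Removed ROIs are excluded from estimation and from every pool.

Two structural consequences of this rule are worth knowing.  First, at
z >= 1 the upper ~16% tail of any homogeneous pool is accepted, so an
effective network is never literally empty of false positives; genuine
synchrony separates by attaining z far above 1.  Second, the pooled
null penalizes hubs: a node synchronized with many partners fills its
own pools with strong competitors, so individually none of its
connections stands out.  A consequence verified in testing is that a
structural "bridge" aggregate shared by two modules does not surface as
an effective-network bridge; betweenness centrality in the effective
network instead reflects nodes whose connections span otherwise
weakly-linked groups.

## Graph metrics

Degrees, global efficiency and modularity are literal evaluations of the
standard formulas (Geff = mean inverse directed hop distance over
ordered pairs with 1/inf = 0; Q on the symmetrized graph against the
degree-preserving null).  Shortest paths (BFS, the unweighted reduction
of Dijkstra), unnormalized directed betweenness with endpoints excluded,
and Louvain community detection are delegated to networkx and
cross-checked in the test suite against independent brute-force oracles
(Floyd-Warshall; exhaustive shortest-path enumeration; a literal
double-loop Q).  Louvain runs with a fixed seed for determinism; ties in
"most central node" resolve to the lowest ROI id.

## Damage protocols

*Targeted attack vs failure* (aggregated): per step, record and infer
the effective network; pick the target (max betweenness, max degree, or
uniform random); disconnect it (couplings zeroed, ROI flagged removed
but kept in the index so ids stay stable); record and infer again;
log Phi, Geff and Q.  Geff always excludes the step's deleted node from
both pre and post networks so the two are size-matched.  The 24 h
between steps is modeled by one homeostatic recovery application
(strength 0.5).

*Diametral cut* (homogeneous): the wound is a 500 um band through the
disc center.  Disc ROIs inside the band are removed; couplings between
scalpel-reachable ROIs crossing the cut line are severed (contour ROIs
survive but their wound-spanning couplings do not); surroundings ROIs
are untouched.  The initial cut also depresses all surviving disc-side
couplings by an acute trauma factor (default 0.5), modeling the
transient synaptic impairment of mechanically wounded tissue; without
it the surroundings relay transmits every burst between the halves
immediately after the cut and there is nothing for the recovery stages
to recover.  The timeline records at stages before / after / 2 h / 6 h /
24 h / 3 d, applying one homeostatic increment (0.3) between post-cut
stages; region partition A/B (disc halves), wound, C (contour), S
(surroundings) yields per-region burst counts and inter-region
effective-connection counts (directed counts folded symmetric).

*Homeostatic recovery* sprouts new short-range couplings between
surviving, currently unconnected ROIs of which at least one has lost
input -- sprouting is injury-induced, so intact tissue does not keep
densifying (radius 1.2 tile spacings for monolayers, 0.8 mm for
aggregates; probability 0.3 x strength per direction) -- then
multiplicatively rescales each surviving ROI's incoming
weights so a fraction `strength` of its lost total input (relative to
the undamaged culture) is restored — sprouting first, scaling second,
so `strength = 1` restores input sums exactly.  Sprouted
disc-surroundings couplings keep the height-factor scaling: a wall that
blocks growth at h = 3 mm blocks sprouting too.  The quantitative
mapping from biological recovery time to these increments is a modeling
choice; only the monotone growth of cumulative restoration along the
timeline is meaningful.

## Benchmark conditions and problem sizes

The test suite and the acceptance script run everything at desk scale on
one CPU:

- estimator anchors and oracle equivalences on <= 10-node graphs and
  <= 4 ROIs x 64 bins;
- TE recovery at 1e5 bins (lag-copy -> 1 bit; independent -> < 0.01);
- pipeline modularity on 60-aggregate cultures with planted modules,
  15 min simulated recordings, 10 seeds;
- attack/failure protocols on 50-aggregate cultures, 20 min recordings,
  3 steps, 10 seeds per scheme (`run_damage_sequence` also offers a
  common-random-numbers mode that reuses one stream for the pre and post
  recordings of a step);
- cut timelines on a 20x20 grid (316 ROIs), 5 min recordings per stage.

What passing shows: the implementation reproduces, on data whose
generative truth is known, the directional phenomenology reported for
real cultures — modular functional organization (Q >> 0.3), enrichment
of inferred connections for structural couplings, activity ratios within
the observed envelope, modularity rising under targeted attack but not
under failure, and cut cultures reconnecting through the surroundings
reservoir only when the geometry couples them.  What it does not show:
agreement with any real culture's numeric values.  The simulator omits,
among other things, indicator photobleaching and drift, inhomogeneous
ROI sizes, inhibitory neurons, development over days in vitro, and the
minute-scale post-damage activity transient; quantitative results on
real recordings will differ accordingly.

Two directional phenomena reported for real cultures are *not*
reproduced by the synthetic benchmark, and the corresponding tests
document that openly.  First, the per-step drop of global efficiency
under betweenness attack relative to random failure: the deleted node is
excluded from the pre-damage network for size-matching, and excising the
betweenness argmax from the very graph it routes depresses the baseline
by ~10% — at desk scale this measurement artifact exceeds the true
single-node effect (which is visible at the spike level as a reduced
cross-module co-burst fraction).  Second, the late-stage recovery of the
halves' interaction band after the cut: the relayed A-B synchrony
genuinely recovers (the inter-half lag shrinks across stages), but the
rank-like z >= 1 rule excludes A-B pairs as long as any lag separates
them from the directly coupled classes.  Both are properties of the
effective-connectivity readout at these problem sizes, not of the
underlying dynamics.

## Numerical conventions

Frames are 0-based; times in seconds are frame/fps; positions in mm with
origin at the disc center; angles from the +x axis.  Event time is the
first frame of each 0->1 transition.  All generators and protocols are
pure functions of (parameters, seed); seeds split through
`numpy.random.SeedSequence` so every stage draws from an independent
stream.  Degenerate inputs (all-zero traces, < 2 bursts, < 3 live ROIs,
edgeless graphs) raise or signal explicitly rather than returning
silent defaults.
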