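# Methods

## The question and the statistical model

Given a set of sRNA → target-gene relations and one or two cellular
networks — an undirected protein-protein interaction network (PPIN) and a
directed transcription-regulatory network (TRN) — the package asks whether
the targets are topologically unusual. "Unusual" is operationalised
against a single null model: node sets of the same size drawn uniformly at
random from a sampling universe, with every statistic recomputed on each
draw. There is no parametric assumption about the network; the network
itself (held fixed) is the population, and the randomness is entirely in
which nodes are designated targets. This is a conditional Monte-Carlo
test: exact in expectation, with resolution limited only by the replicate
count.

Both networks are simple, unweighted, binary graphs. Self-loops and
duplicate edges are dropped at load time; regulation signs on TRN edges
are parsed but ignored — every statistic here is purely topological.

## Statistics

Node-level (averaged over the mapped in-network targets):

- degree; on the directed network split into in-degree and out-degree;
- closeness: 1 / mean shortest-path distance from the node, averaged over
  *reachable* nodes only, 0 if none are reachable. Averaging over
  reachable nodes keeps the value finite on fragmented interaction maps
  without a penalty-distance convention. Harmonic closeness (mean of
  reciprocal distances) is available behind a switch but is not the
  default. Note that reachable-only closeness is not monotone under edge
  addition on disconnected graphs — an edge that merges components pulls
  distant nodes into the average — which is the reason the harmonic
  variant exists;
- betweenness: the fractional (multiplicity-weighted) count of shortest
  paths between other node pairs passing through the node, endpoints
  excluded, normalised by (n−1)(n−2)/2 (undirected) or (n−1)(n−2)
  (directed) so values lie in [0, 1]. When several geodesics tie, each
  contributes its share — the standard pair-dependency convention;
- clustering coefficient: edges among neighbours / C(k, 2); defined as 0
  for degree < 2 nodes (rather than excluded) so means stay defined for
  any node set; undefined on the directed network.

Subnet-level (computed per sRNA on its in-network target set, then
macro-averaged over eligible sRNAs — not pooled over all targets):

- characteristic path length (CPL): mean pairwise distance over
  *connected* target pairs; undefined (NaN) if no pair is connected;
  undirected network only;
- density: within-set edges / C(k, 2); directed: within-set arcs /
  k(k−1). A symmetrised arc set therefore has directed density equal to
  the undirected density of its support;
- in-degree ratio (IDR): within-set edges divided by edges with exactly
  one endpoint in the set (directed: arcs leaving the set; outbound only).
  This is a raw count ratio, not normalised by possible-edge counts — it
  is 0 when the targets share no edges, and undefined in the degenerate
  case of a set with internal edges but no boundary.

An sRNA is eligible for the subnet statistics only if at least two of its
targets are in the network; ineligible sRNAs and undefined cells are
excluded from means with logged counts.

On the directed network only outbound (direction-respecting) paths are
used for closeness and betweenness, and CC and CPL are not reported.

## The null and the p-value

For the node-level statistics each replicate draws one random node set of
the same size as the mapped target count; for the subnet statistics each
replicate draws one random set per eligible sRNA with the size multiset
preserved, because the observed value is a macro-average over per-sRNA
subnets. One family of draws per replicate feeds all statistics — sharing
draws is cheaper, and any induced correlation between statistics leaves
each marginal p-value untouched.

The default sampling universe is the network node set. A full gene list
may be supplied instead; random draws that land off-network then shrink
(and can invalidate) their replicate, which is recorded as undefined and
excluded with a logged count.

p = (1 + r) / (N + 1), where r counts null replicates at least as extreme
as the observation, ties included. The estimator is mildly conservative,
never exactly 0, and at the default N = 1000 resolves three significant
figures. Tests are one-tailed in the direction of the scientific
alternative — greater for every statistic except CPL, whose alternative is
"targets are closer than random" (tail = less); a different tail map can
be passed. Z = (observed − null mean) / null SD (sample SD; NaN when the
null is degenerate). No multiple-testing correction is applied; the seven
statistics are reported side by side as one descriptive panel.

Implementation note: the engine precomputes per-node metric vectors, a
boolean adjacency matrix, and (when path statistics are requested) an
all-pairs BFS distance matrix, so each null replicate costs an index-and-
mean rather than a graph traversal. This is what makes hundreds of
studies × hundreds of replicates per study feasible in the test suite.

## Target assembly, tiers and operon extension

Target tables carry an evidence label per (sRNA, target) pair:
`experimental` or `predicted` (prediction itself — hybridisation scanning
and its p-value filtering — is out of scope; the package ingests the
resulting pair lists). When maps merge and a pair arrives under both
labels, the experimental label wins. Four predefined analysis tiers are
reported: experimental; experimental + predicted; and each of those with
operon extension. Extension is applied *after* tier selection, so the
extended-experimental tier never inherits predicted-derived operon genes.

Operon extension adds, for every (sRNA, target) whose target lies in an
operon, all genes strictly *downstream* of the target in transcription
order, labelled `extended-experimental` / `extended-predicted` after
their source pair. Upstream genes are never added: an sRNA acting on one
cistron can affect translation of the cistrons after it on the same
mRNA, not before it. The canonical fixtures are gadB → gadC and
lexA → dinF. Extension through *all* downstream genes (not only the
adjacent one) was chosen; the two rules coincide on two-gene operons, and
the all-downstream rule follows the polarity argument. Extension is
idempotent and never removes pairs.

Targets absent from a network are silently dropped (with coverage counts
reported) before any statistic sees them; sRNA genes themselves are never
added to the networks — the analysis concerns the targets.

## Robustness analysis

To probe sensitivity to interaction-data errors, a stated fraction f of
edges (defaults 0.05 and 0.10) is randomly removed, added (uniform over
non-edges), or both, and the whole significance suite is re-run on each of
`reps` perturbed replicates (default 20 per condition; the replicate count
is configurable). Counts are round(f·|E|), rounding half away from zero.
The summary is, per statistic, the fraction of replicates whose
significance call at α = 0.05 matches the unperturbed call. Separate add
and remove runs are the default; a combined mode exists. Degree-preserving
rewiring is deliberately not offered — it answers a different question
(edge placement given degrees), whereas the node-set null used here
randomises target identity, not edges.

## Synthetic studies

The generator emulates exactly the structure the statistics assume:

- background: Erdős–Rényi graphs over one gene universe — undirected
  (default n = 500, p = 0.01, mean degree ≈ 5, a sparse giant-component
  regime comparable to curated interaction maps at desk scale) and
  directed (p = 0.004, mean out-degree ≈ 2). A preferential-attachment
  option exists for the undirected background;
- planted modules: 15 sRNAs by default, each with 2–8 targets sampled
  without replacement (sets may overlap across sRNAs, as real regulons
  do). Every within-set node pair is *resampled*: an existing background
  edge is removed, then the pair is connected with probability
  `within_edge_prob` (default 0.3). Resampling, rather than adding on
  top of the background, makes the within-set edge probability exactly
  the configured value, so setting it equal to the background probability
  yields an exact calibration null. The directed network is planted the
  same way per ordered pair (default: background probability, i.e. no
  directed signal). Optional boundary attachment adds Poisson-distributed
  extra edges from targets to background genes;
- operons: disjoint ordered runs of 1–5 genes, about half seeded to start
  with a planted target so downstream extension is exercised;
- evidence labels: each pair is `predicted` with probability 0.5.

Everything derives from one integer seed, and `generate_study` writes the
exact TSV dialects the loaders consume, so a file round trip reproduces
the in-memory bundle byte for byte.

What the generator does *not* emulate: the heavy-tailed degree
distributions, study bias and autocorrelation of real curated interaction
data, gene-name synonymy, or regulation signs. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated under
the stated model, not that any particular biological dataset will show
modularity.

## Test and simulation sizes

The acceptance-level checks run at: 20 random graphs (n = 30, ER p = 0.15,
directed and undirected) for oracle equivalence at 1e-9; 200
calibration-null studies × 200 replicates for the rejection-rate band
[0.02, 0.09] (the 95% binomial band around the nominal 0.05 at 200
studies); and 100 planted studies (background 0.01, within-set 0.3, 10
sRNAs × 5 targets) × 500 replicates for recovery (≥ 90% for density and
IDR, ≥ 80% for CPL). These sizes keep the whole suite at a few minutes on
one CPU while leaving the binomial bands meaningful.

## Numerical and degenerate-input conventions

- Undefined values are NaN end to end and rendered N/A in reports; means
  skip them with logged counts.
- A degenerate null (SD = 0) reports Z = NaN; the empirical p remains
  valid (ties count as extreme, so an observation equal to every null
  value gets p = 1).
- With n_sims = 1 the add-one rule confines p to {0.5, 1.0}.
- Node identifiers are case-sensitive opaque strings; no synonym mapping.
- Sorted node order is used for every matrix and every file export, which
  together with the single-seed RNG discipline gives bit-identical
  reports for identical configuration.

## Known limitations

- The node-set null conditions on the observed network; it does not model
  uncertainty in the network itself (the perturbation analysis probes
  that empirically instead).
- Macro-averaging over sRNAs weights a 2-target sRNA as heavily as an
  8-target one; this matches the per-sRNA definition of the subnet
  statistics but means a single small, dense subnet can drive the mean.
- Betweenness normalisation and the raw-ratio IDR are conventions; both
  are recorded in the report metadata so numbers are comparable across
  runs.
- Whether operon-internal regulatory edges or autoregulatory loops should
  be retained in a TRN is a curation question; self-loops are dropped
  here, and loop-dependent statistics are out of scope.
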