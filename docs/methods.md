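# Methods

## The model

`cernaforge` treats ceRNA-pair discovery as a two-filter test on every
(lncRNA, TF) pair.  Let `N` be the miRNA universe, `m_l` and `m_t` the two
members' miRNA target-set sizes and `k` the shared count.  Under the null
that the two target sets are independent uniform draws, `k` follows
`Hypergeom(N, m_l, m_t)`, and a pair is called when the upper tail
`P(X ≥ k)` is below 0.05 *and* the Pearson correlation of the members'
log-scale expression across samples exceeds 0.6 — both strict inequalities.
The universe defaults to the union of source miRNAs over both interaction
tables and is overridable, since a fixed curated universe (e.g. 386 miRNAs)
does not generalise to other inputs.  No multiple-testing correction is
applied by default (a Benjamini–Hochberg option exists in the
over-representation op): the procedure is a screen whose joint filter, not
its marginal p-value, controls the false-positive rate — the planted-truth
simulations below quantify that control directly.

Called pairs are merged with TF–TF PPI edges into a single simple
undirected graph; node kinds (`lncRNA`/`TF`) and edge types (`ceRNA`/`PPI`)
are attributes.  PPI edges are kept only between TFs already present in a
ceRNA pair (an include-all switch exists), because a crosstalk analysis of
ceRNA hubs gains nothing from PPI-only satellites.

## Topology and the rewiring null

The scale-free diagnostic is the log–log least-squares fit of degree
frequencies over degrees `k ≥ 1` with nonzero frequency (at least three
distinct degree classes required).  This regression-with-R² convention is
deliberately the network-toolbox one, not a Clauset-style MLE tail fit: the
quantity of interest here is the R² such tools report.

Average path length (APL) is the mean BFS distance over unordered
same-component pairs, computed with `scipy.sparse.csgraph` so that a
1,000-replicate null finishes in about a minute on a 300-node network.
The null rewires each edge-type class separately by double-edge swaps —
ceRNA swaps exchange TF partners between two lncRNA–TF edges, preserving
bipartiteness; PPI swaps are ordinary — rejecting any swap that would
create a self-loop or parallel edge.  Ten attempted swaps per edge is the
mixing budget (configurable).  The empirical p is exactly
`(#random networks with APL strictly shorter) / n_random`, with no
continuity correction.  A graph can be swap-frozen (a star, a K₂,₂); the
rewirer then warns and returns an unchanged copy, which makes the null
degenerate at p = 0 rather than failing.

Hubs are the top `floor(0.10·|V|)` nodes by degree; ties at the cutoff are
broken by higher betweenness, then lexicographic id, making selection
independent of node insertion order.

## Module detection

The MCODE-style detector weights each vertex by `k_max × density` of the
highest k-core of its closed neighbourhood (vertices below the degree
cutoff, default 2, get weight 0), then grows complexes greedily from the
highest-weight unassigned seed, admitting a neighbour whose weight strictly
exceeds `seed_weight × (1 − node_score_cutoff)` (cutoff 0.2), to a maximum
depth of 100.  Each node joins at most one complex.  Post-processing drops
complexes with an empty 2-core and applies the haircut — implemented as the
iterated removal of degree-<2 fringe nodes, i.e. the complex's 2-core —
before scoring.  A complex is reported when `density × size > 5` (strict).
Haircut defaults on and fluff off; both are exposed, and exact membership
of modules reported by other tools can depend on these toggles.  All
internal orderings are canonical (weight, degree, id), so results are
deterministic and permutation-invariant.

## Survival analysis

Univariate Cox fits use lifelines (Efron tie handling, Newton iteration);
the package surfaces coefficient, HR, Wald 95% CI and p.  Monotone
likelihood (perfect separation) is flagged on the returned fit, not raised,
and flagged fits are excluded from risk models.  The risk score of a sample
is `Σᵢ rᵢ·Expᵢ` over a gene set's fitted coefficients; samples strictly
above the cohort mean form the high-risk group and a score exactly at the
mean goes to low risk (the boundary case is otherwise unassigned by the
mean-cutoff rule; low was fixed for determinism).  Groups are compared by
Kaplan–Meier curves and the standard log-rank test.  Overall survival is
the assumed endpoint.  Group-wise expression comparisons default to the
Wilcoxon rank-sum test (exact for small tie-free groups), with Welch's
t-test selectable.

A caution the package documents rather than hides: fitting per-gene Cox
coefficients, building the risk score from those same data, stratifying at
the mean and log-rank testing the same samples is circular, and for
multi-gene sets the resulting p-values are anti-conservative under the
null.  For a single gene the group assignment does not depend on the
fitted coefficient (the mean split of `r·x` is the mean split of `x`, and
the log-rank test is label-symmetric), so the procedure is calibrated
there — which is how the null-calibration test is constructed.  Risk models
intended for inference rather than screening should be validated on held-out
samples.

## Motif scanning

Promoters are `[TSS − 2000, TSS + 2000)` with the strand-aware TSS at
`start` (+) or `end − 1` (−) in 0-based half-open coordinates, clipped at
contig boundaries.  A window is scored as the sum of per-position log₂
odds of the PWM against a 0-order background (uniform by default,
overridable); zero matrix entries receive a 1e-3 pseudocount before the
log.  Scores are discretized to integers at 1/1000 of a log₂ unit, and the
exact null distribution of the window score under the background model is
obtained by convolving the per-column score distributions — so the p-value
attached to a window, `P(background score ≥ observed)`, is exact for the
discretized scores, and the scanner scores windows with the same integers
the null uses.  Hits require `p < 1e-4`; both strands are scanned (the
minus strand via the reverse-complemented matrix at the same forward-offset
convention) and windows containing N are skipped.

Because the score spectrum is discrete, the largest achievable p below the
threshold, `q`, can sit well under the nominal 1e-4 for near-degenerate
motifs; the per-window false-hit probability is exactly `q`, and the
calibration check compares observed background hits to `2·n_windows·q`
rather than to the nominal rate.

The crosstalk network keeps a ceRNA edge (l, t) when l is among the top
`floor(0.20·n_lncRNA)` lncRNAs by network degree and t's motif has at least
one hit in a region linked to l.  Enhancer-to-gene linkage is by explicit
mapping table — no distance heuristic is baked in — and motif→TF mapping
likewise, since motif databases key on motif ids.

## Synthetic data: what it emulates and what it does not

The generators plant exactly the structure each analysis assumes, with a
known truth object:

- *Interactions*: every miRNA targets every lncRNA/TF independently at a
  baseline rate (default 0.05); each planted pair additionally receives a
  disjoint block of `shared_boost` miRNAs wired to both members.
  Disjointness across pairs keeps non-planted pairs exactly at the
  baseline null.
- *Expression*: pair members share a standard-normal latent factor,
  `x = √ρ·z_pair + √(1−ρ)·z_own`, giving correlation exactly ρ in
  expectation; values are centred at 8 with unit SD on the log scale, and
  designated genes can be mean-shifted in tumor samples.
- *Survival*: exponential event times with hazard
  `λ₀·exp(Σ coef·expr)` (proportional hazards by construction; expression
  is mean-centred inside the hazard by default so λ₀ sets the time scale)
  and independent exponential censoring.
- *Regions*: i.i.d. bases at a chosen GC content with motif consensus
  sequences written at known positions/strands.

These emulate none of the marginal skew, batch structure, subtype biology
or linkage of a real tumor cohort; passing the planted-recovery tests shows
the procedures find what they are defined to find at the stated effect
sizes, not that they would behave identically on real data.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use: exhaustive oracle sweeps up
to universe 12 for the hypergeometric tail and widths 4–6 (4^w words) for
PWM p-values; 20-seed planted-pair runs at 386 miRNAs, 30 lncRNAs × 20 TFs,
10 planted pairs, 400 samples; a 300-node / 600-edge network with 1,000
rewired replicates; 20-seed Cox recovery at n = 300, 100-trial log-rank
power at 200/arm, and 200 null replicates for type-I error (20 replicates
cannot resolve the [0.01, 0.12] band being checked); 60 background
sequences of 5 kb for scanner calibration.  Vertex-weight oracles run
exhaustively over all labeled graphs on ≤ 5 nodes plus seeded random
6–8-node samples, since enumerating all labeled 8-node graphs (2²⁸) is not
meaningful effort.  Every stochastic component takes a `numpy`
`default_rng` seed; replicate seeds are spawned from a master
`SeedSequence`, so all reported numbers are reproducible bit-for-bit given
the seed.

## Known limitations

- The hypergeometric null assumes exchangeable miRNA target sets; real
  target prediction is biased by sequence composition, which the test does
  not model.
- Power-law R² from binned log–log regression is a descriptive convention
  and a poor estimator of tail exponents.
- The APL null conditions on the degree sequence only; it does not preserve
  assortativity or clustering.
- MCODE module membership can shift with the haircut/fluff toggles.
- Only 0-order backgrounds are supported in the scanner; no q-values.
- The module-prognosis procedure is in-sample (see the caution above).
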