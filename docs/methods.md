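# Methods

This note documents the statistical models, algorithmic choices and
limitations behind each `mthap` stage, and what the synthetic-data
generator does and does not emulate.

## Haplotype collapsing

Specimens share a haplotype iff their aligned sequences are identical as
strings. Ambiguity codes do **not** wildcard-match: `ACGN` and `ACGT`
are distinct haplotypes. This is the strict convention of exact-match
collapsers; it avoids the order-dependence that partial matching
introduces, at the cost of occasionally splitting a haplotype on a poor
base call. Input is uppercased on read and `U` mapped to `T` with a
warning. Window coordinates (e.g. extracting a 549-bp fragment) are
1-based inclusive **on the provided alignment**; mapping to full-gene
numbering is the caller's concern. Haplotype ids `H1..Hk` follow first
appearance, so relabeling — not content — depends on input order.

Base composition pools all specimen sequences and excludes gaps and
ambiguity codes from the denominator, so A+C+G+T = 1 exactly.

## K2P distances

`d = -½ ln(1-2P-Q) - ¼ ln(1-2Q)` with transition (A↔G, C↔T) proportion P
and transversion proportion Q computed per pair after **pairwise
deletion** (a site is dropped for a pair only when either member is
gap/ambiguous). Pairwise rather than complete deletion maximizes usable
sites on short fragments. Saturated pairs (log argument ≤ 0) raise a
flagged error and are dropped from group means with a logged count —
for intraspecific mtDNA data (divergences ≲ 12 %) saturation signals bad
input rather than real signal.

Group means weight **haplotypes equally** (one sequence each), not
specimens; this matches the convention of distance tables computed over
unique haplotypes. Standard errors use the site bootstrap: alignment
columns resampled with replacement (default 1000 replicates, seeded),
SE = SD of the group mean across pseudo-alignments.

## Diversity

Nei's unbiased estimators: `H = n/(n-1)(1-Σpᵢ²)`,
`π = n/(n-1) Σᵢ≠ⱼ pᵢpⱼdᵢⱼ` with d the raw per-site difference proportion
between haplotypes (a `corrected=True` flag switches d to K2P; the raw
proportion is the conventional π and the default). π is stored per site
and reported in percent in the TSV. No variance/SE for H or π is
computed. Samples with n = 1 appear in the report with H and π flagged
undefined rather than being silently dropped.

## Differentiation (AMOVA)

One-level AMOVA on a specimen-pair distance matrix δ:

```
SSD_total  = Σᵢⱼ δᵢⱼ / 2N          (ordered pairs)
SSD_within = Σₖ Σ_{i,j∈k} δᵢⱼ / 2nₖ
σ²_w = MS_within,   σ²_a = (MS_among − MS_within)/n′
n′   = (N − Σnₖ²/N)/(K−1),   Φ = σ²_a/(σ²_a+σ²_w)
```

δ is 0/1 haplotype identity for the frequency Fst, the raw count of
differing sites (pairwise deletion, **not** squared — the conventional
choice for haplotype data) for Φst, or K2P. Negative estimates are
reported as-is; they are the expected sampling behaviour of the
variance-component estimator near zero differentiation. Significance:
specimens permuted between the two populations with sizes preserved;
`p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm)` (add-one correction avoids
p = 0; ties count as ≥). Default n_perm = 10,000, seed mandatory. An
exhaustive-enumeration mode exists for samples small enough to list all
splits; it returns the exact tail fraction.

## Median-joining network

Distances are Hamming counts over **variable columns only** (invariant
sites stripped for speed; pairwise deletion of ambiguous positions).

1. *Minimum spanning network*: edge (u,v) admitted iff
   `d(u,v) ≤ minimax-path(u,v) + ε`, where the minimax path weight is
   the single-linkage join level of u's and v's clusters. At ε = 0 this
   is exactly the union of all minimum spanning trees (an edge is in
   some MST iff its weight equals the minimax value). ε defaults to 0.
2. *Median addition*: for every triple of nodes spanning ≥ 2 MSN edges,
   the position-wise majority consensus is a candidate; three-way ties
   expand into all variants (lexicographic order, capped at 32 per
   triple). Per round, the candidate giving the largest strict reduction
   of the spanning (MST) cost is added — ties broken lexicographically —
   and the loop repeats until no candidate helps. Greedy single-addition
   keeps the construction deterministic and order-invariant when no
   ties exist; on adversarial instances it may stop above the true
   minimal Steiner cost (the usual greedy gap of median-joining).
3. *Pruning*: median vectors of degree ≤ 2 that lie on no shortest path
   between observed haplotypes are removed, and the network rebuilt, to
   a fixpoint. Because Hamming distance is a metric, a degree-2 Steiner
   point can never strictly reduce cost, so surviving medians generically
   have degree ≥ 3. Survivors are named mv1, mv2, … in creation order.

The *network cost* reported is the weight of a minimum spanning tree
within the final network — the parsimony cost — not the plain edge-weight
sum, which double-counts tied alternative edges that an MSN deliberately
retains.

## Strict-clock dating

UPGMA (average linkage) on K2P distances; node height = join distance/2,
giving an ultrametric tree by construction, which is the topology a
strict clock presumes (neighbour-joining would estimate unequal tip
depths the clock model cannot use). Ties in the agglomeration order are
broken by the lexicographically smallest member label, so runs are
reproducible. Internal nodes are labeled `node1..nodeK` in join order.

Ages over a rate grid: a rate `r` ("x % per Myr", as substitutions/
site/Myr) is interpreted as a **pairwise-divergence** rate, so
`age = 2h/r`; a `per_lineage` flag switches to `age = h/r`. Both
conventions exist in the literature; the divergence-rate reading is the
default because rate grids of this kind are usually quoted as pairwise
divergence. Ages are exactly inversely proportional to the rate and
monotone decreasing along the grid. Output is in Ma, 4 decimals.

Calibration: for dated nodes (MRCA of a label set, age in Ma) the scale
`s` minimizing `Σ(s·hᵢ − ageᵢ)²` is fitted through the origin; all node
ages are `s·h`, with the residual reported. A single calibration point is
reproduced exactly. Note that Bayesian dating with node-age priors does
**not** scale inversely with the assumed rate (priors dominate when data
are weak), so a deterministic clock like this one reproduces the
qualitative rate-grid design, not MCMC posteriors.

## Synthetic data

`simulate_genealogy` uses the structured Kingman coalescent (msprime;
island model, deme size 1 in coalescent units, haploid), so a
within-deme pair coalesces at rate 1 (E[T₂] = 1) and each lineage
migrates at rate M. `mutate` lays a finite-sites process on the
genealogy: Poisson(θ/2·t·L) mutations per branch of length t, uniform
site choice, transition with probability κ/(κ+1) (default κ = 4, a
typical mtDNA transition bias), random uniform root sequence. Under this
scaling E[pairwise differences per site] = θ. Defaults — L = 549, θ of
order 0.5–1 %, 2–5 demes, skewed haplotype spectra from the coalescent
itself — mirror the shape of a small-mammal mtDNA survey (tens of
specimens, ~550-bp fragment, 2–20 haplotypes per population).

One integer seed drives everything through `numpy.random.SeedSequence`
spawning, in fixed order: genealogy stream first, then mutation stream.

What the generator does **not** emulate: selection, recombination
(irrelevant for mtDNA), population growth or bottlenecks, sequencing
error and ambiguity calls, and base-composition bias (the root is
uniform ACGT). Passing parameter-recovery tests therefore demonstrates
estimator correctness under neutral equilibrium assumptions, not
robustness to those real-data features. Finite-sites multiple hits bias
raw π̂ slightly below θ (≈ 1–3 % at θ·L ≈ 5), which is why recovery is
asserted at 5 %.

Planted fixtures (`table4_like`, `two_pop_fixed`, `star`) are fully
deterministic datasets with hand-placed haplotype counts (5/1/1 and
singletons), fixed inter-population differences, and a star phylogeny,
used for exact-value tests downstream.

## Problem sizes

Default test and acceptance runs use 2-sequence coalescent replicates
(2000) for π recovery, 250 replicates × 3 migration rates (6+6 samples)
for the Φst trend, and ≤ 10-haplotype networks — sizes at which the
exhaustive oracles (all permutations, all Steiner candidates) remain
enumerable and the whole suite runs in well under a minute on one CPU.

## Known limitations

- Exact-match collapsing treats a single miscalled base as a new
  haplotype; real surveys sometimes hand-curate such cases.
- The MJ implementation targets intraspecific data sizes (≤ a few dozen
  haplotypes); its per-round MST evaluation is quadratic-cubic and not
  tuned for hundreds of haplotypes.
- Fst/Φst here is the two-population pairwise statistic; hierarchical
  (multi-level) AMOVA is out of scope.
- Clock dating is deterministic; no posterior intervals, no relaxed
  clocks.
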