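# recoverymics

Tools for asking how a host-associated microbial community reassembles after
an environmental disturbance: by **neutral processes** (immigration and
ecological drift) or by **selection**. The motivating system is a fish
host–microbiota experiment — water, skin and gut communities of juvenile
perch across three exposure regimes (control, constant and variable cadmium),
eight tanks and seven timepoints spanning an exposure phase (T0→T3) and a
recovery phase (T3→T5) — but every component works on any OTU count table
with sample metadata and a rooted phylogeny.

## What it computes

**Sloan neutral community model.** For a taxon whose source-pool relative
abundance is *p*, the neutral expectation for its local relative abundance is
Beta(*Nmp*, *Nm*(1−*p*)), where *N* is the community size (reads per sample)
and *m* the migration rate — the probability that a death in the local
community is replaced by an immigrant rather than a local birth. The
probability of detecting the taxon at depth *N* with detection limit *d*
reads is

```
F(p; m, N, d) = 1 − I_{d/N}( Nmp, Nm(1−p) )
```

with *I* the regularized incomplete beta function. `fit_ncm` estimates *m*
by nonlinear least squares of observed occurrence frequencies on *F*,
reports R², and classifies every OTU against a 95% Wilson score band around
its predicted frequency: *neutral* (inside), *above* (occurs more often than
neutrality predicts — candidate host selection), *below* (less often —
dispersal limitation, or a rare-immigrant taxon amplified by the host, the
classic signature of host-adapted taxa such as *Mycoplasma* in fish).

**Generalized UniFrac.** Phylogenetic beta diversity
d(A,B) = Σ_b l_b (p_A+p_B)^α |p_A−p_B|/(p_A+p_B) / Σ_b l_b (p_A+p_B)^α over
tree branches, with α interpolating between rare- (α=0) and abundance-
weighted (α=1) lineages; α=0.5 by default.

**Permutation tests.** PERMANOVA (pseudo-F on squared distances), MRPP
(weighted mean within-group distance δ and chance-corrected effect A) and a
multivariate dispersion-homogeneity test (ANOVA-F on distances to group
centroids in PCoA space, negative eigenvalues kept as imaginary axes) — all
with seeded permutations, exact enumeration for small n, within-stratum
(e.g. tank) permutation, and Benjamini–Hochberg control across pairwise
contrasts. Kruskal–Wallis / Wilcoxon / Fisher wrappers plus per-taxon
differential-abundance scans.

**Sample correlation networks.** Spearman rho between samples, BH-FDR edge
filtering, unnormalized betweenness and eigenvector centrality, and
centrality-shift summaries between treatments over time.

**Synthetic communities with known truth.** A Hubbell-type local-community
simulator (explicit death–replacement events, or the Dirichlet stationary
approximation for speed) with per-taxon reproductive fitness *w*, a factorial
exposure–recovery design generator with per-regime selection trajectories,
and a shared coalescent tree — so every estimator above can be validated
against ground truth.

## Worked example

```
python examples/fit_neutral_model.py
```

prints (seed 42):

```
true migration rate      m  = 0.3
fitted migration rate    m^ = 0.290
goodness of fit          R2 = 0.972
community size (reads)   N  = 2000
classification: 81.6% neutral, 11.4% above, 7.0% below
```

100 neutral communities were simulated from a 300-taxon lognormal source
pool at migration rate 0.3 and sequenced to 2000 reads; the fit recovers the
migration rate within a few percent, the occurrence-frequency curve explains
97% of the variance, and ~82% of OTUs sit inside the 95% neutral band — the
baseline against which selection-driven departures are read. The other
examples (`beta_diversity_tests.py`, `sample_networks.py`,
`full_recovery_analysis.py`) walk through divergence testing, network
centrality and the full recovery pipeline, each printing the numbers it
computes with a short interpretation.

A thin CLI mirrors the library:
`recoverymics simulate|validate|diversity|betadiv|ncm|network|run`.

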