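# Methods

## The question the package operationalizes

After a pulse disturbance (here: cadmium exposure of a fish host system),
does the microbial community reassemble through neutral processes —
immigration from a source pool plus ecological drift — or through
selection? The package answers this with four measurements run over a
factorial design (exposure regime × habitat × tank × timepoint): the Sloan
neutral-model fit with per-OTU classification, generalized-UniFrac
divergence with permutation tests, sample correlation networks with
centrality scoring, and a distance-to-control recovery trajectory.

## Sloan neutral community model (`neutral_model`)

The model treats the local relative abundance x of a taxon with source
proportion p as Beta(Nmp, Nm(1−p)): N is the community size, m the
probability that a death is replaced by an immigrant. The detectable
occurrence frequency at detection limit d reads is
F(p; m, N, d) = 1 − I_{d/N}(Nmp, Nm(1−p)).

Conventions (all configurable):

- **N** = arithmetic mean of sample read totals (median available). This
  identifies the sequenced reads with the model's community, the standard
  choice for this analysis.
- **d** = 1 read.
- **p** = per-OTU mean of within-sample relative abundances; OTUs detected
  nowhere are excluded (they carry no information), OTUs detected everywhere
  are retained.
- **m̂** minimizes Σ_i (f_obs,i − F(p_i))² over (0, 1]: a coarse grid
  (step 10⁻³) locates the global basin, then bounded scalar minimization
  refines inside the winning bracket (xatol 10⁻⁷). The grid pass makes the
  estimate reproducible against an exhaustive grid search by construction.
- **R²** = 1 − SS_res/SS_tot about the mean observed frequency; NaN when all
  observed frequencies are identical (classification still runs).
- **Band**: Wilson score interval at the chosen level (default 95%),
  centered on the predicted frequency with n = number of samples. Band
  edges are closed (a tie classifies as neutral). With small n (≲ 10) the
  band is wide and, near f_pred → 1, asymmetric; occupancy saturation can
  flag f_obs = 1 taxa as "above" — an intrinsic property of this
  de-facto-standard construction, visible in any small-n fit.
- **Bootstrap** for m: resampling samples with replacement (percentile
  interval), off by default.

### Estimator bias under explicit sequencing noise

A point documented here because the simulator makes it measurable: when
communities are generated with an explicit multinomial read-sampling layer,
detection becomes Poisson-like rather than the sharp threshold at d/N that
F assumes. Mass of the abundance distribution just below d/N still gets
detected sometimes; for the decreasing densities typical of rare taxa the
net effect is that observed occupancy exceeds the threshold-model
prediction, and the fitted concentration N·m̂ overshoots the generative
concentration by roughly 20–35%. Removing the read-sampling layer (scoring
detection directly as x > d/N) removes the bias (≤ 3% error). Separately,
the finite-community (Hubbell) parameterization of immigration,
I = m(N_local−1)/(1−m), differs from the Sloan concentration N·m by the
1/(1−m) factor, so "the migration probability of the simulated community"
and "the fitted Sloan m" are the same quantity only when m is small or when
N_local ≈ N(1−m). Both effects partially cancel near m ≈ 0.3 with
N_local = 1000 and depth 2000 — the package's default validation operating
point — and parameter recovery there is within a few percent; at m = 0.05
or m = 0.6 the fitted m is biased low/high by 25–50%. Consumers comparing
fitted m values across strata (the package's main use) are unaffected, as
the bias is shared; consumers needing absolute migration probabilities
should interpret N·m̂ as an immigration–drift concentration, not m alone.

## Synthetic communities (`synthetic_data`)

- **Source pools**: lognormal (default σ = 1.5–2) or flat-Dirichlet
  abundance distributions over S taxa; deterministic per seed.
- **Dynamic mode** is a Moran-type zero-sum process: a community of N_local
  individuals is initialized as Multinomial(N_local, q); each event kills a
  uniformly chosen individual and replaces it from the source pool with
  probability m, else with a copy of a survivor chosen ∝ counts × fitness w.
  Burn-in is 10·N_local events (overridable). The neutral stationary state
  is Beta-binomial with concentration I = m(N_local−1)/(1−m); a unit test
  verifies the simulated variance matches q(1−q)/(I+1)·(I+N)/N.
- **Stationary mode** draws proportions directly from Dirichlet(I·q)
  (I capped at 10⁶ as m → 1) — valid only under neutrality, used where speed
  matters. Both modes sequence each community as Multinomial(depth,
  proportions).
- **Randomness**: one master seed; per-sample streams come from seed-sequence
  spawning, so sample k's community is identical whatever the batch size,
  and the event loop is vectorized across samples without breaking that.
- **Selection** multiplies reproductive weight only; immigration is
  unaffected. Consequences worth knowing, because they decide what is
  detectable by the occupancy-curve method:
  - a strongly favored *common* taxon sweeps to a deterministic high
    abundance in every sample — occupancy 1 at high p, which lies **on**
    the neutral curve: homogeneous equilibrium enrichment of a common taxon
    is invisible to this analysis;
  - a strongly favored *rare* taxon (source q of order 1/(events·m)) is the
    detectable case: immigration is rare enough that colonization is patchy
    across replicate communities, and amplification makes colonized samples
    extreme — high mean abundance at low occurrence, far **below** the
    curve. This is the signature reported for host-adapted taxa
    (*Mycoplasma*-like), and it is how the preset models them;
  - a suppressed taxon is held at a small, immigration-maintained abundance
    with *less* between-sample variance than a neutral taxon of equal mean,
    so it surfaces **above** the curve when its suppressed abundance sits
    near the detection transition zone (p ~ a few reads per sample).
- **Experiment preset** (`perch_recovery_preset`): 3 regimes × 3 habitats ×
  8 tanks × 7 timepoints × 3 replicates; S = 150 taxa per habitat-specific
  lognormal pool over a shared Kingman coalescent tree (pairwise rate 1,
  exponential inter-coalescence branch lengths); N_local = 500, depth 2000,
  m = 0.3; every stratum runs the dynamic process so control and treated
  cells differ only through selection. Selection targets 25 rare-source
  taxa (q ≈ 10⁻³, w = 8) and 10 transition-zone taxa (q ≈ 4·10⁻³,
  w = 0.02); strength ramps over exposure (constant regime at full strength
  from T0, variable regime ramping to T3), relaxes stepwise over
  TR1–TR4, and ends at a habitat residual (0 for gut and water — full
  relaxation; 0.4 for skin — an alternative stable state). The targeted-taxa
  counts were calibrated so the control-vs-treated %neutral gap at peak
  exposure is of the magnitude the motivating study reports (≈ 10 points)
  rather than within per-stratum noise (±3 points at n = 24).

What the generator does **not** emulate: sequencing error and chimeras,
compositional spike-ins, host-to-host heterogeneity in selection strength,
temporal autocorrelation within a tank (each stratum is simulated at its
own equilibrium), and OTU-clustering artifacts. Passing validations
therefore show the estimators are correct under the stated assembly model,
not that real perch data satisfy those assumptions.

## Diversity (`diversity`)

Alpha: richness (count ≥ 1), Shannon H (natural log, 0·ln0 := 0),
effective number exp(H), Pielou-type evenness H/ln(richness) (NaN at
richness ≤ 1, flagged not dropped), and richness/exp(H). Generalized
UniFrac is computed by one postorder traversal accumulating per-branch
descendant read fractions, then pairwise evaluation; the root branch is
excluded (it carries all reads of both samples and cannot discriminate);
branches with p_A + p_B = 0 are skipped. α = 0.5 by default with the full
α family sharing one traversal. OTUs absent from the tree raise, or are
pruned (with renormalization) when requested. Optional seeded rarefaction
to a common depth via multivariate hypergeometric draws.

## Permutation tests (`community_tests`)

- p values follow (1 + b)/(1 + B) with B seeded random label permutations;
  an exact mode enumerates every distinct labelling for n ≤ 9. Optional
  strata restrict permutations to within-stratum shuffles (e.g. tanks).
- PERMANOVA: SS from squared distances; pseudo-F equals the classical
  one-way ANOVA F on 1-D Euclidean input (tested to 10⁻¹⁰).
- MRPP: δ = Σ_g (n_g/n)·(mean within-group distance), lower-tail;
  A = 1 − δ_obs/mean(δ_perm).
- Dispersion homogeneity: PCoA with negative eigenvalues retained as
  imaginary axes; distance to group centroid =
  √max(0, Σ_real Δ² − Σ_imag Δ²); ANOVA-F on those distances, permuting
  labels over fixed coordinates.
- Pairwise contrasts subset the distance matrix per pair; BH runs per test
  family across the pairs.
- Rank tests and Fisher exact wrap SciPy; BH wraps statsmodels. All-tied
  Kruskal–Wallis input returns H = 0, p = 1 rather than an error.

## Networks (`networks`)

Nodes are samples. Spearman rho (tie-corrected, t-approximation p) between
abundance profiles; edges kept when |rho| ≥ rho_min **and** BH-adjusted
p ≤ fdr (BH over all defined pairs); samples with constant profiles yield
undefined correlations and are excluded from edges but kept as nodes.
Default rho_min: 0.5 for water, 0.3 for host habitats. Betweenness is
unnormalized pair-counting with fractional credit for tied shortest paths,
on the unweighted topology (negative edges retained unless positive-only is
requested); eigenvector centrality is power iteration on the largest
connected component (damped by the implicit +I term), L2-normalized, NaN
elsewhere. Centrality summaries report medians/means per (treatment, time)
network plus a control-vs-treatment rank-sum p.

## Pipeline (`pipeline`)

Per habitat: alpha table, GUniFrac matrix, per-timepoint overall + pairwise
divergence tests (BH per family), per-(treatment × timepoint) neutral-model
fits and sample networks, and a recovery trajectory: mean between-group
distance control↔treatment per timepoint against the within-control
baseline, with a terminal `recovered` flag defined as a non-significant
(p_adj > α) terminal pairwise PERMANOVA contrast — one defensible
operationalization of convergence, recorded in the manifest. Stage seeds
derive from the master seed by CRC32 of the stage path, so adding a stage
never shifts another stage's stream; runs are byte-identical given a seed.
Outputs are TSVs plus a JSON manifest (config echo, versions, warnings).

## Validation problem sizes

Chosen to give stable statistics at interactive runtimes: parameter
recovery at S = 300, n = 200, depth 2000; coverage/sensitivity at n = 100
with 10 neutral and 50 selection replicates; type-I calibration with 1000
null datasets of n = 12 at 99 permutations; recovery signature over 20
seeded experiment replicates of an 8-tank, 2-regime gut design; the
determinism check on a reduced 192-sample preset. The acceptance script
(`scripts/acceptance.py`) re-runs all of these from one seed.

## Known limitations

- The fitted m is a Sloan-scale parameter; absolute migration probabilities
  of finite communities need the Hubbell inversion (see bias note above).
- The Wilson band classification undercovers at small n near occupancy
  saturation; %neutral comparisons should be made at matched n.
- MRPP's A uses the permutation mean of δ, so exact-mode A varies with the
  enumerated set, matching the reference behavior only asymptotically.
- Networks correlate samples (as in the motivating study), not taxa;
  no compositional correction (SparCC-type) is attempted.
- The dispersion test permutes labels over fixed PCoA coordinates; with
  very heterogeneous group sizes its small-sample level can drift, which is
  why the calibration suite checks it explicitly.
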