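"""Neutral / selective community simulator with a factorial exposure design.

The simulator produces OTU count tables with *known* assembly process so the
downstream estimators (neutral-model fit, beta-diversity tests, networks)
can be validated against ground truth:

* **Neutral assembly** follows Hubbell-style local-community dynamics: each
  death in a local community of ``N_local`` individuals is replaced with
  probability ``m`` by an immigrant drawn from a fixed source pool, else by
  a local birth.  The stationary distribution of a taxon's local relative
  abundance is Beta-distributed — exactly the regime the Sloan neutral
  community model fits.
* **Selection** multiplies a taxon's local birth weight by a fitness ``w``
  (``w > 1`` host-enriched, ``w < 1`` suppressed).  Selection acts on
  reproduction only, not on immigration, which is the simplest mechanism
  producing the above-/below-prediction occupancy of host-selected taxa.
* **The factorial design** mirrors a disturbance–recovery experiment:
  3 exposure regimes × 3 habitats × 8 tanks × 7 timepoints × replicates,
  with selection ramping during exposure (T0→T3) and relaxing during
  recovery (T3→T5), optionally leaving a residual (incomplete recovery).

Every output is a pure function of (configuration, seed); per-sample random
streams are derived by seed-sequence spawning so sample order never changes
results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import HABITATS, TIMEPOINTS, TREATMENTS, CountTable

__all__ = [
    "SourcePool",
    "SimulationConfig",
    "make_source_pool",
    "simulate_neutral_community",
    "inject_selection",
    "random_coalescent_tree",
    "ExperimentDesign",
    "SelectionEffects",
    "ExperimentResult",
    "simulate_experiment",
    "perch_recovery_preset",
]

_I_CAP = 1e6  # cap on the Dirichlet concentration as m -> 1


@dataclass(frozen=True)
class SourcePool:
    """Source (meta)community: taxon ids and their pool proportions."""

    taxon_ids: tuple[str, ...]
    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        if len(self.taxon_ids) != q.size:
            raise ValueError("taxon_ids and q length mismatch")
        if (q <= 0).any():
            raise ValueError("source proportions must be strictly positive")
        if abs(q.sum() - 1.0) > 1e-12:
            raise ValueError("source proportions must sum to 1")

    @property
    def S(self) -> int:
        return len(self.taxon_ids)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one batch of local communities.

    ``m`` is the immigration probability per death; ``N_local`` the number
    of individuals in each local community; ``depth`` the multinomial
    sequencing depth per sample.  ``selection`` maps taxon id → fitness
    multiplier ``w`` (reproduction weight; 1.0 = neutral).  ``stationary``
    mode draws local proportions directly from the Dirichlet stationary
    approximation Dir(I·q), I = m(N_local−1)/(1−m) — valid only when all
    w = 1; ``dynamic`` mode runs explicit death–replacement events.
    """

    n_samples: int
    N_local: int = 1000
    m: float = 0.3
    depth: int = 2000
    selection: Mapping[str, float] = field(default_factory=dict)
    mode: str = "stationary"
    seed: int = 0
    burn_in_factor: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.m <= 1.0):
            raise ValueError("m must be in (0, 1]")
        if self.N_local < 10:
            raise ValueError("N_local must be >= 10")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mode not in ("dynamic", "stationary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for t, w in self.selection.items():
            if w <= 0:
                raise ValueError(f"fitness must be > 0 (taxon {t!r})")


def make_source_pool(
    S: int,
    sad: str = "lognormal",
    sad_params: Mapping | None = None,
    seed: int = 0,
    prefix: str = "OTU",
) -> SourcePool:
    """Build a source pool with a lognormal or flat-Dirichlet abundance
    distribution.  Deterministic given ``seed``."""
    if S < 2:
        raise ValueError("S must be >= 2")
    params = dict(sad_params or {})
    rng = np.random.default_rng(seed)
    if sad == "lognormal":
        sigma = float(params.pop("sigma", 2.0))
        x = rng.lognormal(mean=0.0, sigma=sigma, size=S)
    elif sad == "dirichlet_uniform":
        x = rng.dirichlet(np.ones(S))
        x = np.clip(x, 1e-12, None)
    else:
        raise ValueError(f"unknown sad {sad!r}")
    if params:
        raise ValueError(f"unused sad_params: {sorted(params)}")
    ids = tuple(f"{prefix}_{i + 1:04d}" for i in range(S))
    q = x / x.sum()
    return SourcePool(ids, q)


def inject_selection(
    cfg: SimulationConfig,
    taxa: Sequence[str],
    w: float,
    pool: SourcePool | None = None,
) -> SimulationConfig:
    """Return a config giving ``taxa`` reproduction weight ``w``.

    ``w = 1`` is the identity.  If a pool is supplied, unknown taxon ids
    raise immediately (they are always checked at simulation time).
    """
    if w <= 0:
        raise ValueError("fitness w must be > 0")
    if pool is not None:
        unknown = sorted(set(taxa) - set(pool.taxon_ids))
        if unknown:
            raise ValueError(f"unknown taxon id(s): {unknown}")
    selection = dict(cfg.selection)
    for t in taxa:
        if w == 1.0:
            selection.pop(t, None)
        else:
            selection[t] = float(w)
    return dataclasses.replace(cfg, selection=selection)


def _fitness_vector(pool: SourcePool, selection: Mapping[str, float]) -> np.ndarray:
    unknown = sorted(set(selection) - set(pool.taxon_ids))
    if unknown:
        raise ValueError(f"selection names unknown taxon id(s): {unknown}")
    w = np.ones(pool.S)
    if selection:
        index = {t: i for i, t in enumerate(pool.taxon_ids)}
        for t, wt in selection.items():
            w[index[t]] = wt
    return w


def _stationary_concentration(m: float, N_local: int) -> float:
    if m >= 1.0:
        return _I_CAP
    return min(m * (N_local - 1) / (1.0 - m), _I_CAP)


def simulate_neutral_community(
    pool: SourcePool, cfg: SimulationConfig, sample_prefix: str = "S"
) -> CountTable:
    """Simulate ``cfg.n_samples`` independent local communities and sequence
    each to ``cfg.depth`` reads (multinomial on local proportions).

    Stationary mode samples local proportions from Dir(I·q); dynamic mode
    initializes each community from Multinomial(N_local, q) and runs
    ``burn_in_factor · N_local`` death–replacement events.
    """
    w = _fitness_vector(pool, cfg.selection)
    if cfg.mode == "stationary" and (w != 1.0).any():
        raise ValueError("stationary mode is only valid under neutrality (all w = 1)")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_samples)
    gens = [np.random.default_rng(c) for c in children]
    n, S, N, D = cfg.n_samples, pool.S, cfg.N_local, cfg.depth

    if cfg.mode == "stationary":
        alpha = _stationary_concentration(cfg.m, N) * pool.q
        reads = np.empty((n, S), dtype=np.int64)
        for i, g in enumerate(gens):
            props = g.dirichlet(alpha)
            reads[i] = g.multinomial(D, props)
    else:
        reads = _simulate_dynamic(pool.q, w, cfg, gens)

    ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    return CountTable(ids, list(pool.taxon_ids), reads)


def _simulate_dynamic(
    q: np.ndarray, w: np.ndarray, cfg: SimulationConfig, gens: list
) -> np.ndarray:
    """Vectorized Moran-type death/replacement process, all samples at once.

    Per-sample randomness is pre-drawn from each sample's own generator, so
    results per sample do not depend on how many other samples are run."""
    n, S, N, D = cfg.n_samples, q.size, cfg.N_local, cfg.depth
    n_events = int(round(cfg.burn_in_factor * N))
    counts = np.empty((n, S), dtype=np.int64)
    U = np.empty((n, n_events, 3))
    for i, g in enumerate(gens):
        counts[i] = g.multinomial(N, q)
        U[i] = g.random((n_events, 3))
    qcum = np.cumsum(q)
    rows = np.arange(n)
    for e in range(n_events):
        u_dead, u_mig, u_pick = U[:, e, 0], U[:, e, 1], U[:, e, 2]
        ccum = np.cumsum(counts, axis=1)
        dead = (ccum > (u_dead * N)[:, None]).argmax(axis=1)
        counts[rows, dead] -= 1
        # local birth weighted by fitness, from the N-1 survivors
        wgt = counts * w
        wcum = np.cumsum(wgt, axis=1)
        born = (wcum > (u_pick * wcum[:, -1])[:, None]).argmax(axis=1)
        migrant = np.minimum(np.searchsorted(qcum, u_pick), S - 1)
        repl = np.where(u_mig < cfg.m, migrant, born)
        counts[rows, repl] += 1
    reads = np.empty((n, S), dtype=np.int64)
    for i, g in enumerate(gens):
        reads[i] = g.multinomial(D, counts[i] / N)
    return reads


def random_coalescent_tree(taxon_ids: Sequence[str], seed: int = 0) -> TreeNode:
    """Random Kingman coalescent tree (pairwise coalescence rate 1) over the
    given taxa; branch lengths are exponential inter-coalescence gaps."""
    rng = np.random.default_rng(seed)
    live: list[tuple[TreeNode, float]] = [
        (TreeNode(name=str(t), length=None), 0.0) for t in taxon_ids
    ]
    if len(live) < 2:
        raise ValueError("need at least 2 taxa")
    t = 0.0
    while len(live) > 1:
        k = len(live)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (b, hb) = live.pop(j)
        (a, ha) = live.pop(i)
        a.length = t - ha
        b.length = t - hb
        parent = TreeNode(length=None)
        parent.extend([a, b])
        live.append((parent, t))
    root = live[0][0]
    root.length = 0.0
    return root


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout: regimes × habitats × tanks × timepoints × replicates."""

    treatments: tuple[str, ...] = TREATMENTS
    habitats: tuple[str, ...] = HABITATS
    tanks: int = 8
    timepoints: tuple[str, ...] = TIMEPOINTS
    replicates: int = 3

    def __post_init__(self):
        if not set(self.treatments) <= set(TREATMENTS):
            raise ValueError(f"treatments must be among {TREATMENTS}")
        if not set(self.habitats) <= set(HABITATS):
            raise ValueError(f"habitats must be among {HABITATS}")
        if not set(self.timepoints) <= set(TIMEPOINTS):
            raise ValueError(f"timepoints must be among {TIMEPOINTS}")
        if self.tanks < 1 or self.tanks > 8 or self.replicates < 1:
            raise ValueError("tanks must be 1..8 and replicates >= 1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.treatments)
            * len(self.habitats)
            * self.tanks
            * len(self.timepoints)
            * self.replicates
        )


# selection-strength schedules on [0, 1]: exposure ramps to T3, recovery
# relaxes afterwards; CV (variable regime) ramps up and relaxes more slowly
# than CC (constant regime), matching a gradual-exposure gradient.
_SCHEDULE = {
    "Ctrl": dict.fromkeys(TIMEPOINTS, 0.0),
    "CC": {"T0": 1.0, "T3": 1.0, "TR1": 0.8, "TR2": 0.6, "TR3": 0.4, "TR4": 0.2, "T5": 0.0},
    "CV": {"T0": 0.4, "T3": 1.0, "TR1": 0.9, "TR2": 0.7, "TR3": 0.5, "TR4": 0.35, "T5": 0.2},
}
_RECOVERY_POINTS = ("TR1", "TR2", "TR3", "TR4", "T5")


@dataclass(frozen=True)
class SelectionEffects:
    """Which taxa cadmium selection targets and how strongly, per regime/time.

    ``n_enriched`` moderately rare taxa get fitness ``w_enriched ** s`` and
    ``n_suppressed`` abundant taxa get ``w_suppressed ** s``, where the
    strength ``s ∈ [0, 1]`` follows the per-treatment schedule.  During the
    recovery phase the strength decays toward ``residual_t5[habitat]``;
    a nonzero residual models an alternative stable state (incomplete
    recovery, as seen for skin communities).
    """

    n_enriched: int = 25
    n_suppressed: int = 10
    w_enriched: float = 8.0
    w_suppressed: float = 0.02
    residual_t5: Mapping[str, float] = field(
        default_factory=lambda: {"water": 0.0, "skin": 0.4, "gut": 0.0}
    )

    def strength(self, treatment: str, timepoint: str, habitat: str) -> float:
        s = _SCHEDULE[treatment][timepoint]
        if treatment != "Ctrl" and timepoint in _RECOVERY_POINTS:
            res = float(self.residual_t5.get(habitat, 0.0))
            s = res + (1.0 - res) * s
        return s

    def target_taxa(self, pool: SourcePool) -> tuple[list[str], list[str]]:
        """Deterministic targets chosen from the source abundance spectrum.

        Enriched taxa are rare pool members (q near 1e-3): immigrants scarce
        enough that colonization is patchy across replicate hosts, yet
        frequent enough to arrive within a host's assembly window; host
        selection then amplifies the colonists to dominance — patchy
        occupancy at high mean abundance, the signature of a host-adapted
        taxon the neutral model cannot explain.  Suppressed taxa sit near
        the detection transition zone (q ~ 4e-3), where losing reproduction
        measurably distorts their occupancy."""
        asc = np.argsort(pool.q)
        eligible = sorted(
            (i for i in asc if pool.q[i] >= 2e-4),
            key=lambda i: abs(np.log(pool.q[i] / 1e-3)),
        )
        enriched = [pool.taxon_ids[i] for i in eligible[: self.n_enriched]]
        near = sorted(
            (i for i in asc if pool.taxon_ids[i] not in enriched),
            key=lambda i: abs(np.log(pool.q[i] / 4e-3)),
        )
        suppressed = [pool.taxon_ids[i] for i in near[: self.n_suppressed]]
        return enriched, suppressed

    def selection_map(
        self, pool: SourcePool, treatment: str, timepoint: str, habitat: str
    ) -> dict[str, float]:
        s = self.strength(treatment, timepoint, habitat)
        if s == 0.0:
            return {}
        enriched, suppressed = self.target_taxa(pool)
        sel = {t: self.w_enriched**s for t in enriched}
        sel.update({t: self.w_suppressed**s for t in suppressed})
        return sel


@dataclass
class ExperimentResult:
    counts: CountTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: pd.DataFrame  # per (habitat, treatment, timepoint, otu) fitness w, plus m


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def simulate_experiment(
    design: ExperimentDesign,
    base_cfg: SimulationConfig,
    effects: SelectionEffects,
    seed: int = 0,
    S: int = 150,
    sad_sigma: float = 1.5,
) -> ExperimentResult:
    """Simulate the full factorial experiment.

    Each habitat gets its own source pool (same taxon set, different
    proportions); each (habitat, treatment, timepoint) stratum is simulated
    as one batch of tank × replicate local communities under that cell's
    selection map; a shared random coalescent tree over all S taxa is
    returned for phylogenetic distances.
    """
    root = np.random.SeedSequence(seed)
    pool_ss, tree_ss, strata_ss = root.spawn(3)
    pools = {
        hab: make_source_pool(
            S, "lognormal", {"sigma": sad_sigma}, seed=_child_seed(child)
        )
        for hab, child in zip(HABITATS, pool_ss.spawn(len(HABITATS)))
    }
    tree = random_coalescent_tree(pools[HABITATS[0]].taxon_ids, seed=_child_seed(tree_ss))

    # fixed stratum indexing over the FULL factor space so that a reduced
    # design reuses the same per-stratum streams
    all_cells = [
        (hab, trt, tp) for hab in HABITATS for trt in TREATMENTS for tp in TIMEPOINTS
    ]
    cell_seeds = {cell: _child_seed(c) for cell, c in zip(all_cells, strata_ss.spawn(len(all_cells)))}

    frames, meta_rows, truth_rows = [], [], []
    n_per_stratum = design.tanks * design.replicates
    for hab in design.habitats:
        pool = pools[hab]
        for trt in design.treatments:
            for tp in design.timepoints:
                sel = effects.selection_map(pool, trt, tp, hab)
                mode = base_cfg.mode if not sel else "dynamic"
                cfg = dataclasses.replace(
                    base_cfg,
                    n_samples=n_per_stratum,
                    selection=sel,
                    mode=mode,
                    seed=cell_seeds[(hab, trt, tp)],
                )
                tab = simulate_neutral_community(pool, cfg, sample_prefix="x")
                sids = []
                k = 0
                for tank in range(1, design.tanks + 1):
                    for rep in range(1, design.replicates + 1):
                        sid = f"{hab}-{trt}-{tp}-t{tank}-r{rep}"
                        sids.append(sid)
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                "treatment": trt,
                                "habitat": hab,
                                "timepoint": tp,
                                "tank": tank,
                                "replicate": rep,
                            }
                        )
                        k += 1
                frames.append(pd.DataFrame(tab.counts, index=sids, columns=tab.otu_ids))
                for taxon, wv in sorted(sel.items()):
                    truth_rows.append(
                        {
                            "habitat": hab,
                            "treatment": trt,
                            "timepoint": tp,
                            "otu_id": taxon,
                            "w": wv,
                            "m": base_cfg.m,
                        }
                    )

    counts_df = pd.concat(frames, axis=0)
    counts = CountTable.from_dataframe(counts_df)
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["habitat", "treatment", "timepoint", "otu_id", "w", "m"]
    )
    return ExperimentResult(counts, metadata, tree, truth)


def perch_recovery_preset(
    seed: int = 42,
    design: ExperimentDesign | None = None,
    effects: SelectionEffects | None = None,
    S: int = 150,
    N_local: int = 500,
    depth: int = 2000,
    m: float = 0.3,
) -> ExperimentResult:
    """The package's standard disturbance–recovery scenario.

    Defaults: full 3 regimes × 3 habitats × 8 tanks × 7 timepoints × 3
    replicates layout; S = 150 taxa, local communities of 500 individuals,
    migration m = 0.3, 2000 reads per sample; cadmium selection enriches 8
    moderately rare taxa (w = 8) and suppresses 4 abundant taxa (w = 0.02)
    at full strength, ramping and relaxing per regime, with an incomplete-
    recovery residual in the skin habitat.
    """
    design = design or ExperimentDesign()
    effects = effects or SelectionEffects()
    # every stratum runs the explicit dynamic process so that control and
    # treated cells differ only through selection, never through the
    # stationary approximation
    base_cfg = SimulationConfig(
        n_samples=design.tanks * design.replicates,
        N_local=N_local,
        m=m,
        depth=depth,
        mode="dynamic",
        seed=seed,
    )
    return simulate_experiment(design, base_cfg, effects, seed=seed, S=S)
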