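"""Forward-in-time diploid Wright-Fisher simulation of fluctuating selection.

Simulates a panmictic population of N diploids carrying a recombining
region of L base pairs.  New mutations arise as Poisson events at rate
mu*L per gamete; a fraction ``prop_selected`` of them are selected, with
a per-locus relative effect (``base_effect``) drawn once from an
Exponential(mean 1) distribution of fitness effects.  Selection is
temporally fluctuating: the timeline after burn-in is tiled by selective
periods, each with a signed mean effect, and the realized per-locus
selection coefficient in a period is ``base_effect * mean_s`` — the same
loci flip effect sign across regimes.  Fitness is multiplicative across
loci with per-locus genotype fitnesses 1, 1 + h*s_t, 1 + s_t.
Recombination is modeled as Poisson crossovers at rate r*L per meiosis.

Standing variation can be established either by an explicit neutral
burn-in or, much faster, by seeding segregating sites directly from the
neutral mutation-drift equilibrium site-frequency spectrum (counts
proportional to 1/i), which is the desk-scale default.  Selected effects
are dormant during burn-in.

"Known selected loci" are the selected loci segregating at the first
post-burn-in generation; their frequency paths over the sampled window
are what the trajectory containers record and what the inference modules
consume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import popgen

__all__ = [
    "SelectionPeriod",
    "SelectionRegime",
    "SimulationConfig",
    "LocusEffect",
    "TrajectorySet",
    "draw_effects",
    "simulate_replicate",
    "simulate_single_locus",
    "run_experiment",
    "write_trajectories",
    "read_trajectories",
]


@dataclass(frozen=True)
class SelectionPeriod:
    """One selective period: [start_gen, end_gen) with a signed mean effect."""

    start_gen: int
    end_gen: int
    mean_s: float

    def __post_init__(self) -> None:
        if self.start_gen >= self.end_gen:
            raise ValueError("period must satisfy start_gen < end_gen")


@dataclass(frozen=True)
class SelectionRegime:
    """Ordered selective periods tiling the post-burn-in timeline."""

    periods: tuple[SelectionPeriod, ...]

    def __init__(self, periods: Iterable[SelectionPeriod | tuple]) -> None:
        ps = tuple(
            p if isinstance(p, SelectionPeriod) else SelectionPeriod(*p)
            for p in periods
        )
        if not ps:
            raise ValueError("at least one selective period is required")
        for a, b in zip(ps, ps[1:]):
            if a.end_gen != b.start_gen:
                raise ValueError("periods must tile the timeline without gaps/overlap")
        object.__setattr__(self, "periods", ps)

    @property
    def start_gen(self) -> int:
        return self.periods[0].start_gen

    @property
    def end_gen(self) -> int:
        return self.periods[-1].end_gen

    @property
    def breakpoints(self) -> tuple[int, ...]:
        """Generations at which the regime shifts (period boundaries)."""
        return tuple(p.start_gen for p in self.periods[1:])

    def mean_s_at(self, gen: int) -> float:
        for p in self.periods:
            if p.start_gen <= gen < p.end_gen:
                return p.mean_s
        raise ValueError(f"generation {gen} outside the regime span")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forward simulation.

    Attributes
    ----------
    N : diploid census size.
    L : region length in base pairs.
    mu : per-site per-generation mutation rate.
    r : per-site per-generation recombination rate.
    h : dominance coefficient applied to all selected loci.
    prop_selected : fraction of new mutations that are selected.
    periods : the fluctuating-selection regime after burn-in.
    burn_in : neutral generations run before the regime starts.
    init : "equilibrium" seeds standing variation from the neutral SFS;
        "monomorphic" starts without variation (mutation builds it up).
    replicates : number of independent replicates for run_experiment.
    seed : base RNG seed for run_experiment.
    """

    N: int
    L: int
    mu: float
    r: float
    periods: SelectionRegime
    h: float = 0.5
    prop_selected: float = 0.05
    burn_in: int = 0
    init: str = "equilibrium"
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mutation and recombination rates must be non-negative")
        if not (0.0 <= self.prop_selected <= 1.0):
            raise ValueError("prop_selected must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.init not in ("equilibrium", "monomorphic"):
            raise ValueError("init must be 'equilibrium' or 'monomorphic'")
        if isinstance(self.periods, (list, tuple)) and not isinstance(
            self.periods, SelectionRegime
        ):
            object.__setattr__(self, "periods", SelectionRegime(self.periods))


@dataclass(frozen=True)
class LocusEffect:
    """Per-locus fitness-effect annotation.

    ``base_effect`` is the non-negative relative effect drawn once per
    locus (Exponential with mean 1 for selected loci, 0 for neutral
    ones); the realized signed coefficient under a period with mean
    effect ``mean_s`` is ``base_effect * mean_s``.
    """

    position: float
    base_effect: float
    is_selected: bool

    def realized_s(self, mean_s: float) -> float:
        return self.base_effect * mean_s


@dataclass
class TrajectorySet:
    """True allele-frequency paths of the known selected loci of one replicate.

    ``freqs`` has shape (n_loci, n_generations); column ``g`` is the
    frequency at generation ``g`` since the end of burn-in (generation 0
    is the state before any post-burn-in selection).
    """

    replicate_id: int
    generations: np.ndarray
    freqs: np.ndarray
    positions: np.ndarray
    base_effects: np.ndarray
    is_selected: np.ndarray
    known: np.ndarray
    h: float
    regime: SelectionRegime

    def __post_init__(self) -> None:
        if self.freqs.shape != (len(self.positions), len(self.generations)):
            raise ValueError("freqs shape inconsistent with loci/generations")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[0]

    @property
    def locus_ids(self) -> np.ndarray:
        return np.arange(self.n_loci)

    def freq_at(self, times: Sequence[int]) -> np.ndarray:
        """Frequencies of all loci at the requested generations, shape (n_loci, n_times)."""
        times = np.asarray(times, dtype=int)
        idx = np.searchsorted(self.generations, times)
        if np.any(idx >= len(self.generations)) or np.any(
            self.generations[np.minimum(idx, len(self.generations) - 1)] != times
        ):
            raise ValueError("requested generations outside the recorded window")
        return self.freqs[:, idx]

    def realized_s(self, gen: int) -> np.ndarray:
        """Realized per-locus selection coefficients at a generation."""
        return self.base_effects * self.regime.mean_s_at(gen)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per locus x generation."""
        n_loci, n_gen = self.freqs.shape
        mean_s = np.array([self.regime.mean_s_at(g) for g in self.generations[:-1]])
        mean_s = np.append(mean_s, mean_s[-1] if len(mean_s) else 0.0)
        return pd.DataFrame(
            {
                "replicate_id": self.replicate_id,
                "locus_id": np.repeat(np.arange(n_loci), n_gen),
                "position": np.repeat(self.positions, n_gen),
                "generation": np.tile(self.generations, n_loci),
                "frequency": self.freqs.ravel(),
                "realized_s": np.repeat(self.base_effects, n_gen) * np.tile(mean_s, n_loci),
                "h": self.h,
                "is_selected": np.repeat(self.is_selected.astype(int), n_gen),
            }
        )


def draw_effects(
    n: int, prop_selected: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fitness-effect annotations for ``n`` new mutations.

    Returns ``(base_effect, is_selected)``; selected loci receive an
    Exponential(mean 1) base effect, neutral loci an effect of 0.
    """
    is_selected = rng.random(n) < prop_selected
    base = np.where(is_selected, rng.exponential(1.0, size=n), 0.0)
    return base, is_selected


class _Population:
    """Haplotype matrix plus per-site annotations; rows 2i, 2i+1 belong to individual i."""

    def __init__(self, N: int, L: int):
        self.N = N
        self.L = L
        self.H = np.zeros((2 * N, 0), dtype=np.uint8)
        self.pos = np.zeros(0, dtype=float)
        self.base = np.zeros(0, dtype=float)
        self.sel = np.zeros(0, dtype=bool)
        self.tracked = np.zeros(0, dtype=bool)

    def freqs(self) -> np.ndarray:
        if self.H.shape[1] == 0:
            return np.zeros(0)
        return self.H.mean(axis=0)

    def seed_equilibrium(self, theta_region: float, prop_selected: float,
                         rng: np.random.Generator) -> None:
        """Seed standing variation from the neutral equilibrium SFS.

        The number of segregating sites is Poisson with mean
        theta * H_{2N-1}; each site's derived-allele count i is drawn
        with probability proportional to 1/i and the copies are placed
        on haplotypes at random (no linkage disequilibrium at time 0).
        """
        two_n = 2 * self.N
        harmonic = np.sum(1.0 / np.arange(1, two_n))
        n_sites = rng.poisson(theta_region * harmonic)
        if n_sites == 0:
            return
        counts = np.arange(1, two_n)
        probs = (1.0 / counts) / harmonic
        derived = rng.choice(counts, size=n_sites, p=probs)
        H = np.zeros((two_n, n_sites), dtype=np.uint8)
        for j, d in enumerate(derived):
            carriers = rng.choice(two_n, size=d, replace=False)
            H[carriers, j] = 1
        self.H = H
        self.pos = rng.uniform(0.0, self.L, size=n_sites)
        self.base, self.sel = draw_effects(n_sites, prop_selected, rng)
        self.tracked = np.zeros(n_sites, dtype=bool)

    def step(self, mean_s: float, h: float, mu: float, r: float,
             prop_selected: float, rng: np.random.Generator) -> None:
        """One Wright-Fisher generation: selection, reproduction, recombination, mutation."""
        N, two_n = self.N, 2 * self.N
        s_loc = self.base * mean_s
        active = np.nonzero(self.sel & (s_loc != 0.0))[0]

        if active.size:
            G = self.H[0::2, active].astype(np.int8) + self.H[1::2, active]
            s_act = s_loc[active]
            lw = np.log1p(s_act * (G == 2) + h * s_act * (G == 1)).sum(axis=1)
            w = np.exp(lw - lw.max())
            prob = w / w.sum()
        else:
            prob = None

        mothers = rng.choice(N, size=N, p=prob)
        fathers = rng.choice(N, size=N, p=prob)
        par = np.empty(two_n, dtype=np.int64)
        par[0::2] = mothers
        par[1::2] = fathers

        start = rng.integers(0, 2, size=two_n)
        n_x = rng.poisson(r * self.L, size=two_n)
        H_new = self.H[2 * par + start]
        # gametes with crossovers, batched by crossover count: the segment
        # parity at each site is the count of crossover points below it, mod 2
        for k in np.unique(n_x[n_x > 0]):
            idx = np.nonzero(n_x == k)[0]
            xs = rng.uniform(0.0, self.L, size=(idx.size, k))
            parity = (xs[:, :, None] < self.pos[None, None, :]).sum(axis=1) & 1
            other = self.H[2 * par[idx] + 1 - start[idx]]
            H_new[idx] = np.where(parity == 0, H_new[idx], other)

        n_mut = rng.poisson(two_n * mu * self.L)
        if n_mut:
            gam = rng.integers(0, two_n, size=n_mut)
            newpos = rng.uniform(0.0, self.L, size=n_mut)
            newbase, newsel = draw_effects(n_mut, prop_selected, rng)
            cols = np.zeros((two_n, n_mut), dtype=np.uint8)
            cols[gam, np.arange(n_mut)] = 1
            H_new = np.concatenate([H_new, cols], axis=1)
            self.pos = np.concatenate([self.pos, newpos])
            self.base = np.concatenate([self.base, newbase])
            self.sel = np.concatenate([self.sel, newsel])
            self.tracked = np.concatenate([self.tracked, np.zeros(n_mut, dtype=bool)])

        self.H = H_new
        self._prune()

    def _prune(self) -> None:
        f = self.freqs()
        keep = self.tracked | ((f > 0.0) & (f < 1.0))
        if not keep.all():
            self.H = self.H[:, keep]
            self.pos = self.pos[keep]
            self.base = self.base[keep]
            self.sel = self.sel[keep]
            self.tracked = self.tracked[keep]


def simulate_replicate(
    config: SimulationConfig, rng: np.random.Generator, replicate_id: int = 0
) -> TrajectorySet:
    """Run one forward replicate and record the known-selected-locus trajectories.

    Burn-in (and equilibrium seeding) is strictly neutral: selected
    effects are dormant until generation 0 of the selective regime.
    """
    pop = _Population(config.N, config.L)
    if config.init == "equilibrium":
        theta_region = 4.0 * config.N * config.mu * config.L
        pop.seed_equilibrium(theta_region, config.prop_selected, rng)
    for _ in range(config.burn_in):
        pop.step(0.0, config.h, config.mu, config.r, config.prop_selected, rng)

    # Known selected loci: selected and segregating at the window start.
    f = pop.freqs()
    known_mask = pop.sel & (f > 0.0) & (f < 1.0)
    pop.tracked = known_mask.copy()
    order = np.nonzero(pop.tracked)[0]
    positions = pop.pos[order].copy()
    base_effects = pop.base[order].copy()

    regime = config.periods
    t0, t1 = regime.start_gen, regime.end_gen
    n_gen = t1 - t0
    gens = np.arange(t0, t1 + 1)
    freqs = np.empty((order.size, n_gen + 1), dtype=float)

    def _tracked_freqs() -> np.ndarray:
        f_all = pop.freqs()
        return f_all[pop.tracked]

    freqs[:, 0] = _tracked_freqs()
    for k, g in enumerate(range(t0, t1)):
        pop.step(regime.mean_s_at(g), config.h, config.mu, config.r,
                 config.prop_selected, rng)
        freqs[:, k + 1] = _tracked_freqs()

    return TrajectorySet(
        replicate_id=replicate_id,
        generations=gens,
        freqs=freqs,
        positions=positions,
        base_effects=base_effects,
        is_selected=np.ones(order.size, dtype=bool),
        known=np.ones(order.size, dtype=bool),
        h=config.h,
        regime=regime,
    )


def simulate_single_locus(
    p0,
    s: float,
    h: float,
    N: int,
    n_gen: int,
    rng: np.random.Generator,
    n_rep: int = 1,
) -> np.ndarray:
    """Single-locus diploid Wright-Fisher trajectories, shape (n_rep, n_gen + 1).

    Each generation applies the deterministic selection recursion and then
    binomial resampling of 2N allele copies.  A light-weight path used for
    drift oracles and for generating exchangeable unlinked loci; ``p0``
    may be an array of length ``n_rep`` to start each path differently.
    """
    fp = popgen.FitnessParams(s=s, h=h) if s != 0.0 else None
    p0 = np.asarray(p0, dtype=float)
    if p0.ndim == 0:
        p = np.full(n_rep, float(p0))
    else:
        if len(p0) != n_rep:
            raise ValueError("array p0 must have length n_rep")
        p = p0.copy()
    out = np.empty((n_rep, n_gen + 1), dtype=float)
    out[:, 0] = p
    two_n = 2 * N
    for g in range(n_gen):
        if fp is not None:
            p = p + popgen.deterministic_delta_p(p, fp)
        p = np.clip(p, 0.0, 1.0)
        p = rng.binomial(two_n, p) / two_n
        out[:, g + 1] = p
    return out


def run_experiment(config: SimulationConfig) -> list[TrajectorySet]:
    """Run ``config.replicates`` independent replicates.

    Sub-seeds are spawned deterministically from ``config.seed``, so the
    output is fully reproducible from the configuration alone.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates)
    return [
        simulate_replicate(config, np.random.default_rng(child), replicate_id=i)
        for i, child in enumerate(children)
    ]


def write_trajectories(trajectories: Iterable[TrajectorySet], out_dir: str) -> list[str]:
    """Write one trajectory TSV per replicate; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for ts in trajectories:
        path = os.path.join(out_dir, f"trajectories_rep{ts.replicate_id}.tsv")
        ts.to_frame().to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_trajectories(path: str) -> pd.DataFrame:
    """Read a trajectory TSV back as a long-format frame."""
    return pd.read_csv(path, sep="\t")
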