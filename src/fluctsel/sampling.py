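"""Observation schemes over true allele-frequency trajectories.

Two designs mirror the main ways temporal genomic data are collected:

* **museum/herbarium ("continuous")** — one potential time point per
  generation over a window, with per-point sample sizes following a
  geometric ramp that intensifies toward the present.  Generations whose
  rounded sample size is zero are dropped, mimicking sparse early
  collections.
* **discrete** — a small number of equally spaced time points straddling
  a known selective shift, each with the same sample size (a
  before/after design).

Sampling noise is binomial: each diploid individual contributes two
allele copies drawn with replacement from the population frequency
(N >> n in all scenarios, so binomial rather than hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrajectorySet

__all__ = [
    "SamplingDesign",
    "museum_design",
    "discrete_design",
    "sample_counts",
    "binomial_counts",
    "attach_env",
    "write_counts",
    "read_counts",
]

COUNT_COLUMNS = ["locus_id", "time", "alleles_sampled", "derived_count"]


@dataclass(frozen=True)
class SamplingDesign:
    """Time points and per-point diploid sample sizes of one observation scheme."""

    time_points: tuple[int, ...]
    n_per_point: tuple[int, ...]
    kind: str  # "continuous" | "discrete"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points)
        n = np.asarray(self.n_per_point)
        if len(t) != len(n):
            raise ValueError("time_points and n_per_point must have equal length")
        if len(t) == 0:
            raise ValueError("design must contain at least one time point")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(n < 1):
            raise ValueError("sample sizes must all be at least 1")
        if self.kind not in ("continuous", "discrete"):
            raise ValueError("kind must be 'continuous' or 'discrete'")

    @property
    def total_n(self) -> int:
        return int(sum(self.n_per_point))

    @property
    def alleles_per_point(self) -> np.ndarray:
        return 2 * np.asarray(self.n_per_point, dtype=int)


def museum_design(window: int, total_n: int, ramp: float = 1.01) -> SamplingDesign:
    """Museum-style continuous design over generations 0..window.

    Per-generation sample sizes are proportional to a geometric ramp
    ``ramp**g`` ending at the present and are rounded by the
    largest-remainder method so that they sum exactly to ``total_n``.
    ``ramp=1`` degenerates to uniform sampling.  Generations rounded to
    zero samples are dropped from the design.
    """
    if window < 1:
        raise ValueError("window must span at least one generation")
    if ramp < 1.0:
        raise ValueError("ramp must be >= 1")
    gens = np.arange(window + 1)
    weights = np.power(float(ramp), gens)
    quota = weights / weights.sum() * total_n
    n = np.floor(quota).astype(int)
    short = total_n - n.sum()
    if short < 0:  # pragma: no cover - floor never overshoots
        raise ValueError("infeasible rounding")
    if short > 0:
        frac = quota - np.floor(quota)
        # ties broken toward the present (later generations first)
        order = np.lexsort((-gens, -frac))
        n[order[:short]] += 1
    keep = n > 0
    if not keep.any():
        raise ValueError(f"total_n={total_n} too small for any time point")
    return SamplingDesign(
        time_points=tuple(int(g) for g in gens[keep]),
        n_per_point=tuple(int(v) for v in n[keep]),
        kind="continuous",
    )


def discrete_design(
    shift_gen: int, steps: int = 6, n_per_step: int = 40, spacing: int = 10
) -> SamplingDesign:
    """Equally spaced before/after design straddling a known selective shift.

    ``steps`` time points with gap ``spacing`` are centred on
    ``shift_gen`` so that half the points fall before and half after the
    shift (the shift lies midway between the two central points for even
    ``steps``).
    """
    if steps < 2:
        raise ValueError("a before/after design needs at least 2 time points")
    if spacing < 1:
        raise ValueError("spacing must be at least one generation")
    offsets = spacing * (np.arange(steps) - steps / 2.0) + spacing / 2.0
    times = np.rint(shift_gen + offsets).astype(int)
    if np.any(np.diff(times) <= 0):
        raise ValueError("spacing too small to give distinct time points")
    if not (times[0] < shift_gen <= times[-1]):
        raise ValueError("design must straddle the shift generation")
    return SamplingDesign(
        time_points=tuple(int(t) for t in times),
        n_per_point=tuple([int(n_per_step)] * steps),
        kind="discrete",
    )


def binomial_counts(
    p: np.ndarray, alleles: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Binomial(alleles, p) draws; p of shape (n_loci, n_times), alleles of shape (n_times,)."""
    p = np.asarray(p, dtype=float)
    alleles = np.broadcast_to(np.asarray(alleles, dtype=int), p.shape)
    return rng.binomial(alleles, p)


def sample_counts(
    trajectories: TrajectorySet,
    design: SamplingDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample allele counts for every tracked locus at the design's time points.

    Returns the long-format counts table consumed by the inference
    module: columns locus_id, time, alleles_sampled, derived_count.
    """
    times = np.asarray(design.time_points, dtype=int)
    p = trajectories.freq_at(times)
    alleles = design.alleles_per_point
    counts = binomial_counts(p, alleles, rng)
    n_loci = trajectories.n_loci
    return pd.DataFrame(
        {
            "locus_id": np.repeat(trajectories.locus_ids, len(times)),
            "time": np.tile(times, n_loci),
            "alleles_sampled": np.tile(alleles, n_loci),
            "derived_count": counts.ravel(),
        }
    )


def attach_env(counts: pd.DataFrame, env_by_time: dict[int, float]) -> pd.DataFrame:
    """Attach an environmental covariate column keyed by time point."""
    out = counts.copy()
    out["env"] = out["time"].map(env_by_time)
    if out["env"].isna().any():
        missing = sorted(set(out.loc[out["env"].isna(), "time"]))
        raise ValueError(f"env covariate missing for time points {missing}")
    return out


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing required columns: {missing}")
    return df
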