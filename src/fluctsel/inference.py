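"""Selection inference from sampled allele-count time series.

The observation model is binomial: at time t a locus j contributes a
derived-allele count y ~ Binomial(m, p_j(t)) with

    logit p_j(t) = alpha_j + f(t),

where f is a continuous piecewise-linear function of time shared across
loci and alpha_j is a locus-specific intercept.  The slope of f within a
segment is the effective selection coefficient S of that selection
regime (the logit of an allele under haploid-equivalent selection moves
linearly at rate S per generation); breakpoints of f are the generations
at which the selection regime shifts.  With many loci sharing the
segment slopes, the fitted slope estimates the *mean* S across loci —
under a distribution of fitness effects the loci are heterogeneous and
the joint fit averages over them.

Fitting is by full Newton iteration on the binomial log-likelihood,
exploiting the block structure of the Hessian (diagonal in the locus
intercepts) through a Schur complement, which makes a single fit cheap
enough to support a grid search over breakpoint locations.  Breakpoints
are searched over the observed time points (integer-generation
resolution) under a minimum of three time points per segment, using a
deterministic coarse-to-fine scheme: a subsampled exhaustive grid,
candidates seeded from the best fit with one fewer breakpoint (which
guarantees the maximized log-likelihood is non-decreasing in the number
of breakpoints), then coordinate-descent refinement at full resolution.
Model selection over the number of breakpoints is by BIC with effective
sample size equal to the total number of sampled allele copies.

Loci whose counts are zero at every time point, or equal to the number
of sampled alleles at every time point, carry no finite intercept
estimate (complete separation) and are excluded and flagged; individual
time points at observed frequency 0 or 1 are informative and retained.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as _expit

from . import popgen

__all__ = [
    "SlopeEstimate",
    "InstantEstimate",
    "SegmentedFit",
    "SeparationError",
    "logit_slope",
    "fit_segmented",
    "select_breakpoints",
    "instantaneous_S",
    "fit_with_environment",
    "s_hat_from_fit",
    "counts_from_vcf",
]

_PROFILE_DROP = 1.92  # chi2(1)/2 at 95%: profile-likelihood interval half-width


class SeparationError(ValueError):
    """Every locus is completely separated; no slope is estimable."""


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    """Counts pivoted onto the locus x time grid.

    Cells without an observation carry M = 0 and contribute nothing to
    the likelihood, so ragged data are handled naturally; duplicate
    (locus, time) rows are summed.
    """

    Y: np.ndarray          # derived counts, (J, T)
    M: np.ndarray          # alleles sampled, (J, T)
    J: int
    times: np.ndarray      # sorted unique observed times, (T,)
    n_obs: int             # original number of count rows
    flagged_loci: list     # locus ids dropped for complete separation
    env_t: np.ndarray | None = None  # per-time-point env covariate


def _prepare(counts: pd.DataFrame, env_col: str | None = None) -> _Prepared:
    required = ["locus_id", "time", "alleles_sampled", "derived_count"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    y = counts["derived_count"].to_numpy(dtype=float)
    m = counts["alleles_sampled"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("derived counts must satisfy 0 <= count <= alleles_sampled")
    loci = counts["locus_id"].to_numpy()
    uniq, j = np.unique(loci, return_inverse=True)
    times, tix = np.unique(counts["time"].to_numpy(dtype=float),
                           return_inverse=True)
    if len(times) < 2:
        raise ValueError("at least two distinct time points are required")
    J_all, T = len(uniq), len(times)
    Y = np.zeros((J_all, T))
    M = np.zeros((J_all, T))
    np.add.at(Y, (j, tix), y)
    np.add.at(M, (j, tix), m)

    tot_y, tot_m = Y.sum(axis=1), M.sum(axis=1)
    separated = (tot_y == 0.0) | (tot_y == tot_m)
    flagged = [uniq[i] for i in np.nonzero(separated)[0]]
    if separated.all():
        raise SeparationError(
            "all loci completely separated (all-zero or all-fixed counts)"
        )
    Y, M = Y[~separated], M[~separated]

    env_t = None
    if env_col is not None:
        if env_col not in counts.columns:
            raise ValueError(f"env column '{env_col}' not present")
        env = counts[env_col].to_numpy(dtype=float)
        env_t = np.full(T, np.nan)
        for ti, ee in zip(tix, env):
            if not np.isnan(env_t[ti]) and env_t[ti] != ee:
                raise ValueError("env covariate must be constant within a time point")
            env_t[ti] = ee
        if np.isnan(env_t).any():
            raise ValueError("env covariate missing for some time points")
    return _Prepared(Y=Y, M=M, J=Y.shape[0], times=times, n_obs=len(y),
                     flagged_loci=flagged, env_t=env_t)


# ---------------------------------------------------------------------------
# Newton solver for the shared-slope binomial GLM
# ---------------------------------------------------------------------------


def _design(times: np.ndarray, breakpoints: tuple[float, ...],
            extra: np.ndarray | None = None) -> np.ndarray:
    """Per-time-point design: linear time plus one hinge per breakpoint."""
    cols = [times] + [np.maximum(0.0, times - b) for b in breakpoints]
    if extra is not None:
        cols.append(extra)
    return np.column_stack(cols)


def _loglik(Y, M, eta):
    # binomial log-likelihood in canonical form (constants dropped):
    # sum Y*eta - M*log(1 + exp(eta)), stable via logaddexp
    return float(np.sum(Y * eta) - np.sum(M * np.logaddexp(0.0, eta)))


def _newton(Y, M, Xt, alpha0=None, beta0=None, max_iter=100, tol=1e-10):
    """Maximize the binomial log-likelihood in (alpha_j, beta) jointly.

    ``Y`` and ``M`` are (J, T) count/trial grids and ``Xt`` the (T, K)
    per-time design.  The Hessian is diagonal in the intercepts, so each
    Newton step solves only the K x K Schur complement.  Returns
    (loglik, alpha, beta, cov_beta, converged); cov_beta is the inverse
    Schur complement, i.e. the covariance of beta with the intercepts
    profiled out.
    """
    J, T = Y.shape
    K = Xt.shape[1]
    if alpha0 is None:
        tot_y, tot_m = Y.sum(axis=1), M.sum(axis=1)
        alpha = np.log((tot_y + 0.5) / (tot_m - tot_y + 0.5))
    else:
        alpha = alpha0.copy()
    beta = np.zeros(K) if beta0 is None else beta0.copy()

    eta = alpha[:, None] + (Xt @ beta)[None, :]
    ll = _loglik(Y, M, eta)
    converged = False
    S = np.eye(K)
    for _ in range(max_iter):
        mu = np.clip(_expit(eta), 1e-12, 1.0 - 1e-12)
        resid = Y - M * mu
        W = M * mu * (1.0 - mu)
        g_a = resid.sum(axis=1)
        D = W.sum(axis=1) + 1e-10
        g_b = Xt.T @ resid.sum(axis=0)
        C = Xt.T @ (W.sum(axis=0)[:, None] * Xt)
        B = W @ Xt                             # (J, K)
        S = C - B.T @ (B / D[:, None])
        rhs = g_b - B.T @ (g_a / D)
        try:
            d_beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            d_beta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        d_alpha = (g_a - B @ d_beta) / D

        step = 1.0
        for _half in range(25):
            a_new = alpha + step * d_alpha
            b_new = beta + step * d_beta
            eta_new = a_new[:, None] + (Xt @ b_new)[None, :]
            ll_new = _loglik(Y, M, eta_new)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        alpha, beta, eta = a_new, b_new, eta_new
        # concave likelihood: converged only when a full Newton step no
        # longer moves the log-likelihood (halved steps mean we are still
        # far from the optimum even if the gain this round was tiny)
        if step == 1.0 and abs(ll_new - ll) < tol * (1.0 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    try:
        cov = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(S)
    return ll, alpha, beta, cov, converged


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class SlopeEstimate:
    """Shared logit-slope (effective selection coefficient) estimate."""

    S: float
    se: float
    loglik: float
    n_loci: int
    flagged_loci: list
    converged: bool
    estimable: bool = True


@dataclass
class InstantEstimate:
    """Instantaneous effective selection coefficient from one before/after pair."""

    S_t: float
    se: float
    estimable: bool = True


@dataclass
class SegmentedFit:
    """Segmented (breakpoint) logistic-regression fit.

    ``breakpoints`` holds one (lower, estimate, upper) triple per
    breakpoint, the bounds being 95% profile-likelihood limits over the
    breakpoint grid with the other breakpoints held fixed.
    ``S_per_segment`` holds (S, se) per segment, segments ordered in
    time; ``model_scores`` maps each candidate breakpoint count to its
    (log-likelihood, BIC) when produced by :func:`select_breakpoints`.
    """

    n_breakpoints: int
    breakpoints: list        # [(lo, hat, hi), ...]
    S_per_segment: list      # [(S, se), ...]
    loglik: float
    bic: float
    converged: bool
    n_loci: int
    n_obs: int
    n_alleles: float
    flagged_loci: list
    model_scores: dict = field(default_factory=dict)
    env_interaction: tuple | None = None   # (gamma, se) per-unit-env change in S
    env_flag: str | None = None

    @property
    def breakpoint_estimates(self) -> list:
        return [b[1] for b in self.breakpoints]

    @property
    def segment_slopes(self) -> np.ndarray:
        return np.array([s for s, _ in self.S_per_segment])


def _segment_stats(beta: np.ndarray, cov: np.ndarray, n_seg: int):
    """Cumulative-sum slopes and their SEs from hinge coefficients."""
    out = []
    for i in range(n_seg):
        u = np.zeros(len(beta))
        u[: i + 1] = 1.0
        S = float(u @ beta)
        var = float(u @ cov @ u)
        out.append((S, math.sqrt(max(var, 0.0))))
    return out


def _bic(ll: float, k: int, J: int, n_alleles: float, extra_params: int = 0) -> float:
    df = J + (k + 1) + k + extra_params
    return -2.0 * ll + df * math.log(max(n_alleles, 2.0))


# ---------------------------------------------------------------------------
# breakpoint search
# ---------------------------------------------------------------------------


def _feasible(idx: tuple[int, ...], n_times: int, min_pts: int) -> bool:
    prev = -1
    for i in idx:
        if i - prev < min_pts:
            return False
        prev = i
    return n_times - 1 - prev >= min_pts


def _fit_at(prep: _Prepared, bp_idx: tuple[int, ...], warm: dict,
            extra: np.ndarray | None = None, screen: bool = False):
    bps = tuple(float(prep.times[i]) for i in bp_idx)
    Xt = _design(prep.times, bps, extra)
    a0, b0 = warm.get("alpha"), warm.get("beta")
    if b0 is not None and len(b0) != Xt.shape[1]:
        a0 = b0 = None
    if screen:
        # cheap ranking pass: a few warm-started Newton steps are enough
        # to order candidates; the shortlist is refit to convergence
        ll, alpha, beta, cov, conv = _newton(prep.Y, prep.M, Xt,
                                             alpha0=a0, beta0=b0, max_iter=4)
        warm["alpha"], warm["beta"] = alpha, beta
        return ll, alpha, beta, cov, conv
    ll, alpha, beta, cov, conv = _newton(prep.Y, prep.M, Xt, alpha0=a0, beta0=b0)
    if not conv and a0 is not None:
        # warm start led Newton astray: retry cold and keep the better optimum
        ll2, alpha2, beta2, cov2, conv2 = _newton(prep.Y, prep.M, Xt)
        if ll2 > ll:
            ll, alpha, beta, cov, conv = ll2, alpha2, beta2, cov2, conv2
    warm["alpha"], warm["beta"] = alpha, beta
    return ll, alpha, beta, cov, conv


def _search_breakpoints(prep: _Prepared, k: int, min_pts: int,
                        coarse_budget: int, seed_idx: tuple[int, ...] | None,
                        extra: np.ndarray | None = None):
    """Coarse-to-fine maximum-likelihood search over k breakpoint locations."""
    n_times = len(prep.times)
    all_idx = list(range(min_pts - 1, n_times - min_pts))
    if not all_idx or len(prep.times) < (k + 1) * min_pts:
        raise ValueError(
            f"too few distinct time points ({n_times}) for {k} breakpoints "
            f"with {min_pts} points per segment"
        )

    step = 1
    while math.comb(max(len(all_idx[::step]), k), k) > coarse_budget:
        step += 1
    coarse = all_idx[::step]

    warm: dict = {}
    candidates = [c for c in itertools.combinations(coarse, k)
                  if _feasible(c, n_times, min_pts)]
    if seed_idx is not None:
        for c in all_idx:
            cand = tuple(sorted(set(seed_idx) | {c}))
            if len(cand) == k and _feasible(cand, n_times, min_pts):
                candidates.append(cand)
    if not candidates:
        raise ValueError(f"no feasible breakpoint placement for k={k}")

    screened = []
    for cand in candidates:
        ll, *_ = _fit_at(prep, cand, warm, extra, screen=True)
        screened.append((ll, cand))
    screened.sort(key=lambda x: (-x[0], x[1]))
    best = None
    for _, cand in screened[:10]:
        ll, alpha, beta, cov, conv = _fit_at(prep, cand, warm, extra)
        if best is None or ll > best[0]:
            best = (ll, cand, alpha, beta, cov, conv)

    # coordinate-descent refinement at full (observed-time) resolution
    profiles = [dict() for _ in range(k)]
    for _pass in range(3):
        improved = False
        cur = list(best[1])
        for pos in range(k):
            lo = cur[pos - 1] + min_pts if pos > 0 else min_pts - 1
            hi = cur[pos + 1] - min_pts if pos < k - 1 else n_times - 1 - min_pts
            profiles[pos] = {}
            for c in range(lo, hi + 1):
                cand = tuple(cur[:pos] + [c] + cur[pos + 1:])
                ll, alpha, beta, cov, conv = _fit_at(prep, cand, warm, extra)
                profiles[pos][c] = ll
                if ll > best[0] + 1e-9:
                    best = (ll, cand, alpha, beta, cov, conv)
                    improved = True
            cur = list(best[1])
        if not improved:
            break

    ll, bp_idx, alpha, beta, cov, conv = best
    intervals = []
    for pos in range(k):
        prof = profiles[pos]
        inside = [prep.times[c] for c, l in prof.items() if l >= ll - _PROFILE_DROP]
        hat = float(prep.times[bp_idx[pos]])
        lo_b = float(min(inside)) if inside else hat
        hi_b = float(max(inside)) if inside else hat
        intervals.append((min(lo_b, hat), hat, max(hi_b, hat)))
    return ll, bp_idx, intervals, alpha, beta, cov, conv


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def logit_slope(counts: pd.DataFrame) -> SlopeEstimate:
    """Shared logit-slope estimate of the effective selection coefficient S.

    Binomial-response logistic regression of derived counts on time with
    locus-specific intercepts.  For a single locus observed at two time
    points this equals Delta logit(p_hat) / Delta t exactly.
    """
    try:
        prep = _prepare(counts)
    except SeparationError:
        return SlopeEstimate(S=float("nan"), se=float("nan"), loglik=float("nan"),
                             n_loci=0, flagged_loci=sorted(counts["locus_id"].unique()),
                             converged=False, estimable=False)
    Xt = _design(prep.times, ())
    ll, alpha, beta, cov, conv = _newton(prep.Y, prep.M, Xt)
    return SlopeEstimate(S=float(beta[0]), se=float(math.sqrt(max(cov[0, 0], 0.0))),
                         loglik=ll, n_loci=prep.J, flagged_loci=prep.flagged_loci,
                         converged=conv)


def fit_segmented(
    counts: pd.DataFrame,
    k: int,
    min_pts: int = 3,
    coarse_budget: int = 1500,
    _seed_idx: tuple[int, ...] | None = None,
    _prep: _Prepared | None = None,
) -> SegmentedFit:
    """Segmented binomial logistic regression with ``k`` breakpoints.

    Maximizes the joint binomial log-likelihood over breakpoint
    locations (grid of observed time points, at least ``min_pts`` time
    points per segment) and segment slopes; the piecewise-linear logit
    predictor is continuous at the breakpoints.  ``k = 0`` reduces
    exactly to :func:`logit_slope`.
    """
    if k < 0:
        raise ValueError("number of breakpoints must be non-negative")
    prep = _prep if _prep is not None else _prepare(counts)
    n_alleles = float(prep.M.sum())
    if k == 0:
        Xt = _design(prep.times, ())
        ll, alpha, beta, cov, conv = _newton(prep.Y, prep.M, Xt)
        return SegmentedFit(
            n_breakpoints=0, breakpoints=[],
            S_per_segment=_segment_stats(beta, cov, 1),
            loglik=ll, bic=_bic(ll, 0, prep.J, n_alleles), converged=conv,
            n_loci=prep.J, n_obs=prep.n_obs, n_alleles=n_alleles,
            flagged_loci=prep.flagged_loci,
        )
    ll, bp_idx, intervals, alpha, beta, cov, conv = _search_breakpoints(
        prep, k, min_pts, coarse_budget, _seed_idx
    )
    return SegmentedFit(
        n_breakpoints=k, breakpoints=intervals,
        S_per_segment=_segment_stats(beta, cov, k + 1),
        loglik=ll, bic=_bic(ll, k, prep.J, n_alleles), converged=conv,
        n_loci=prep.J, n_obs=prep.n_obs, n_alleles=n_alleles,
        flagged_loci=prep.flagged_loci,
    )


def select_breakpoints(
    counts: pd.DataFrame,
    k_max: int,
    min_pts: int = 3,
    coarse_budget: int = 1500,
) -> SegmentedFit:
    """Fit k = 0..k_max breakpoints and return the fit minimizing the BIC.

    The BIC uses the total number of sampled allele copies as the
    effective sample size and counts locus intercepts, segment slopes
    and breakpoint locations as parameters.  Scores for every candidate
    k are reported in ``model_scores``.  Because each k is seeded with
    the best (k-1)-breakpoint solution, the maximized log-likelihood is
    non-decreasing in k.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    prep = _prepare(counts)
    fits: dict[int, SegmentedFit] = {}
    seed: tuple[int, ...] | None = None
    for k in range(k_max + 1):
        if len(prep.times) < (k + 1) * min_pts:
            break
        fit = fit_segmented(counts, k, min_pts=min_pts, coarse_budget=coarse_budget,
                            _seed_idx=seed, _prep=prep)
        fits[k] = fit
        seed = tuple(
            int(np.searchsorted(prep.times, b[1])) for b in fit.breakpoints
        )
    scores = {k: (f.loglik, f.bic) for k, f in fits.items()}
    best = min(fits.values(), key=lambda f: f.bic)
    best.model_scores = scores
    return best


def instantaneous_S(
    p_before: float,
    p_after: float,
    n_before: int | None = None,
    n_after: int | None = None,
    dt: float = 1.0,
) -> InstantEstimate:
    """Instantaneous effective selection coefficient from a before/after pair.

    S_t = (p_after - p_before) / (p_before * (1 - p_before)) / dt, the
    denominator using the pre-shift frequency.  ``dt`` (generations
    between the two estimates) defaults to 1; pass the actual gap to put
    the estimate on a per-generation scale.  The standard error is the
    binomial delta-method value given the two allele sample sizes.
    """
    if not (0.0 < p_before < 1.0):
        return InstantEstimate(S_t=float("nan"), se=float("nan"), estimable=False)
    denom = p_before * (1.0 - p_before)
    S = (p_after - p_before) / denom / dt
    se = float("nan")
    if n_before is not None and n_after is not None:
        d_after = 1.0 / denom
        d_before = (-denom - (p_after - p_before) * (1.0 - 2.0 * p_before)) / denom**2
        var = (
            d_after**2 * p_after * (1.0 - p_after) / n_after
            + d_before**2 * p_before * (1.0 - p_before) / n_before
        ) / dt**2
        se = math.sqrt(max(var, 0.0))
    return InstantEstimate(S_t=float(S), se=se)


def fit_with_environment(
    counts: pd.DataFrame,
    k: int,
    env_col: str = "env",
    min_pts: int = 3,
    coarse_budget: int = 1500,
) -> SegmentedFit:
    """Segmented fit with an environment-by-time interaction.

    The per-generation logit slope is modeled as S(t) = f'(t) + gamma *
    env(t): the design gains a cumulative-exposure column E(t) =
    sum_{u<t} env(u) * du, whose coefficient gamma is the per-unit-env
    change in the effective selection coefficient.  A constant
    environment is degenerate (exposure proportional to time): the fit
    falls back to the plain segmented model with a zero interaction and
    ``env_flag='constant'``.  An environment that is itself linear in
    time confounds the baseline time trend with the env effect and is
    flagged ``'collinear'`` without estimating the interaction.
    """
    prep = _prepare(counts, env_col=env_col)
    times = prep.times
    env_t = prep.env_t

    def _plain(flag):
        fit = fit_segmented(counts, k, min_pts=min_pts, coarse_budget=coarse_budget)
        fit.env_interaction = (0.0, 0.0) if flag == "constant" else None
        fit.env_flag = flag
        return fit

    if np.allclose(env_t, env_t[0]):
        return _plain("constant")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(env_t, times)[0, 1]
    if abs(corr) > 0.9999:
        return _plain("collinear")

    exposure_t = np.concatenate([[0.0], np.cumsum(env_t[:-1] * np.diff(times))])

    n_alleles = float(prep.M.sum())
    if k == 0:
        Xt = _design(times, (), exposure_t)
        ll, alpha, beta, cov, conv = _newton(prep.Y, prep.M, Xt)
        intervals = []
    else:
        ll, bp_idx, intervals, alpha, beta, cov, conv = _search_breakpoints(
            prep, k, min_pts, coarse_budget, None, extra=exposure_t
        )
    seg = _segment_stats(beta[:-1], cov[:-1, :-1], k + 1)
    gamma = float(beta[-1])
    gamma_se = float(math.sqrt(max(cov[-1, -1], 0.0)))
    return SegmentedFit(
        n_breakpoints=k, breakpoints=intervals, S_per_segment=seg,
        loglik=ll, bic=_bic(ll, k, prep.J, n_alleles, extra_params=1),
        converged=conv, n_loci=prep.J, n_obs=prep.n_obs, n_alleles=n_alleles,
        flagged_loci=prep.flagged_loci,
        env_interaction=(gamma, gamma_se), env_flag=None,
    )


def s_hat_from_fit(
    fit: SegmentedFit,
    h: float,
    counts: pd.DataFrame | None = None,
    p_ref: float | list | None = None,
) -> np.ndarray:
    """Invert per-segment effective selection coefficients to true s.

    Applies :func:`fluctsel.popgen.s_from_S` segment-wise at a reference
    frequency: either supplied explicitly (scalar or one value per
    segment) or, given the counts table, the allele-weighted mean
    observed frequency within each segment.  With h = 0.5 the inversion
    gives s approximately equal to 2 S.
    """
    n_seg = fit.n_breakpoints + 1
    if p_ref is None:
        if counts is None:
            raise ValueError("provide either p_ref or the counts table")
        edges = [-np.inf] + fit.breakpoint_estimates + [np.inf]
        refs = []
        t = counts["time"].to_numpy(dtype=float)
        y = counts["derived_count"].to_numpy(dtype=float)
        m = counts["alleles_sampled"].to_numpy(dtype=float)
        for i in range(n_seg):
            sel = (t > edges[i]) & (t <= edges[i + 1]) if i else (t <= edges[1])
            if m[sel].sum() == 0:
                refs.append(0.5)
            else:
                refs.append(float(np.clip(y[sel].sum() / m[sel].sum(), 1e-6, 1 - 1e-6)))
    elif np.isscalar(p_ref):
        refs = [float(p_ref)] * n_seg
    else:
        refs = [float(v) for v in p_ref]
        if len(refs) != n_seg:
            raise ValueError("p_ref must give one reference frequency per segment")
    return np.array([
        popgen.s_from_S(S, h, p) for (S, _), p in zip(fit.S_per_segment, refs)
    ])


# ---------------------------------------------------------------------------
# VCF front-end
# ---------------------------------------------------------------------------


def counts_from_vcf(
    vcf_path: str,
    dates: pd.DataFrame,
    ancestral: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build a counts table from a VCF plus a sample collection-dates table.

    ``dates`` needs columns ``sample`` and ``time``; samples sharing a
    time value form one time bin.  Only biallelic SNPs are used.  The
    derived allele defaults to ALT; an ``ancestral`` mapping of locus id
    ("chrom:pos") to the ancestral base flips the orientation where the
    ancestral allele is ALT.
    """
    from cyvcf2 import VCF

    if not {"sample", "time"}.issubset(dates.columns):
        raise ValueError("dates table needs 'sample' and 'time' columns")
    vcf = VCF(vcf_path)
    sample_time = dict(zip(dates["sample"], dates["time"]))
    missing = [s for s in vcf.samples if s not in sample_time]
    if missing:
        raise ValueError(f"no collection date for samples {missing}")
    times = np.array([sample_time[s] for s in vcf.samples])
    uniq_times = np.unique(times)
    rows = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        locus = f"{var.CHROM}:{var.POS}"
        gt = np.asarray(var.genotype.array())[:, :2]  # (n_samples, 2) alleles
        flip = False
        if ancestral is not None and locus in ancestral:
            anc = ancestral[locus].upper()
            if anc == var.ALT[0].upper():
                flip = True
            elif anc != var.REF.upper():
                continue  # ancestral state matches neither allele
        for tt in uniq_times:
            sel = times == tt
            alleles = gt[sel].ravel()
            called = alleles >= 0
            n_called = int(called.sum())
            if n_called == 0:
                continue
            alt = int((alleles[called] == 1).sum())
            derived = n_called - alt if flip else alt
            rows.append((locus, tt, n_called, derived))
    return pd.DataFrame(rows, columns=["locus_id", "time", "alleles_sampled",
                                       "derived_count"])
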