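"""Distribution of fitness effects from folded syn/nonsyn spectra.

Synonymous sites act as the neutral reference: stage 1 fits a two-epoch
size-change nuisance to the synonymous folded SFS; stage 2 fits a gamma
distribution of scaled deleterious effects (Nes) to the nonsynonymous
folded SFS, integrating fixed-effect expected spectra over a discretized
gamma.  Demography enters the selected spectra through per-bin
distortion factors (two-epoch neutral over constant-size neutral), so
the selected expectation reduces exactly to the fitted neutral shape at
Nes = 0.  Only deleterious effects are modelled.

All expected spectra are shapes (theta = 1); every likelihood carries a
free per-class total-rate scaling profiled analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy.linalg import expm
from scipy.special import gammaln, gammainc
from scipy.stats import gamma as gamma_dist

from .sfs import FoldedSFS, fold_spectrum

DEFAULT_NES_BINS = (0.0, 1.0, 10.0, 100.0, math.inf)


@dataclass
class GammaDFE:
    """Gamma distribution of Nes for new deleterious mutations."""

    shape: float
    mean_nes: float

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.mean_nes < 0:
            raise ValueError("mean_nes must be non-negative")

    @property
    def scale(self) -> float:
        return self.mean_nes / self.shape


@dataclass
class DFEFit:
    gamma: GammaDFE
    nuisance_size_ratio: float
    nuisance_change_time: float
    loglik: float
    bin_edges: tuple = DEFAULT_NES_BINS
    bin_proportions: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bin_proportions is None:
            self.bin_proportions = dfe_bin_proportions(self.gamma, self.bin_edges)
        if abs(float(np.sum(self.bin_proportions)) - 1.0) > 1e-9:
            raise ValueError("bin proportions must sum to 1")


# ---------------------------------------------------------------------------
# Neutral expectations


def _death_chain_occupancy(n: int, size_ratio: float, change_time: float):
    """E[time with k lineages], k = n..2, under a single size change.

    Backward in time the population has relative size ``size_ratio`` for
    ``change_time`` (units of 2*N_ancestral generations), then size 1.
    """
    ks = np.arange(n, 1, -1)          # n, n-1, ..., 2
    rates = ks * (ks - 1) / 2.0
    m = ks.size
    Q = np.zeros((m, m))
    for a in range(m):
        Q[a, a] = -rates[a] / size_ratio
        if a + 1 < m:
            Q[a + 1, a] = rates[a] / size_ratio
    occ = np.zeros(m)
    p0 = np.zeros(m)
    p0[0] = 1.0
    if change_time > 0:
        aug = np.zeros((2 * m, 2 * m))
        aug[:m, :m] = Q
        aug[m:, :m] = np.eye(m)
        e = expm(aug * change_time)
        p_t = e[:m, :m] @ p0
        occ += e[m:, :m] @ p0
    else:
        p_t = p0
    # epoch 2, constant size 1: a death chain visits every k below its
    # start, so occupancy of k is P(>= k lineages at the change) / rate_k
    alive_geq = np.cumsum(p_t)        # P(current lineage count >= ks[a])
    occ += alive_geq / rates
    return dict(zip(ks.tolist(), occ))


def _p_subtend(n: int) -> np.ndarray:
    """P[i, k] that a lineage of the k-lineage stage subtends i leaves."""
    out = np.zeros((n, n + 1))
    for k in range(2, n + 1):
        for i in range(1, n - k + 2):
            out[i, k] = math.exp(
                gammaln(n - i) - gammaln(k - 1) - gammaln(n - i - k + 2)
                - (gammaln(n) - gammaln(k) - gammaln(n - k + 1)))
    return out


def _neutral_two_epoch_unfolded(n: int, size_ratio: float,
                                change_time: float) -> np.ndarray:
    """Unfolded expected SFS (theta = 1; 1/i at constant size)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if size_ratio <= 0 or change_time < 0:
        raise ValueError("nuisance parameters must be positive")
    occ = _death_chain_occupancy(n, size_ratio, change_time)
    psub = _p_subtend(n)
    xi = np.zeros(n + 1)
    for i in range(1, n):
        xi[i] = 0.5 * sum(k * occ[k] * psub[i, k] for k in range(2, n + 1))
    return xi


def expected_sfs_neutral_two_epoch(n: int, size_ratio: float,
                                   change_time: float) -> FoldedSFS:
    """Expected folded SFS (theta = 1) under a single size change.

    Reduces to the folded 1/i spectrum when ``size_ratio`` is 1.
    """
    xi = _neutral_two_epoch_unfolded(n, size_ratio, change_time)
    return FoldedSFS(n=n, counts=fold_spectrum(xi))


# ---------------------------------------------------------------------------
# Selected expectations


def _sojourn_density(x, nes: float):
    """Relative sojourn density for genic selection *against* the mutant
    (deleterious), normalized to the neutral 1/x at nes -> 0:

        g(x) = (exp(2*nes*(1-x)) - 1) / ((exp(2*nes) - 1) * x * (1-x))

    evaluated in log space so strong selection does not overflow.
    """
    x = np.asarray(x, dtype=float)
    if nes < 1e-9:
        return 1.0 / x
    s2 = 2.0 * nes
    with np.errstate(divide="ignore"):
        log_num = s2 * (1.0 - x) + np.log(-np.expm1(-s2 * (1.0 - x)))
    log_den = s2 + math.log(-math.expm1(-s2))
    return np.exp(log_num - log_den) / (x * (1.0 - x))


@lru_cache(maxsize=4096)
def _selected_unfolded_bin(n: int, i: int, nes: float) -> float:
    log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    c = math.exp(log_c)

    def f(x):
        return c * x ** i * (1.0 - x) ** (n - i) * _sojourn_density(x, nes)

    # strong selection concentrates mass near x ~ 1/(2*nes)
    pts = None
    if nes > 50.0:
        pts = [min(0.5, 5.0 / (2.0 * nes)), min(0.9, 50.0 / (2.0 * nes))]
    val, _ = integrate.quad(f, 0.0, 1.0, limit=200, epsabs=1e-12,
                            epsrel=1e-9, points=pts)
    return float(val)


def expected_sfs_selected(n: int, nes: float, size_ratio: float = 1.0,
                          change_time: float = 0.0) -> FoldedSFS:
    """Expected folded SFS (theta = 1) at a fixed selection strength Nes.

    The constant-size diffusion sojourn integral is binomially sampled
    to n chromosomes; the two-epoch nuisance is applied as per-bin
    neutral distortion factors, so nes = 0 returns exactly the two-epoch
    neutral expectation.
    """
    if nes < 0:
        raise ValueError("nes must be non-negative")
    xi = np.zeros(n + 1)
    for i in range(1, n):
        xi[i] = _selected_unfolded_bin(n, i, float(nes))
    if not np.all(np.isfinite(xi)):
        raise RuntimeError(f"sojourn integration failed (n={n}, nes={nes})")
    if size_ratio != 1.0 or change_time != 0.0:
        neutral_2e = _neutral_two_epoch_unfolded(n, size_ratio, change_time)
        i = np.arange(1, n)
        xi[1:n] *= neutral_2e[1:n] * i  # distortion relative to the 1/i shape
    return FoldedSFS(n=n, counts=fold_spectrum(xi))


# ---------------------------------------------------------------------------
# Gamma mixture and fitting


def _nes_grid(n_points: int = 64, lo: float = 1e-4, hi: float = 1e5):
    return np.geomspace(lo, hi, n_points)


def _gamma_weights(gamma: GammaDFE, grid: np.ndarray) -> np.ndarray:
    """Trapezoid mass of the gamma density on the log-spaced grid; tail
    mass outside the grid is folded onto the end points."""
    dist = gamma_dist(a=gamma.shape, scale=gamma.scale)
    logg = np.log(grid)
    dens = dist.pdf(grid) * grid        # density in log space
    w = np.zeros_like(grid)
    dlog = np.diff(logg)
    w[:-1] += 0.5 * dens[:-1] * dlog
    w[1:] += 0.5 * dens[1:] * dlog
    w[0] += dist.cdf(grid[0])
    w[-1] += dist.sf(grid[-1])
    total = w.sum()
    return w / total if total > 0 else w


def _poisson_ll_profiled(obs: np.ndarray, shape: np.ndarray) -> float:
    """Poisson log-likelihood with the total rate profiled analytically."""
    use = shape > 0
    if np.any(obs[~use] > 0):
        return -np.inf
    o, s = obs[use], shape[use]
    scale = o.sum() / s.sum()
    if scale <= 0:
        return -np.inf
    lam = scale * s
    return float(np.sum(o * np.log(lam) - lam - gammaln(o + 1.0)))


def fit_two_epoch_nuisance(syn_sfs: FoldedSFS, n_starts: int = 8,
                           seed: int = 0):
    """Maximum-likelihood two-epoch nuisance from the synonymous SFS.

    Returns (size_ratio, change_time, loglik).
    """
    from scipy.optimize import minimize

    obs = syn_sfs.counts[1:]
    n = syn_sfs.n

    def nll(x):
        ratio, tau = math.exp(x[0]), math.exp(x[1])
        if not (1e-3 <= ratio <= 1e3 and 1e-4 <= tau <= 10.0):
            return 1e9
        exp = expected_sfs_neutral_two_epoch(n, ratio, tau)
        return -_poisson_ll_profiled(obs, exp.counts[1:])

    rng = np.random.default_rng(seed)
    best = None
    starts = [(0.0, math.log(0.1))] + [
        (rng.uniform(math.log(1e-2), math.log(1e2)),
         rng.uniform(math.log(1e-3), math.log(2.0))) for _ in range(n_starts - 1)]
    for s in starts:
        res = minimize(nll, np.asarray(s), method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    ratio, tau = math.exp(best.x[0]), math.exp(best.x[1])
    return ratio, tau, -float(best.fun)


def _selected_basis(n: int, size_ratio: float, change_time: float,
                    grid: np.ndarray) -> np.ndarray:
    """Folded selected spectra (rows: grid Nes values; theta = 1)."""
    return np.vstack([
        expected_sfs_selected(n, float(g), size_ratio, change_time).counts
        for g in grid])


def fit_dfe(syn_sfs: FoldedSFS, nonsyn_sfs: FoldedSFS,
            n_grid: int = 64, n_starts: int = 12, seed: int = 0,
            bin_edges: tuple = DEFAULT_NES_BINS,
            share_theta: bool | None = None) -> DFEFit:
    """Two-stage gamma-DFE fit with synonymous sites as neutral reference.

    When both spectra carry surveyed lengths (``L``), the per-site
    mutation rate estimated from the synonymous class also scales the
    nonsynonymous expectation (``share_theta``); the overall depletion
    of nonsynonymous polymorphism then identifies the mean selection
    strength.  Without lengths the nonsynonymous total rate is profiled
    freely, which leaves the gamma mean poorly identified from folded
    spectra at small n.
    """
    from scipy.optimize import minimize

    if syn_sfs.n != nonsyn_sfs.n:
        raise ValueError("spectra must share the sample size n")
    if syn_sfs.segregating_sites <= 0 or nonsyn_sfs.segregating_sites <= 0:
        raise ValueError("both spectra must be non-empty")
    if share_theta is None:
        share_theta = syn_sfs.L is not None and nonsyn_sfs.L is not None
    if share_theta and (syn_sfs.L is None or nonsyn_sfs.L is None):
        raise ValueError("share_theta requires surveyed lengths on both spectra")
    n = syn_sfs.n
    ratio, tau, ll_syn = fit_two_epoch_nuisance(syn_sfs, seed=seed)
    grid = _nes_grid(n_grid)
    basis = _selected_basis(n, ratio, tau, grid)
    obs = nonsyn_sfs.counts[1:]

    theta_site = None
    if share_theta:
        neutral_shape = expected_sfs_neutral_two_epoch(n, ratio, tau).counts[1:]
        theta_site = (syn_sfs.counts[1:].sum() / neutral_shape.sum()) / syn_sfs.L

    def nll(x):
        shape, mean = math.exp(x[0]), math.exp(x[1])
        if not (1e-2 <= shape <= 20.0 and 1e-4 <= mean <= 1e5):
            return 1e9
        w = _gamma_weights(GammaDFE(shape, mean), grid)
        expected = (w @ basis)[1:]
        if share_theta:
            lam = theta_site * nonsyn_sfs.L * expected
            keep = lam > 0
            if np.any(obs[~keep] > 0):
                return 1e9
            return -float(np.sum(obs[keep] * np.log(lam[keep]) - lam[keep]
                                 - gammaln(obs[keep] + 1.0)))
        return -_poisson_ll_profiled(obs, expected)

    # coarse grid scan, then Nelder-Mead refinements from the best corners
    shape_grid = np.log(np.geomspace(0.03, 5.0, 16))
    mean_grid = np.log(np.geomspace(0.05, 5e4, 20))
    scan = [(nll((a, b)), a, b) for a in shape_grid for b in mean_grid]
    scan.sort(key=lambda t: t[0])
    rng = np.random.default_rng(seed)
    starts = [np.asarray([a, b]) for _, a, b in scan[:max(3, n_starts // 3)]]
    starts += [starts[0] + rng.uniform(-1.0, 1.0, size=2)
               for _ in range(n_starts - len(starts))]
    best = None
    for s in starts:
        res = minimize(nll, s, method="Nelder-Mead",
                       options={"maxiter": 500, "xatol": 1e-5, "fatol": 1e-8,
                                "adaptive": True})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e9:
        raise RuntimeError("DFE fit failed to converge within the start budget")
    g = GammaDFE(shape=math.exp(best.x[0]), mean_nes=math.exp(best.x[1]))
    return DFEFit(gamma=g, nuisance_size_ratio=ratio, nuisance_change_time=tau,
                  loglik=ll_syn - float(best.fun), bin_edges=bin_edges)


def dfe_bin_proportions(gamma: GammaDFE, bins=DEFAULT_NES_BINS) -> np.ndarray:
    """Gamma probability mass in each Nes bin (bins must tile [0, inf))."""
    edges = np.asarray(bins, dtype=float)
    if edges[0] != 0.0 or not math.isinf(edges[-1]) or \
            np.any(np.diff(edges) <= 0):
        raise ValueError("bins must increase from 0 to infinity")
    if gamma.mean_nes == 0:
        out = np.zeros(edges.size - 1)
        out[0] = 1.0
        return out
    a, scale = gamma.shape, gamma.scale
    cdf = np.array([gammainc(a, e / scale) if math.isfinite(e) else 1.0
                    for e in edges])
    return np.diff(cdf)
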