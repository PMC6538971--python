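"""Two-population demographic inference from the folded joint SFS.

Model family: an ancestral population (size N_anc, the reference) splits
at scaled time Ts into daughters of relative size nu1 and nu2.  The
daughters either never exchange migrants (SI), exchange them throughout
(IM), only until T_change before the present (AM, "ancient migration"),
or only since T_change (SC, "secondary contact").

The expected-SFS engine is deterministic and exact up to linear-algebra
tolerance: it tracks the structured-coalescent ancestral process on the
full space of lineage configurations (which sampled chromosomes each
ancestral lineage subtends, and in which population it currently sits)
and accumulates, by uniformization within each epoch, the expected time
each (i, j)-descendant class exists.  theta/2 times that occupancy is
the expected unfolded joint SFS entry, which is then folded with the
same convention used for observed spectra.

Scaled units match the simulator: time in 2*N_anc generations, pair
coalescence rate 1/nu_d, per-lineage backward migration rates m12/m21,
theta = 4*N_anc*mu*L.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import gammaln
from scipy.stats import chi2, poisson

from .sfs import FoldedJointSFS, fold_joint

MODEL_PARAM_NAMES = {
    "SI": ("theta", "nu1", "nu2", "Ts"),
    "IM": ("theta", "nu1", "nu2", "Ts", "m12", "m21"),
    "AM": ("theta", "nu1", "nu2", "Ts", "m12", "m21", "Ta"),
    "SC": ("theta", "nu1", "nu2", "Ts", "m12", "m21", "Tsc"),
}

#: nested pairs (null, alternative) testable by LRT
NESTED_PAIRS = (("SI", "IM"), ("IM", "AM"), ("IM", "SC"))

DEFAULT_BOUNDS = {"nu": (1e-3, 1e3), "T": (1e-4, 10.0), "m": (1e-4, 50.0)}


class EnginePrecisionError(RuntimeError):
    """The uniformization budget was exceeded for the requested parameters."""


@dataclass
class DemographicModelSpec:
    """One of the SI / IM / AM / SC model shapes."""

    kind: str

    def __post_init__(self):
        if self.kind not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.kind]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def nested_within(self, other: "DemographicModelSpec") -> bool:
        return (self.kind, other.kind) in NESTED_PAIRS or \
            (self.kind == "SI" and other.kind in ("AM", "SC"))


@dataclass
class FitResult:
    kind: str
    params: dict[str, float]
    loglik: float
    aic: float
    replicate_index: int
    converged: bool
    n_replicates: int
    observed_total: float
    replicates: pd.DataFrame | None = None

    def __post_init__(self):
        k = len(MODEL_PARAM_NAMES[self.kind])
        expected_aic = 2.0 * k - 2.0 * self.loglik
        if not math.isclose(self.aic, expected_aic, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("AIC inconsistent with loglik and parameter count")


@dataclass
class PhysicalParams:
    N_anc: float
    N1: float
    N2: float
    T_split_years: float
    T_change_years: float | None
    migrants_per_gen_into_1: float | None
    migrants_per_gen_into_2: float | None
    mu: float
    L: float
    g: float


# ---------------------------------------------------------------------------
# Lineage-configuration state space


class _StateSpace:
    """Reachable configurations for n1 + n2 sampled chromosomes.

    A lineage is typed by (i, j, deme) — the numbers of population-1 and
    population-2 chromosomes it subtends and its current location; a
    state is the multiset of lineage types.  Rate matrices are stored as
    generators acting on column probability vectors (entry [dst, src])
    and decompose as Q = C1/nu1 + C2/nu2 + m12*M12 + m21*M21.
    """

    def __init__(self, n1: int, n2: int):
        self.n1, self.n2 = n1, n2
        init = tuple(sorted([(1, 0, 0)] * n1 + [(0, 1, 1)] * n2))
        index = {init: 0}
        order = [init]
        stack = [init]
        coal = {0: [], 1: []}
        while stack:
            s = stack.pop()
            si = index[s]
            lin = list(s)
            k = len(lin)
            for a in range(k):
                for b in range(a + 1, k):
                    if lin[a][2] == lin[b][2]:
                        merged = (lin[a][0] + lin[b][0], lin[a][1] + lin[b][1],
                                  lin[a][2])
                        ns = tuple(sorted(lin[:a] + lin[a + 1:b] + lin[b + 1:]
                                          + [merged]))
                        if ns not in index:
                            index[ns] = len(order)
                            order.append(ns)
                            stack.append(ns)
                        coal[lin[a][2]].append((si, index[ns]))
            for a in range(k):
                i, j, d = lin[a]
                ns = tuple(sorted(lin[:a] + lin[a + 1:] + [(i, j, 1 - d)]))
                if ns not in index:
                    index[ns] = len(order)
                    order.append(ns)
                    stack.append(ns)
        mig = {0: [], 1: []}
        for s, si in index.items():
            lin = list(s)
            for a in range(len(lin)):
                i, j, d = lin[a]
                ns = tuple(sorted(lin[:a] + lin[a + 1:] + [(i, j, 1 - d)]))
                mig[d].append((si, index[ns]))
        S = len(order)

        def mat(pairs):
            c = Counter(pairs)
            rows, cols, vals = [], [], []
            for (src, dst), m in c.items():
                rows += [dst, src]
                cols += [src, src]
                vals += [float(m), -float(m)]
            return sp.csr_matrix((vals, (rows, cols)), shape=(S, S))

        self.states = order
        self.index = index
        self.size = S
        self.C1 = mat(coal[0])
        self.C2 = mat(coal[1])
        self.M12 = mat(mig[0])
        self.M21 = mat(mig[1])
        self.p0 = np.zeros(S)
        self.p0[index[init]] = 1.0

        # reward matrix: lineage-type counts per state (root class excluded)
        full = (n1, n2)
        grid = (n1 + 1) * (n2 + 1)
        rows, cols, vals = [], [], []
        for si, s in enumerate(order):
            for (i, j, _d), m in Counter(s).items():
                if (i, j) == full:
                    continue
                rows.append(si)
                cols.append(i * (n2 + 1) + j)
                vals.append(float(m))
        self.R = sp.csr_matrix((vals, (rows, cols)), shape=(S, grid))

        # single-deme ancestral chain: collapse deme labels
        anc_index: dict[tuple, int] = {}
        anc_order: list[tuple] = []

        def anc_id(state):
            key = tuple(sorted((i, j, 0) for i, j, _ in state))
            if key not in anc_index:
                anc_index[key] = len(anc_order)
                anc_order.append(key)
            return anc_index[key]

        collapse = np.empty(S, dtype=np.int64)
        for si, s in enumerate(order):
            collapse[si] = anc_id(s)
        # enumerate coalescences within the collapsed chain
        anc_coal = []
        pending = list(anc_order)
        seen = set(anc_index)
        while pending:
            s = pending.pop()
            lin = list(s)
            for a in range(len(lin)):
                for b in range(a + 1, len(lin)):
                    merged = (lin[a][0] + lin[b][0], lin[a][1] + lin[b][1], 0)
                    ns = tuple(sorted(lin[:a] + lin[a + 1:b] + lin[b + 1:]
                                      + [merged]))
                    if ns not in seen:
                        seen.add(ns)
                        anc_index[ns] = len(anc_order)
                        anc_order.append(ns)
                        pending.append(ns)
                    anc_coal.append((anc_index[s], anc_index[ns]))
        Sa = len(anc_order)
        c = Counter(anc_coal)
        rows, cols, vals = [], [], []
        for (src, dst), m in c.items():
            rows += [dst, src]
            cols += [src, src]
            vals += [float(m), -float(m)]
        Qanc = sp.csr_matrix((vals, (rows, cols)), shape=(Sa, Sa))
        absorbing = anc_index[((n1, n2, 0),)]
        transient = np.array([i for i in range(Sa) if i != absorbing])
        self.anc_order = anc_order
        self.anc_collapse = collapse
        self.anc_transient = transient
        self._anc_lu = splu(sp.csc_matrix(-Qanc[np.ix_(transient, transient)]))
        rows, cols, vals = [], [], []
        for si, s in enumerate(anc_order):
            for (i, j, _d), m in Counter(s).items():
                if (i, j) == full:
                    continue
                rows.append(si)
                cols.append(i * (n2 + 1) + j)
                vals.append(float(m))
        self.R_anc = sp.csr_matrix((vals, (rows, cols)), shape=(Sa, grid))

    def ancestral_occupancy(self, p: np.ndarray) -> np.ndarray:
        """Expected transient occupancy of the collapsed single-deme chain
        started from the collapsed distribution of ``p``."""
        Sa = len(self.anc_order)
        p_anc = np.zeros(Sa)
        np.add.at(p_anc, self.anc_collapse, p)
        u = np.zeros(Sa)
        u[self.anc_transient] = self._anc_lu.solve(p_anc[self.anc_transient])
        return u


@lru_cache(maxsize=8)
def _state_space(n1: int, n2: int) -> _StateSpace:
    return _StateSpace(n1, n2)


def _uniformized_occupancy(Q: sp.csr_matrix, p0: np.ndarray, T: float,
                           max_terms: int = 60_000):
    """(p(T), integral of p over [0, T]) for dp/dt = Q p, by uniformization."""
    if T <= 0:
        return p0.copy(), np.zeros_like(p0)
    lam = float(-Q.diagonal().min())
    if lam <= 0:
        return p0.copy(), T * p0
    lt = lam * T
    K = int(lt + 12.0 * math.sqrt(lt) + 30.0)
    if K > max_terms:
        raise EnginePrecisionError(
            f"uniformization needs {K} terms (budget {max_terms}); "
            "parameters too extreme for the requested precision")
    ks = np.arange(K + 1)
    pmf = poisson.pmf(ks, lt)
    sf_w = poisson.sf(ks, lt) / lam
    P = sp.identity(Q.shape[0], format="csr") + Q * (1.0 / lam)
    pk = p0.copy()
    pT = np.zeros_like(p0)
    occ = np.zeros_like(p0)
    for k in range(K + 1):
        if pmf[k] > 0.0:
            pT += pmf[k] * pk
        occ += sf_w[k] * pk
        if sf_w[k] < 1e-16 and pmf[k] < 1e-16 and k > lt:
            break
        pk = P @ pk
    return pT, occ


def _model_epochs(kind: str, params: dict[str, float]):
    """Backward-time epochs (duration, nu1, nu2, m12, m21) before the merge."""
    nu1, nu2, Ts = params["nu1"], params["nu2"], params["Ts"]
    if kind == "SI":
        return [(Ts, nu1, nu2, 0.0, 0.0)]
    m12, m21 = params["m12"], params["m21"]
    if kind == "IM":
        return [(Ts, nu1, nu2, m12, m21)]
    if kind == "AM":
        Ta = params["Ta"]
        if not 0.0 <= Ta <= Ts:
            raise ValueError("AM requires 0 <= Ta <= Ts")
        return [(Ta, nu1, nu2, 0.0, 0.0), (Ts - Ta, nu1, nu2, m12, m21)]
    if kind == "SC":
        Tsc = params["Tsc"]
        if not 0.0 <= Tsc <= Ts:
            raise ValueError("SC requires 0 <= Tsc <= Ts")
        return [(Tsc, nu1, nu2, m12, m21), (Ts - Tsc, nu1, nu2, 0.0, 0.0)]
    raise ValueError(kind)


def expected_joint_sfs(spec: DemographicModelSpec, params: dict[str, float],
                       n1_eff: int = 4, n2_eff: int = 4,
                       fold: bool = True):
    """Expected (real-valued) joint SFS under the model.

    ``params`` holds the scaled parameters by name; ``theta`` (default 1)
    scales the output linearly.  Folding uses the same combined-minor
    convention as observed spectra, so the two are commensurable.
    """
    if n1_eff < 2 or n2_eff < 2:
        raise ValueError("need n_eff >= 2 per population")
    theta = float(params.get("theta", 1.0))
    for name in ("nu1", "nu2"):
        if params[name] <= 0:
            raise ValueError(f"{name} must be positive")
    if params["Ts"] < 0:
        raise ValueError("Ts must be non-negative")
    ss = _state_space(n1_eff, n2_eff)
    p = ss.p0
    reward = np.zeros((n1_eff + 1) * (n2_eff + 1))
    for duration, nu1, nu2, m12, m21 in _model_epochs(spec.kind, params):
        if duration <= 0:
            continue
        Q = (ss.C1 * (1.0 / nu1) + ss.C2 * (1.0 / nu2)
             + ss.M12 * m12 + ss.M21 * m21).tocsr()
        p, occ = _uniformized_occupancy(Q, p, duration)
        reward += ss.R.T @ occ
    reward += ss.R_anc.T @ ss.ancestral_occupancy(p)
    xi = 0.5 * theta * reward.reshape(n1_eff + 1, n2_eff + 1)
    if not np.all(np.isfinite(xi)):
        raise EnginePrecisionError("non-finite expected SFS")
    if not fold:
        return xi
    out = fold_joint(xi)
    return out


def composite_loglik(observed: FoldedJointSFS, expected: FoldedJointSFS,
                     floor: float | None = None):
    """Poisson composite log-likelihood with the analytically optimal
    theta scaling (ratio of observed to expected totals).

    Returns (loglik, theta_hat).  An expected cell of zero under positive
    observation raises unless ``floor`` supplies a documented floor value
    substituted for zero expectations.
    """
    if observed.data.shape != expected.data.shape:
        raise ValueError("spectrum shapes differ")
    if np.any(observed.mask != expected.mask):
        raise ValueError("spectrum masks differ")
    use = ~observed.mask
    obs = observed.data[use]
    exp = expected.data[use].copy()
    zero_bad = (exp <= 0) & (obs > 0)
    if zero_bad.any():
        if floor is None:
            raise ValueError(
                "expected cell is zero where observation is positive; "
                "pass floor= to substitute a small positive value")
        exp[exp <= 0] = floor
    total_exp = exp.sum()
    if total_exp <= 0:
        raise ValueError("expected spectrum sums to zero")
    theta_hat = obs.sum() / total_exp
    lam = theta_hat * exp
    keep = lam > 0
    ll = float(np.sum(obs[keep] * np.log(lam[keep]) - lam[keep]
                      - gammaln(obs[keep] + 1.0)) - lam[~keep].sum())
    return ll, theta_hat


# ---------------------------------------------------------------------------
# Fitting


def _opt_names(kind: str) -> list[str]:
    # theta is profiled analytically; AM/SC epoch times are optimized as a
    # fraction of Ts so the constraint 0 <= T_change <= Ts always holds
    base = ["nu1", "nu2", "Ts"]
    if kind in ("IM", "AM", "SC"):
        base += ["m12", "m21"]
    if kind in ("AM", "SC"):
        base += ["tfrac"]
    return base


def _opt_bounds(kind: str, bounds: dict) -> list[tuple[float, float]]:
    out = []
    for name in _opt_names(kind):
        if name.startswith("nu"):
            out.append(bounds["nu"])
        elif name == "Ts":
            out.append(bounds["T"])
        elif name.startswith("m"):
            out.append(bounds["m"])
        else:  # tfrac
            out.append((1e-3, 1.0 - 1e-3))
    return out


def _decode(kind: str, x: np.ndarray) -> dict[str, float]:
    names = _opt_names(kind)
    vals = dict(zip(names, np.exp(x)))
    params = {"nu1": vals["nu1"], "nu2": vals["nu2"], "Ts": vals["Ts"]}
    if "m12" in vals:
        params["m12"] = vals["m12"]
        params["m21"] = vals["m21"]
    if kind == "AM":
        params["Ta"] = vals["tfrac"] * vals["Ts"]
    elif kind == "SC":
        params["Tsc"] = vals["tfrac"] * vals["Ts"]
    return params


def fit_model(observed: FoldedJointSFS, spec: DemographicModelSpec,
              n_replicates: int = 50, seed: int | None = None,
              bounds: dict | None = None, grid_size: int = 128,
              maxiter: int = 300, keep_replicates: bool = True) -> FitResult:
    """Multi-start composite-likelihood fit of one model.

    A coarse random search over the (log-scale) parameter box picks a
    starting point; each replicate perturbs it multiplicatively (factor
    up to 4) and runs a bounded Nelder-Mead refinement.  Deterministic
    given ``seed``.
    """
    from scipy.optimize import minimize

    if observed.total <= 0:
        raise ValueError("observed spectrum is empty")
    bounds = bounds or DEFAULT_BOUNDS
    rng = np.random.default_rng(seed)
    kind = spec.kind
    box = np.log(np.asarray(_opt_bounds(kind, bounds)))
    ndim = box.shape[0]

    def objective(x: np.ndarray) -> float:
        if np.any(x < box[:, 0] - 1e-12) or np.any(x > box[:, 1] + 1e-12):
            return 1e12 + float(np.sum(np.maximum(box[:, 0] - x, 0)
                                       + np.maximum(x - box[:, 1], 0)))
        try:
            params = _decode(kind, x)
            exp = expected_joint_sfs(spec, params, observed.n1, observed.n2)
            ll, _ = composite_loglik(observed, exp, floor=1e-12)
        except EnginePrecisionError:
            return 1e11
        if not np.isfinite(ll):
            return 1e11
        return -ll

    # coarse random search (log-uniform over a moderate interior box)
    interior = box.copy()
    interior[:, 0] = np.maximum(interior[:, 0], np.log(1e-2))
    interior[:, 1] = np.minimum(interior[:, 1], np.log(20.0))
    grid = rng.uniform(interior[:, 0], interior[:, 1], size=(grid_size, ndim))
    grid_vals = np.array([objective(x) for x in grid])
    # perturb replicate starts around the best few grid points, not just the
    # single best, so distinct likelihood modes all get local refinements
    order = np.argsort(grid_vals)
    centers = grid[order[:max(1, min(5, grid_size // 8))]]

    best = None
    rows = []
    log4 = math.log(4.0)
    for rep in range(n_replicates):
        start = centers[rep % len(centers)] + rng.uniform(-log4, log4, size=ndim)
        start = np.clip(start, box[:, 0], box[:, 1])
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4,
                                "fatol": 1e-6, "adaptive": True})
        rows.append({"replicate": rep, "loglik": -res.fun,
                     "converged": bool(res.success),
                     **{f"log_{n}": v for n, v in
                        zip(_opt_names(kind), res.x)}})
        if best is None or res.fun < best[1]:
            best = (res.x, res.fun, rep, bool(res.success))
    if best is None or best[1] >= 1e10:
        raise RuntimeError("no replicate converged to a finite likelihood; "
                           f"best objective {best[1] if best else 'n/a'}")
    x_hat, nll, rep_idx, conv = best
    params = _decode(kind, x_hat)
    exp = expected_joint_sfs(spec, params, observed.n1, observed.n2)
    ll, theta_hat = composite_loglik(observed, exp, floor=1e-12)
    params["theta"] = theta_hat
    k = spec.n_params
    return FitResult(kind=kind, params=params, loglik=ll, aic=2.0 * k - 2.0 * ll,
                     replicate_index=rep_idx, converged=conv,
                     n_replicates=n_replicates, observed_total=observed.total,
                     replicates=pd.DataFrame(rows) if keep_replicates else None)


@dataclass
class ModelComparison:
    ranking: pd.DataFrame
    lrt: pd.DataFrame
    best_by_aic: str
    am_vs_sc: str | None = None


def compare_models(fits: dict[str, FitResult] | list[FitResult]) -> ModelComparison:
    """Rank fitted models; LRT for nested pairs, AIC for non-nested.

    AM and SC are non-nested in each other and compared by AIC only.
    """
    if isinstance(fits, list):
        fits = {f.kind: f for f in fits}
    totals = {f.observed_total for f in fits.values()}
    if len(totals) > 1:
        raise ValueError("fits must be on identical observed data")
    rows = [{"kind": f.kind, "k": len(MODEL_PARAM_NAMES[f.kind]),
             "loglik": f.loglik, "aic": f.aic} for f in fits.values()]
    ranking = (pd.DataFrame(rows)
               .sort_values(["loglik"], ascending=False)
               .reset_index(drop=True))
    ranking["delta_aic"] = ranking["aic"] - ranking["aic"].min()
    lrt_rows = []
    for null, alt in NESTED_PAIRS:
        if null in fits and alt in fits:
            df = (len(MODEL_PARAM_NAMES[alt]) - len(MODEL_PARAM_NAMES[null]))
            stat = 2.0 * (fits[alt].loglik - fits[null].loglik)
            p = float(chi2.sf(max(stat, 0.0), df))
            lrt_rows.append({"null": null, "alternative": alt,
                             "statistic": stat, "df": df, "p_value": p})
    best_by_aic = ranking.loc[ranking["aic"].idxmin(), "kind"]
    am_vs_sc = None
    if "AM" in fits and "SC" in fits:
        am_vs_sc = "AM" if fits["AM"].aic <= fits["SC"].aic else "SC"
    return ModelComparison(ranking=ranking, lrt=pd.DataFrame(lrt_rows),
                           best_by_aic=str(best_by_aic), am_vs_sc=am_vs_sc)


# ---------------------------------------------------------------------------
# Unit conversion


def to_physical_units(fit: FitResult, mu: float, L: float,
                      g: float = 5.0) -> PhysicalParams:
    """Convert scaled estimates to physical units via theta = 4 N_anc mu L
    and T_years = T_scaled * 2 N_anc * g."""
    if mu <= 0 or L <= 0 or g <= 0:
        raise ValueError("mu, L and g must be positive")
    theta = fit.params.get("theta", 0.0)
    if theta <= 0:
        raise ValueError("theta estimate must be positive")
    N_anc = theta / (4.0 * mu * L)
    p = fit.params
    t_change = p.get("Ta", p.get("Tsc"))
    m12 = p.get("m12")
    m21 = p.get("m21")
    return PhysicalParams(
        N_anc=N_anc, N1=p["nu1"] * N_anc, N2=p["nu2"] * N_anc,
        T_split_years=p["Ts"] * 2.0 * N_anc * g,
        T_change_years=None if t_change is None else t_change * 2.0 * N_anc * g,
        migrants_per_gen_into_1=None if m12 is None else 0.5 * m12 * p["nu1"],
        migrants_per_gen_into_2=None if m21 is None else 0.5 * m21 * p["nu2"],
        mu=mu, L=L, g=g,
    )


def to_scaled_units(phys: PhysicalParams) -> dict[str, float]:
    """Inverse of :func:`to_physical_units`; round-trips exactly."""
    N_anc = phys.N_anc
    out = {
        "theta": 4.0 * N_anc * phys.mu * phys.L,
        "nu1": phys.N1 / N_anc,
        "nu2": phys.N2 / N_anc,
        "Ts": phys.T_split_years / (2.0 * N_anc * phys.g),
    }
    if phys.T_change_years is not None:
        out["T_change"] = phys.T_change_years / (2.0 * N_anc * phys.g)
    if phys.migrants_per_gen_into_1 is not None:
        out["m12"] = 2.0 * phys.migrants_per_gen_into_1 / out["nu1"]
    if phys.migrants_per_gen_into_2 is not None:
        out["m21"] = 2.0 * phys.migrants_per_gen_into_2 / out["nu2"]
    return out
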