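"""Comparative layer: life-history factor projection, the propagule-size
diversity regression, ancestral-diversity rescaling, and the
divergence-based mutation-rate derivation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

LIFE_HISTORY_COLUMNS = (
    "species", "adult_mass_g", "neonatal_mass_g", "litter_size",
    "gestation_d", "interbirth_d", "weaning_d", "maturity_d",
)

OUTPUT_VARS = ("neonatal_mass_g", "litter_size", "gestation_d")
TIMING_VARS = ("interbirth_d", "weaning_d", "maturity_d")

#: Placeholder loadings for tests and demos.  The published Eutherian
#: loadings are not bundled; users supply them via a YAML file.
PLACEHOLDER_LOADINGS = {
    "output": {"neonatal_mass_g": 0.58, "litter_size": -0.58, "gestation_d": 0.58},
    "timing": {"interbirth_d": 0.58, "weaning_d": 0.58, "maturity_d": 0.58},
}


@dataclass
class FactorLoadings:
    """Weight vectors over the six mass-corrected life-history variables."""

    output: dict[str, float]
    timing: dict[str, float]

    def validate(self) -> None:
        if set(self.output) != set(OUTPUT_VARS):
            raise ValueError(f"output loadings must cover {OUTPUT_VARS}")
        if set(self.timing) != set(TIMING_VARS):
            raise ValueError(f"timing loadings must cover {TIMING_VARS}")
        for d in (self.output, self.timing):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("loadings must be finite")

    @classmethod
    def placeholder(cls) -> "FactorLoadings":
        return cls(output=dict(PLACEHOLDER_LOADINGS["output"]),
                   timing=dict(PLACEHOLDER_LOADINGS["timing"]))

    @classmethod
    def from_yaml(cls, path) -> "FactorLoadings":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        loadings = cls(output=dict(raw["output"]), timing=dict(raw["timing"]))
        loadings.validate()
        return loadings

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"output": self.output, "timing": self.timing}, fh)


def mass_residual_factors(records: pd.DataFrame,
                          loadings: FactorLoadings | None = None,
                          log=np.log) -> pd.DataFrame:
    """Two-factor projection of mass-corrected life-history variation.

    Every variable is log-transformed; each is regressed on log adult
    body mass by OLS; the residuals are combined by the loading vectors
    into a reproductive-output and a reproductive-timing score per
    species.  Scores are invariant to species order and to multiplying
    all masses by a constant.
    """
    loadings = loadings or FactorLoadings.placeholder()
    loadings.validate()
    missing = [c for c in LIFE_HISTORY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"life-history table lacks columns: {missing}")
    if len(records) < 3:
        raise ValueError("need at least 3 species")
    vals = records[list(LIFE_HISTORY_COLUMNS[1:])].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("life-history quantities must be positive")
    logged = log(vals)
    x = logged[:, 0]  # log adult mass
    if np.allclose(x, x[0]):
        raise ValueError("singular regression: constant body mass")
    resid = {}
    for col_idx, name in enumerate(LIFE_HISTORY_COLUMNS[2:], start=1):
        y = logged[:, col_idx]
        slope, intercept = np.polyfit(x, y, 1)
        resid[name] = y - (slope * x + intercept)
    out = np.zeros(len(records))
    tim = np.zeros(len(records))
    for var, w in loadings.output.items():
        out += w * resid[var]
    for var, w in loadings.timing.items():
        tim += w * resid[var]
    return pd.DataFrame({"species": records["species"].to_numpy(),
                         "output_factor": out, "timing_factor": tim})


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    n: int

    def predict_pi(self, propagule_cm) -> np.ndarray:
        """Prediction on the diversity scale from propagule size in cm."""
        logp = np.log10(np.asarray(propagule_cm, dtype=float))
        return 10.0 ** (self.intercept + self.slope * logp)


@dataclass
class PropaguleRegression:
    with_all: RegressionFit
    without_excluded: RegressionFit | None
    excluded: frozenset = field(default_factory=frozenset)


def propagule_diversity_regression(table: pd.DataFrame,
                                   exclude: set[str] | None = None
                                   ) -> PropaguleRegression:
    """OLS of log10 diversity on log10 propagule size, fitted both with
    every species and with ``exclude`` removed."""
    from scipy.stats import linregress

    for col in ("species", "pi_s", "propagule_cm"):
        if col not in table.columns:
            raise ValueError(f"diversity table lacks column {col}")
    if np.any(table["pi_s"] <= 0) or np.any(table["pi_s"] >= 1):
        raise ValueError("pi_s must lie in (0, 1)")
    if np.any(table["propagule_cm"] <= 0):
        raise ValueError("propagule size must be positive")

    def fit(df) -> RegressionFit:
        if len(df) < 3:
            raise ValueError("need at least 3 species after exclusion")
        x = np.log10(df["propagule_cm"].to_numpy(dtype=float))
        y = np.log10(df["pi_s"].to_numpy(dtype=float))
        if np.allclose(x, x[0]):
            raise ValueError("degenerate x-variance")
        res = linregress(x, y)
        return RegressionFit(slope=float(res.slope),
                             intercept=float(res.intercept), n=len(df))

    exclude = set(exclude or ())
    full = fit(table)
    reduced = None
    if exclude:
        reduced = fit(table[~table["species"].isin(exclude)])
    return PropaguleRegression(with_all=full, without_excluded=reduced,
                               excluded=frozenset(exclude))


def rescale_ancestral_diversity(pi_current: float, N_current: float,
                                N_ancestral: float) -> float:
    """Equilibrium rescaling pi_anc = pi_current * N_ancestral / N_current."""
    if pi_current <= 0 or N_current <= 0 or N_ancestral <= 0:
        raise ValueError("all inputs must be positive")
    return pi_current * N_ancestral / N_current


def round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def mutation_rate_from_divergence(ds: float, T_split_years: float,
                                  sig_figures: int | None = None) -> float:
    """Per-site per-year mutation rate mu = ds / (2 * T_split)."""
    if ds < 0:
        raise ValueError("ds must be non-negative")
    if T_split_years <= 0:
        raise ValueError("split time must be positive")
    mu = ds / (2.0 * T_split_years)
    if sig_figures is not None:
        mu = round_sig(mu, sig_figures)
    return mu
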