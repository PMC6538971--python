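"""Genotype- and site-level filters, replicate-based artifact-window
detection, and per-window SNP thinning.

All window grids are anchored at coordinate 1 and half-open:
window w covers 1-based positions [w*size + 1, (w+1)*size].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callset import GenotypeCallset, MISSING

logger = logging.getLogger(__name__)


@dataclass
class GenotypeFilterConfig:
    min_depth: int = 6
    balance_min: float = 0.23
    balance_max: float = 0.76
    min_gq: int = 10

    def validate(self) -> None:
        if not 0.0 <= self.balance_min < self.balance_max <= 1.0:
            raise ValueError("need 0 <= balance_min < balance_max <= 1")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")


@dataclass
class SiteFilterConfig:
    """Stage-specific site filters.

    The heterozygosity stage uses QUAL >= 20 and a coverage band relative
    to the mean; the demography stage uses QUAL >= 30 with absolute
    mean-DP bounds plus the hard annotation filters.  The rank-sum
    thresholds are exclusion boundaries: a site passes if the statistic
    lies inside the closed interval.
    """

    biallelic_only: bool = True
    min_qual_heterozygosity: float = 20.0
    min_qual_demography: float = 30.0
    min_rms_mq: float = 20.0
    cov_min_frac: float = 0.2
    cov_max_frac: float = 2.0
    dp_min: float = 10.0
    dp_max: float = 50.0
    qd_min: float = 2.0
    sor_max: float = 3.0
    mq_min: float = 50.0
    mqranksum_range: tuple[float, float] = (-2.4, 0.6)
    readposranksum_range: tuple[float, float] = (-2.2, 2.4)

    def validate(self) -> None:
        if not self.cov_min_frac < self.cov_max_frac:
            raise ValueError("cov_min_frac must be < cov_max_frac")
        for name in ("min_qual_heterozygosity", "min_qual_demography",
                     "min_rms_mq", "dp_min", "dp_max", "qd_min", "sor_max",
                     "mq_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FPWindowReport:
    window_bp: int
    fp_positions: np.ndarray
    blacklisted_windows: list[tuple[int, int]]   # 1-based inclusive intervals
    fp_discarded_fraction: float
    genome_removed_fraction: float
    window_counts: dict[int, int] = field(default_factory=dict)


def filter_genotypes(callset: GenotypeCallset,
                     config: GenotypeFilterConfig | None = None):
    """Mask genotypes failing depth / allele-balance / GQ rules.

    A genotype is retained iff DP >= min_depth, GQ >= min_gq and — for
    heterozygotes — ref/(ref+alt) within [balance_min, balance_max].
    Returns (filtered callset, per-rule masked-genotype counts).
    """
    config = config or GenotypeFilterConfig()
    config.validate()
    callset.require_format("DP", "AD", "GQ")
    out = callset.copy()
    called = out.gt != MISSING
    fail_dp = called & (out.dp < config.min_depth)
    fail_gq = called & (out.gq < config.min_gq)
    het = called & (out.gt == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        total = (out.ad_ref + out.ad_alt).astype(float)
        ratio = np.where(total > 0, out.ad_ref / np.where(total > 0, total, 1), np.nan)
    fail_balance = het & ~((ratio >= config.balance_min) & (ratio <= config.balance_max))
    fail = fail_dp | fail_gq | fail_balance
    out.gt = np.where(fail, MISSING, out.gt).astype(np.int8)
    counts = {
        "min_depth": int(fail_dp.sum()),
        "allele_balance": int(fail_balance.sum()),
        "min_gq": int(fail_gq.sum()),
        "total_masked": int(fail.sum()),
    }
    logger.info("filter_genotypes %s", counts)
    return out, counts


def filter_sites(callset: GenotypeCallset, config: SiteFilterConfig | None = None,
                 stage: str = "heterozygosity"):
    """Boolean pass mask over sites for the given stage, with per-rule
    exclusion counts.  Rules are pure per-site predicates, so order is
    irrelevant and the filter is idempotent."""
    config = config or SiteFilterConfig()
    config.validate()
    if stage not in ("heterozygosity", "demography"):
        raise ValueError("stage must be 'heterozygosity' or 'demography'")
    if callset.n_sites == 0:
        raise ValueError("cannot filter an empty callset (mean coverage undefined)")
    n = callset.n_sites
    passing = np.ones(n, dtype=bool)
    counts: dict[str, int] = {}

    def apply(name: str, ok: np.ndarray):
        nonlocal passing
        counts[name] = int((~ok).sum())
        passing &= ok

    if config.biallelic_only:
        alt = np.asarray([a if a is not None else "." for a in callset.alt])
        ok = np.array([("," not in str(a)) and str(a) not in (".", "")
                       for a in alt])
        ref_ok = np.array([len(str(r)) == 1 for r in callset.ref])
        apply("biallelic", ok & ref_ok)

    qual_thresh = (config.min_qual_heterozygosity if stage == "heterozygosity"
                   else config.min_qual_demography)
    if callset.qual is not None:
        apply("qual", np.nan_to_num(callset.qual, nan=-np.inf) >= qual_thresh)

    mean_dp_site = callset.mean_depth_per_site()
    if stage == "heterozygosity":
        overall = float(np.nanmean(mean_dp_site))
        if not np.isfinite(overall):
            raise ValueError("mean coverage undefined (no called genotypes)")
        ok = ((mean_dp_site >= config.cov_min_frac * overall)
              & (mean_dp_site <= config.cov_max_frac * overall))
        apply("coverage_band", np.nan_to_num(ok, nan=False))
    else:
        ok = (mean_dp_site >= config.dp_min) & (mean_dp_site <= config.dp_max)
        apply("mean_dp_bounds", np.nan_to_num(ok, nan=False))

    def info_ok(rule, key, pred):
        if key in callset.info:
            vals = callset.info[key]
            ok = pred(vals)
            ok[np.isnan(vals)] = True  # absent annotation does not fail a site
            apply(rule, ok)

    info_ok("rms_mq", "MQ", lambda v: v >= config.min_rms_mq)
    if stage == "demography":
        info_ok("QD", "QD", lambda v: v > config.qd_min)
        info_ok("SOR", "SOR", lambda v: v < config.sor_max)
        info_ok("MQ_hard", "MQ", lambda v: v > config.mq_min)
        lo, hi = config.mqranksum_range
        info_ok("MQRankSum", "MQRankSum", lambda v: (v >= lo) & (v <= hi))
        lo2, hi2 = config.readposranksum_range
        info_ok("ReadPosRankSum", "ReadPosRankSum",
                lambda v: (v >= lo2) & (v <= hi2))

    counts["total_excluded"] = int((~passing).sum())
    logger.info("filter_sites stage=%s %s", stage, counts)
    return passing, counts


def window_index(pos: np.ndarray, window_bp: int) -> np.ndarray:
    """Grid window index for 1-based positions (grid anchored at 1)."""
    return (np.asarray(pos, dtype=np.int64) - 1) // window_bp


def detect_fp_windows(callset_a: GenotypeCallset, callset_b: GenotypeCallset,
                      window_bp: int = 5_000, genome_bp: int | None = None):
    """Blacklist windows with clustered replicate-discordant homozygotes.

    A false-positive SNP is a position where the two replicate callsets
    of the same individual carry *different homozygous* genotypes.  Any
    window holding more than one FP-SNP is blacklisted genome-wide.
    Returns (FPWindowReport, callset_a restricted to kept windows).
    """
    if callset_a.n_sites != callset_b.n_sites or \
            np.any(callset_a.pos != callset_b.pos):
        raise ValueError("replicate callsets must share the same site set")
    ga = callset_a.gt[:, 0]
    gb = callset_b.gt[:, 0]
    hom_a = (ga == 0) | (ga == 2)
    hom_b = (gb == 0) | (gb == 2)
    is_fp = hom_a & hom_b & (ga != gb)
    fp_pos = callset_a.pos[is_fp]

    widx = window_index(callset_a.pos, window_bp)
    fp_widx = widx[is_fp]
    uniq, cnt = np.unique(fp_widx, return_counts=True)
    black = set(uniq[cnt > 1].tolist())

    if genome_bp is None:
        genome_bp = int(callset_a.pos.max()) if callset_a.n_sites else 0
    n_windows = max(1, -(-genome_bp // window_bp))
    fp_in_black = int(np.isin(fp_widx, list(black)).sum()) if black else 0
    report = FPWindowReport(
        window_bp=window_bp,
        fp_positions=fp_pos,
        blacklisted_windows=[(int(w) * window_bp + 1, (int(w) + 1) * window_bp)
                             for w in sorted(black)],
        fp_discarded_fraction=(fp_in_black / len(fp_pos)) if len(fp_pos) else 0.0,
        genome_removed_fraction=len(black) / n_windows,
        window_counts={int(w): int(c) for w, c in zip(uniq, cnt)},
    )
    keep = ~np.isin(widx, list(black)) if black else np.ones(callset_a.n_sites, bool)
    logger.info("detect_fp_windows n_fp=%d blacklisted=%d", len(fp_pos), len(black))
    return report, callset_a.take_sites(keep)


def apply_window_blacklist(callset: GenotypeCallset, report: FPWindowReport):
    """Remove all sites falling in the report's blacklisted windows."""
    if not report.blacklisted_windows:
        return callset.copy()
    black = {(s - 1) // report.window_bp for s, _ in report.blacklisted_windows}
    widx = window_index(callset.pos, report.window_bp)
    return callset.take_sites(~np.isin(widx, list(black)))


def thin_variants(callset: GenotypeCallset, window_bp: int = 20_000):
    """Keep the first SNP (by coordinate) in each occupied grid window."""
    if np.any(np.diff(callset.pos) < 0):
        raise ValueError("positions must be sorted")
    widx = window_index(callset.pos, window_bp)
    _, first = np.unique(widx, return_index=True)
    return callset.take_sites(np.sort(first))


def filter_counts_table(counts: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame({"rule": list(counts.keys()),
                         "n_excluded": list(counts.values())})
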