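import numpy as np
import pytest

from popgenpipe.callset import GenotypeCallset


def make_callset(pos, gt, dp=None, ad_ref=None, ad_alt=None, gq=None,
                 qual=None, info=None, chrom="1", samples=None):
    """Build a small callset from plain arrays, filling benign defaults."""
    gt = np.asarray(gt, dtype=np.int8)
    if gt.ndim == 1:
        gt = gt[:, None]
    n_sites, n_samples = gt.shape
    pos = np.asarray(pos, dtype=np.int64)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]

    def fill(x, default):
        if x is None:
            return np.full(gt.shape, default, dtype=np.int32)
        x = np.asarray(x, dtype=np.int32)
        return x[:, None] if x.ndim == 1 and n_samples == 1 else x

    dp = fill(dp, 20)
    ad_alt_default = np.where(gt == 2, dp, np.where(gt == 1, dp // 2, 0))
    ad_alt = fill(ad_alt, 0) if ad_alt is not None else ad_alt_default.astype(np.int32)
    ad_ref = fill(ad_ref, 0) if ad_ref is not None else (dp - ad_alt).astype(np.int32)
    gq = fill(gq, 99)
    qual = (np.full(n_sites, 500.0) if qual is None
            else np.asarray(qual, dtype=float))
    base_info = {"QD": np.full(n_sites, 20.0), "SOR": np.full(n_sites, 1.0),
                 "MQ": np.full(n_sites, 58.0), "MQRankSum": np.full(n_sites, 0.0),
                 "ReadPosRankSum": np.full(n_sites, 0.0)}
    if info:
        base_info.update({k: np.asarray(v, dtype=float) for k, v in info.items()})
    return GenotypeCallset(
        chrom=np.full(n_sites, chrom, dtype=object), pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        gt=gt, samples=list(samples), dp=dp, ad_ref=ad_ref, ad_alt=ad_alt,
        gq=gq, qual=qual, info=base_info)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
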