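"""Diploid genotype callsets and VCF v4.2 input/output.

The in-memory representation is a dense sites-by-individuals matrix of
diploid genotypes (0/1/2 counts of the alternate allele, -1 for missing)
together with the per-genotype FORMAT fields (DP, AD, GQ) and the per-site
QC annotations (QUAL plus the INFO keys used by the hard filters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: INFO keys carried through read/write and consumed by the site filters.
INFO_KEYS = ("QD", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")

MISSING = -1


class VcfParseError(ValueError):
    """Malformed VCF input; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class GenotypeCallset:
    """Sites x individuals diploid genotype matrix with QC annotations.

    Attributes
    ----------
    chrom : array of str, shape (n_sites,)
    pos : int64 array, 1-based positions, non-decreasing within chromosome
    ref, alt : arrays of allele strings
    gt : int8 array, shape (n_sites, n_samples); 0/1/2 alt-allele dosage,
        -1 for missing
    dp, ad_ref, ad_alt, gq : int32 arrays, same shape as ``gt`` (or None);
        -1 marks missing values
    qual : float array, shape (n_sites,)
    info : mapping of INFO key -> float array, shape (n_sites,)
    samples : list of sample names
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    samples: list[str]
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    gq: np.ndarray | None = None
    qual: np.ndarray | None = None
    info: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.ndim != 2:
            raise ValueError("gt must be 2-D (sites x samples)")
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError("gt shape does not match positions/samples")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def require_format(self, *names: str) -> None:
        """Raise if any of the named FORMAT fields is absent."""
        for name in names:
            attr = {"DP": "dp", "AD": ("ad_ref", "ad_alt"), "GQ": "gq"}[name]
            attrs = attr if isinstance(attr, tuple) else (attr,)
            if any(getattr(self, a) is None for a in attrs):
                raise ValueError(f"callset is missing required FORMAT field {name}")

    def take_sites(self, index) -> "GenotypeCallset":
        """Subset to a boolean mask or integer index over sites."""
        sub = {k: (v[index] if v is not None else None)
               for k, v in (("dp", self.dp), ("ad_ref", self.ad_ref),
                            ("ad_alt", self.ad_alt), ("gq", self.gq))}
        return GenotypeCallset(
            chrom=self.chrom[index], pos=self.pos[index],
            ref=self.ref[index], alt=self.alt[index],
            gt=self.gt[index], samples=list(self.samples),
            qual=None if self.qual is None else self.qual[index],
            info={k: v[index] for k, v in self.info.items()},
            **sub,
        )

    def take_samples(self, index) -> "GenotypeCallset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = {k: (v[:, idx] if v is not None else None)
               for k, v in (("dp", self.dp), ("ad_ref", self.ad_ref),
                            ("ad_alt", self.ad_alt), ("gq", self.gq))}
        return GenotypeCallset(
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=self.alt,
            gt=self.gt[:, idx], samples=[self.samples[i] for i in idx],
            qual=self.qual, info=dict(self.info), **sub,
        )

    def copy(self) -> "GenotypeCallset":
        return self.take_sites(slice(None))

    def mean_depth_per_site(self) -> np.ndarray:
        """Mean DP across non-missing genotypes at each site."""
        self.require_format("DP")
        dp = np.where(self.dp >= 0, self.dp, np.nan).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(dp, axis=1)

    def is_het(self) -> np.ndarray:
        return self.gt == 1

    def is_hom(self) -> np.ndarray:
        return (self.gt == 0) | (self.gt == 2)


# ---------------------------------------------------------------------------
# VCF writing (plain text, v4.2)

_VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by depth">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(callset: GenotypeCallset, path, contigs: dict[str, int] | None = None) -> None:
    """Write a callset as an uncompressed VCF v4.2 text file."""
    has_fmt = callset.dp is not None
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contigs is None:
            contigs = {}
            for c in callset.chrom:
                contigs[str(c)] = None
        for name, length in contigs.items():
            if length:
                fh.write(f"##contig=<ID={name},length={int(length)}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(callset.samples) + "\n")
        fmt = "GT:DP:AD:GQ" if has_fmt else "GT"
        for s in range(callset.n_sites):
            qual = "." if callset.qual is None else f"{callset.qual[s]:g}"
            info_parts = []
            for key in INFO_KEYS:
                if key in callset.info:
                    info_parts.append(f"{key}={callset.info[key][s]:g}")
            info = ";".join(info_parts) if info_parts else "."
            cols = [str(callset.chrom[s]), str(int(callset.pos[s])), ".",
                    str(callset.ref[s]), str(callset.alt[s]), qual, "PASS", info, fmt]
            for j in range(callset.n_samples):
                g = _GT_STR[int(callset.gt[s, j])]
                if has_fmt:
                    dp = int(callset.dp[s, j])
                    adr = int(callset.ad_ref[s, j])
                    ada = int(callset.ad_alt[s, j])
                    gq = int(callset.gq[s, j])
                    dp_s = "." if dp < 0 else str(dp)
                    ad_s = "." if adr < 0 else f"{adr},{ada}"
                    gq_s = "." if gq < 0 else str(gq)
                    cols.append(f"{g}:{dp_s}:{ad_s}:{gq_s}")
                else:
                    cols.append(g)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2-backed, with a structural pre-scan for line numbers)


def _prescan(path) -> int:
    """Validate gross VCF structure; return the number of record lines.

    cyvcf2 does not report line numbers on malformed input, so a cheap text
    scan runs first and raises :class:`VcfParseError` pointing at the line.
    """
    n_records = 0
    n_cols = None
    saw_fileformat = False
    saw_header = False
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                if not line.startswith("##fileformat=VCF"):
                    raise VcfParseError("missing ##fileformat header", lineno)
                saw_fileformat = True
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                n_cols = len(line.rstrip("\n").split("\t"))
                if n_cols < 8:
                    raise VcfParseError("#CHROM header has too few columns", lineno)
                continue
            if not saw_header:
                raise VcfParseError("record before #CHROM header", lineno)
            if not line.endswith("\n"):
                raise VcfParseError("truncated final line (no newline)", lineno)
            ncols_here = len(line.rstrip("\n").split("\t"))
            if ncols_here != n_cols:
                raise VcfParseError(
                    f"expected {n_cols} tab-separated fields, found {ncols_here}",
                    lineno,
                )
            n_records += 1
    if not (saw_fileformat and saw_header):
        raise VcfParseError("no #CHROM header found", None)
    return n_records


def read_vcf(path, strict: bool = True) -> GenotypeCallset:
    """Read a VCF v4.2 file into a :class:`GenotypeCallset`.

    In strict mode the FORMAT fields DP, AD and GQ must be declared; in
    lenient mode missing fields are left as ``None`` on the callset.
    """
    from cyvcf2 import VCF

    _prescan(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    has = {k: k in {h["ID"] for h in vcf.header_iter() if h["HeaderType"] == "FORMAT"}
           for k in ("DP", "AD", "GQ")}
    if strict:
        for k, present in has.items():
            if not present:
                raise VcfParseError(f"required FORMAT field {k} not declared in header")

    chrom, pos, ref, alt, qual = [], [], [], [], []
    gt_rows, dp_rows, adr_rows, ada_rows, gq_rows = [], [], [], [], []
    info_rows = {k: [] for k in INFO_KEYS}
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else ".")
        qual.append(np.nan if rec.QUAL is None else rec.QUAL)
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gt_rows.append(g)
        if has["DP"]:
            dp = rec.format("DP")
            dp_rows.append(np.full(n, MISSING, dtype=np.int32) if dp is None
                           else np.where(dp[:, 0] < 0, MISSING, dp[:, 0]).astype(np.int32))
        if has["AD"]:
            ad = rec.format("AD")
            if ad is None:
                adr_rows.append(np.full(n, MISSING, dtype=np.int32))
                ada_rows.append(np.full(n, MISSING, dtype=np.int32))
            else:
                adr_rows.append(np.where(ad[:, 0] < 0, MISSING, ad[:, 0]).astype(np.int32))
                col = ad[:, 1] if ad.shape[1] > 1 else np.full(n, MISSING)
                ada_rows.append(np.where(col < 0, MISSING, col).astype(np.int32))
        if has["GQ"]:
            gq = rec.format("GQ")
            if gq is None:
                gq_rows.append(np.full(n, MISSING, dtype=np.int32))
            else:
                arr = np.asarray(gq).reshape(n, -1)[:, 0]
                gq_rows.append(np.where(np.isnan(arr.astype(float)), MISSING, arr).astype(np.int32))
        for k in INFO_KEYS:
            v = rec.INFO.get(k)
            info_rows[k].append(np.nan if v is None else float(v))

    def stack(rows, dtype):
        if not rows:
            return np.zeros((0, n), dtype=dtype) if len(pos) == 0 else None
        return np.vstack(rows).astype(dtype)

    n_sites = len(pos)
    info = {}
    for k in INFO_KEYS:
        arr = np.asarray(info_rows[k], dtype=float)
        if n_sites and not np.all(np.isnan(arr)):
            info[k] = arr
    return GenotypeCallset(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        gt=(np.vstack(gt_rows).astype(np.int8) if gt_rows
            else np.zeros((0, n), dtype=np.int8)),
        samples=samples,
        dp=stack(dp_rows, np.int32) if has["DP"] else None,
        ad_ref=stack(adr_rows, np.int32) if has["AD"] else None,
        ad_alt=stack(ada_rows, np.int32) if has["AD"] else None,
        gq=stack(gq_rows, np.int32) if has["GQ"] else None,
        qual=np.asarray(qual, dtype=float),
        info=info,
    )


# ---------------------------------------------------------------------------
# Coordinate conversions


def intervals_to_bed(intervals, path=None):
    """Convert 1-based inclusive (chrom, start, end) intervals to 0-based
    half-open BED rows; optionally write them to ``path``."""
    rows = [(str(c), int(s) - 1, int(e)) for c, s, e in intervals]
    if path is not None:
        with open(path, "w") as fh:
            for c, s, e in rows:
                fh.write(f"{c}\t{s}\t{e}\n")
    return rows


def bed_to_intervals(rows):
    """Convert 0-based half-open BED rows back to 1-based inclusive."""
    return [(c, int(s) + 1, int(e)) for c, s, e in rows]
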