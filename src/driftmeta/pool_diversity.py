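"""Pool-seq variant table, hard-filtering rules, and pi estimation.

The :class:`VariantTable` is the in-memory model of a multi-sample VCF with
per-sample allele depths (AD) and total depths (DP). Depths are always
recomputed as the sum of the allelic depths on load, since upstream callers
may count uninformative reads in DP but not in AD.

Filtering reproduces a standard pool-seq hard-filter stack: site-level
QUAL > 30, MQ > 40, QD > 2.0, FS < 60, biallelic SNVs only; per-sample
genotype masks for DP < 10 and for a minor-allele read depth of exactly 1
(a depth-aware guard against sequencing errors, more conservative than a
minor-allele-frequency cut).

Diversity is the read-sampling-unbiased per-site heterozygosity
``(D/(D-1)) * 2 p (1-p)`` summed over sites and divided by the number of
assayed sites of each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, UndefinedStatisticError
from .records import StatsRecord
from .site_classes import SiteClassTable

__all__ = [
    "PoolSample",
    "VariantTable",
    "FilterReport",
    "FilterThresholds",
    "filter_variants",
    "site_pi",
    "region_pi",
    "read_vcf",
    "write_vcf",
    "read_pools_csv",
]


@dataclass(frozen=True)
class PoolSample:
    """One pooled population sample."""

    sample: str
    pool_size: int = 50

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")

    @property
    def haploid_size(self) -> int:
        return 2 * self.pool_size


@dataclass
class VariantTable:
    """Biallelic-oriented table of variant records with per-sample depths.

    Arrays are aligned on the first axis (records). ``ad_ref``/``ad_alt``
    hold the read depths of the reference and the first alternate allele;
    ``dp`` is the recomputed total depth (sum over all alleles).
    ``n_alleles`` counts REF + ALTs, and ``is_snv`` is True when every
    allele is a single base. ``mask[i, j]`` True excludes sample j at
    record i from all statistics.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    mq: np.ndarray
    qd: np.ndarray
    fs: np.ndarray
    n_alleles: np.ndarray
    is_snv: np.ndarray
    samples: list[str]
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual", "mq", "qd", "fs",
                     "n_alleles", "is_snv"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} not aligned with pos")
        if self.ad_ref.shape != (n, len(self.samples)):
            raise ValueError("ad_ref shape mismatch")

    @property
    def n_records(self) -> int:
        return len(self.pos)

    def take(self, idx) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=self.alt[idx], qual=self.qual[idx], mq=self.mq[idx],
            qd=self.qd[idx], fs=self.fs[idx], n_alleles=self.n_alleles[idx],
            is_snv=self.is_snv[idx], samples=list(self.samples),
            ad_ref=self.ad_ref[idx], ad_alt=self.ad_alt[idx],
            dp=self.dp[idx], mask=self.mask[idx],
        )

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref,
             "alt": self.alt, "qual": self.qual, "mq": self.mq,
             "qd": self.qd, "fs": self.fs}
        )
        for j, s in enumerate(self.samples):
            df[f"{s}.ad_ref"] = self.ad_ref[:, j]
            df[f"{s}.ad_alt"] = self.ad_alt[:, j]
            df[f"{s}.masked"] = self.mask[:, j]
        return df

    @classmethod
    def from_arrays(cls, chrom, pos, ref, alt, samples, ad_ref, ad_alt,
                    qual=None, mq=None, qd=None, fs=None) -> "VariantTable":
        """Convenience constructor for clean biallelic SNV tables."""
        n = len(pos)
        ad_ref = np.asarray(ad_ref, dtype=np.int64)
        ad_alt = np.asarray(ad_alt, dtype=np.int64)

        def _info(x, default):
            if x is None:
                return np.full(n, default, dtype=float)
            return np.asarray(x, dtype=float)

        return cls(
            chrom=np.asarray(chrom, dtype=object),
            pos=np.asarray(pos, dtype=np.int64),
            ref=np.asarray(ref, dtype=object),
            alt=np.asarray(alt, dtype=object),
            qual=_info(qual, 60.0), mq=_info(mq, 60.0),
            qd=_info(qd, 25.0), fs=_info(fs, 0.0),
            n_alleles=np.full(n, 2, dtype=np.int64),
            is_snv=np.ones(n, dtype=bool),
            samples=list(samples),
            ad_ref=ad_ref, ad_alt=ad_alt,
            dp=ad_ref + ad_alt,
            mask=np.zeros((n, len(samples)), dtype=bool),
        )


@dataclass
class FilterThresholds:
    """Hard-filter thresholds (all strict inequalities, as printed)."""

    qual_min: float = 30.0
    mq_min: float = 40.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    dp_min: int = 10
    minor_ad_masked: int = 1


@dataclass
class FilterReport:
    """Counts removed per rule (first-failing-rule attribution in
    ``removed_by_rule``; rules are checked in the listed order)."""

    n_input: int
    n_retained: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    genotypes_masked_dp: int = 0
    genotypes_masked_minor_ad: int = 0

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + sum(self.removed_by_rule.values())


_RULES = ("QUAL", "MQ", "QD", "FS", "biallelic_snv")


def filter_variants(
    table: VariantTable, thresholds: FilterThresholds | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply site-level hard filters and per-sample genotype masks.

    Missing INFO fields (NaN) fail their criterion. Returns the filtered
    table (with masks set) and a :class:`FilterReport`.
    """
    th = thresholds or FilterThresholds()
    with np.errstate(invalid="ignore"):
        passes = {
            "QUAL": table.qual > th.qual_min,
            "MQ": table.mq > th.mq_min,
            "QD": table.qd > th.qd_min,
            "FS": table.fs < th.fs_max,
            "biallelic_snv": (table.n_alleles == 2) & table.is_snv,
        }
    keep = np.ones(table.n_records, dtype=bool)
    removed: dict[str, int] = {}
    for rule in _RULES:
        newly_failed = keep & ~passes[rule]
        removed[rule] = int(newly_failed.sum())
        keep &= passes[rule]
    out = table.take(keep)

    minor = np.minimum(out.ad_ref, out.ad_alt)
    mask_dp = out.dp < th.dp_min
    mask_minor = minor == th.minor_ad_masked
    out.mask = out.mask | mask_dp | mask_minor
    return out, FilterReport(
        n_input=table.n_records,
        n_retained=out.n_records,
        removed_by_rule=removed,
        genotypes_masked_dp=int(mask_dp.sum()),
        genotypes_masked_minor_ad=int((mask_minor & ~mask_dp).sum()),
    )


def site_pi(ad) -> float:
    """Unbiased per-site diversity from per-allele read counts.

    ``(D/(D-1)) * (1 - sum_a p_a^2)``, which is ``(D/(D-1)) * 2 p (1-p)``
    at a biallelic site. Raises ``UndefinedStatisticError`` for D < 2.
    """
    ad = np.asarray(ad, dtype=float)
    depth = ad.sum()
    if depth < 2:
        raise UndefinedStatisticError("site_pi undefined for depth < 2")
    p = ad / depth
    return float(depth / (depth - 1.0) * (1.0 - np.sum(p**2)))


def region_pi(
    table: VariantTable,
    classes: SiteClassTable,
    sample: PoolSample | str,
) -> StatsRecord:
    """Per-sample pi, pi_N and pi_S over a region.

    Variant sites contribute their ``site_pi``; monomorphic sites
    contribute 0 to numerators but stay in the denominators. Sites whose
    genotype is masked or below the depth floor are skipped and removed
    from the class denominator. The overall pi denominator is
    ``s_syn + s_nonsyn`` (coding sites assayed). The pi_N/pi_S ratio is
    flagged as undefined when pi_S is 0.
    """
    name = sample.sample if isinstance(sample, PoolSample) else sample
    j = table.sample_index(name)
    if classes.s_syn + classes.s_nonsyn <= 0:
        raise ValueError("empty region: no assayed sites")

    sum_pi = {"synonymous": 0.0, "nonsynonymous": 0.0, "other": 0.0}
    skipped = {"synonymous": 0, "nonsynonymous": 0, "other": 0}
    n_variant = 0
    for i in range(table.n_records):
        cls_raw = (
            classes.classify(table.chrom[i], int(table.pos[i]),
                             table.ref[i], table.alt[i])
            if classes.classify is not None else "other"
        )
        cls = cls_raw if cls_raw in ("synonymous", "nonsynonymous") else (
            "nonsynonymous" if cls_raw == "nonsense" else "other"
        )
        if table.mask[i, j]:
            skipped[cls] += 1
            continue
        ad = (table.ad_ref[i, j], table.ad_alt[i, j])
        try:
            pi_i = site_pi(ad)
        except UndefinedStatisticError:
            skipped[cls] += 1
            continue
        if pi_i > 0:
            n_variant += 1
        sum_pi[cls] += pi_i

    denom_s = classes.s_syn - skipped["synonymous"]
    denom_n = classes.s_nonsyn - skipped["nonsynonymous"]
    flags: list[str] = []
    pi_s = sum_pi["synonymous"] / denom_s if denom_s > 0 else 0.0
    pi_n = sum_pi["nonsynonymous"] / denom_n if denom_n > 0 else 0.0
    denom_all = denom_s + denom_n
    pi_all = (sum_pi["synonymous"] + sum_pi["nonsynonymous"]) / denom_all
    if pi_s > 0:
        ratio = pi_n / pi_s
    else:
        ratio = None
        flags.append("pi_n_over_pi_s_undefined")
    return StatsRecord(
        sample=name, pi=pi_all, pi_n=pi_n, pi_s=pi_s,
        pi_n_over_pi_s=ratio,
        n_sites_assayed=int(round(denom_all)),
        n_variant_sites=n_variant,
        n_skipped_sites=sum(skipped.values()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# VCF input / output


def read_vcf(path) -> VariantTable:
    """Load a VCF (4.2, FORMAT AD or AD-equivalent) into a VariantTable.

    DP is recomputed as the sum of allelic depths. Records with malformed
    AD arrays raise ``DataIntegrityError`` with their coordinates.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    qual, mq, qd, fs, n_alleles, is_snv = [], [], [], [], [], []
    ad_ref, ad_alt, dp = [], [], []
    for rec in vcf:
        alts = rec.ALT or []
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(",".join(alts) if alts else ".")
        qual.append(rec.QUAL if rec.QUAL is not None else np.nan)
        mq.append(_info_float(rec, "MQ"))
        qd.append(_info_float(rec, "QD"))
        fs.append(_info_float(rec, "FS"))
        n_alleles.append(1 + len(alts))
        is_snv.append(len(rec.REF) == 1 and all(len(a) == 1 for a in alts))
        ad = rec.format("AD")
        if ad is None or ad.shape[0] != len(samples):
            raise DataIntegrityError(
                f"{rec.CHROM}:{rec.POS}: missing or malformed AD"
            )
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        ad_ref.append(ad[:, 0])
        ad_alt.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples)))
        dp.append(ad.sum(axis=1))
    n = len(pos)
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        mq=np.array(mq, dtype=float),
        qd=np.array(qd, dtype=float),
        fs=np.array(fs, dtype=float),
        n_alleles=np.array(n_alleles, dtype=np.int64),
        is_snv=np.array(is_snv, dtype=bool),
        samples=samples,
        ad_ref=np.array(ad_ref, dtype=np.int64).reshape(n, len(samples)),
        ad_alt=np.array(ad_alt, dtype=np.int64).reshape(n, len(samples)),
        dp=np.array(dp, dtype=np.int64).reshape(n, len(samples)),
        mask=np.zeros((n, len(samples)), dtype=bool),
    )


def _info_float(rec, key: str) -> float:
    val = rec.INFO.get(key)
    return float(val) if val is not None else np.nan


def write_vcf(table: VariantTable, path, contigs: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with INFO MQ/QD/FS and FORMAT GT:AD:DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_records):
            info = (f"MQ={table.mq[i]:g};QD={table.qd[i]:g};FS={table.fs[i]:g}")
            cells = []
            for j in range(len(table.samples)):
                r, a = table.ad_ref[i, j], table.ad_alt[i, j]
                gt = "./." if table.mask[i, j] else "0/1" if (r and a) else (
                    "1/1" if a else "0/0")
                cells.append(f"{gt}:{r},{a}:{r + a}")
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t{table.qual[i]:g}\tPASS\t{info}\tGT:AD:DP\t"
                + "\t".join(cells) + "\n"
            )


def read_pools_csv(path) -> list[PoolSample]:
    """pools.csv with columns ``sample`` and ``pool_size``."""
    df = pd.read_csv(path)
    return [PoolSample(str(r["sample"]), int(r["pool_size"]))
            for _, r in df.iterrows()]


def records_to_tsv(records: list[StatsRecord], path) -> None:
    pd.DataFrame([r.to_dict() for r in records]).to_csv(path, sep="\t", index=False)
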