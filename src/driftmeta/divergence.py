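"""Outgroup polarization and rates of (non)adaptive substitution.

Counts, for one pooled sample, synonymous and nonsynonymous polymorphisms
(P_s, P_n) and fixed differences from an outgroup (D_s, D_n), then derives
the McDonald-Kreitman-style statistics:

    alpha    = 1 - (D_s * P_n) / (D_n * P_s)
    d_N      = D_n / S_nonsyn,   d_S = D_s / S_syn
    omega_A  = alpha * d_N / d_S
    omega_NA = (1 - alpha) * d_N / d_S

so that omega_A + omega_NA == d_N/d_S exactly. A site contributes to at
most one of P or D: substitutions are only counted at sites without a
polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import UndefinedStatisticError
from .pool_diversity import VariantTable
from .records import StatsRecord
from .site_classes import SiteClassTable

__all__ = [
    "PolarizedCounts",
    "polarize",
    "alpha",
    "substitution_rates",
    "omega_rates",
    "mk_record",
]


@dataclass(frozen=True)
class PolarizedCounts:
    """Polymorphism / substitution counts plus the site totals."""

    P_n: int
    P_s: int
    D_n: int
    D_s: int
    S_syn: float
    S_nonsyn: float
    n_excluded: int = 0  # countable sites lacking an outgroup allele

    def __post_init__(self) -> None:
        if min(self.P_n, self.P_s, self.D_n, self.D_s) < 0:
            raise ValueError("counts must be non-negative")


def polarize(
    table: VariantTable,
    sample: str,
    outgroup: Mapping[tuple[str, int], str],
    classes: SiteClassTable,
    fixation_threshold: float = 1.0,
) -> PolarizedCounts:
    """Polarize one sample's variant records against outgroup alleles.

    A site is polymorphic (P, by class) when both alleles retain read
    support after masking. It is a substitution (D, by class) when the
    sample is monomorphic and its allele differs from the outgroup base.
    Polymorphic sites never count in D. Sites absent from the table are
    assumed identical to the reference and are not assayed here.

    ``fixation_threshold`` < 1 relaxes the monomorphism rule: a site whose
    major-allele read fraction reaches the threshold is treated as fixed
    for that allele (default 1.0 = strict).

    Sites whose outgroup allele is missing are excluded and tallied in
    ``n_excluded``.
    """
    j = table.sample_index(sample)
    p_n = p_s = d_n = d_s = 0
    excluded = 0
    for i in range(table.n_records):
        if table.mask[i, j]:
            continue
        r, a = int(table.ad_ref[i, j]), int(table.ad_alt[i, j])
        depth = r + a
        if depth == 0:
            continue
        chrom, pos = table.chrom[i], int(table.pos[i])
        ref, alt = table.ref[i], table.alt[i]
        cls_raw = (classes.classify(chrom, pos, ref, alt)
                   if classes.classify is not None else "nonsynonymous")
        if cls_raw == "noncoding":
            continue
        nonsyn = cls_raw in ("nonsynonymous", "nonsense")

        major_frac = max(r, a) / depth
        if major_frac < fixation_threshold and min(r, a) > 0:
            # polymorphic: counts in P regardless of the outgroup state
            if nonsyn:
                p_n += 1
            else:
                p_s += 1
            continue
        out_base = outgroup.get((chrom, pos))
        if out_base is None:
            excluded += 1
            continue
        sample_base = alt if a >= r else ref
        if sample_base.upper() != out_base.upper():
            if nonsyn:
                d_n += 1
            else:
                d_s += 1
    return PolarizedCounts(
        P_n=p_n, P_s=p_s, D_n=d_n, D_s=d_s,
        S_syn=classes.s_syn, S_nonsyn=classes.s_nonsyn,
        n_excluded=excluded,
    )


def alpha(counts: PolarizedCounts) -> float:
    """Proportion of nonsynonymous substitutions driven by positive
    selection: ``1 - (D_s * P_n) / (D_n * P_s)``. May be negative."""
    if counts.D_n == 0 or counts.P_s == 0:
        raise UndefinedStatisticError(
            f"alpha undefined: D_n={counts.D_n}, P_s={counts.P_s}"
        )
    return 1.0 - (counts.D_s * counts.P_n) / (counts.D_n * counts.P_s)


def substitution_rates(counts: PolarizedCounts) -> tuple[float, float]:
    """Substitutions per site of each class: (d_N, d_S)."""
    if counts.S_nonsyn <= 0 or counts.S_syn <= 0:
        raise ValueError("site totals must be positive")
    return counts.D_n / counts.S_nonsyn, counts.D_s / counts.S_syn


def omega_rates(alpha_value: float, d_n: float, d_s: float) -> tuple[float, float]:
    """(omega_A, omega_NA) = (alpha, 1 - alpha) * d_N/d_S.

    The identity omega_A + omega_NA == d_N/d_S holds exactly.
    """
    if d_s == 0:
        raise UndefinedStatisticError("omega undefined: d_S = 0")
    ratio = d_n / d_s
    return alpha_value * ratio, (1.0 - alpha_value) * ratio


def mk_record(counts: PolarizedCounts, sample: str = "") -> StatsRecord:
    """Assemble a StatsRecord from polarized counts, flagging undefined
    statistics instead of raising."""
    rec = StatsRecord(
        sample=sample, P_n=counts.P_n, P_s=counts.P_s,
        D_n=counts.D_n, D_s=counts.D_s,
    )
    try:
        rec.d_n, rec.d_s = substitution_rates(counts)
    except ValueError:
        rec.flags.append("rates_undefined")
        return rec
    try:
        rec.alpha = alpha(counts)
    except UndefinedStatisticError:
        rec.flags.append("alpha_undefined")
    if rec.alpha is not None:
        try:
            rec.omega_a, rec.omega_na = omega_rates(rec.alpha, rec.d_n, rec.d_s)
        except UndefinedStatisticError:
            rec.flags.append("omega_undefined")
    return rec


def counts_from_simulation(result, L: int, nonsyn_fraction: float) -> PolarizedCounts:
    """Polarized counts from a forward-simulation substitution run.

    In a substitution-tracking run the ancestral state is known exactly,
    so P and D counts map one-to-one onto :class:`PolarizedCounts` with
    site totals ``L * nonsyn_fraction`` / ``L * (1 - nonsyn_fraction)``.
    Combine with :func:`mk_record` to study how alpha, omega_A and
    omega_NA behave across simulated population sizes or DFEs.
    """
    return PolarizedCounts(
        P_n=result.P_n, P_s=result.P_s, D_n=result.D_n, D_s=result.D_s,
        S_syn=L * (1.0 - nonsyn_fraction), S_nonsyn=L * nonsyn_fraction,
    )


def read_outgroup_tsv(path) -> dict[tuple[str, int], str]:
    """Outgroup alleles from a TSV with columns chrom, pos, base."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None if _headerless(path) else 0)
    if df.shape[1] < 3:
        raise ValueError("outgroup TSV needs >= 3 columns: chrom, pos, base")
    df.columns = ["chrom", "pos", "base"] + list(df.columns[3:])
    return {(str(r.chrom), int(r.pos)): str(r.base) for r in df.itertuples()}


def _headerless(path) -> bool:
    with open(path) as fh:
        first = fh.readline().split("\t")
    try:
        int(first[1])
        return True
    except (ValueError, IndexError):
        return False
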