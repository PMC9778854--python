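"""Per-(sub)population summary-statistic record."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class StatsRecord:
    """All summary statistics reported for one (sub)population sample.

    Fields left ``None`` were not computed (or were undefined for the
    inputs, in which case the companion ``flags`` list says why).
    """

    sample: str = ""
    pi: float | None = None
    pi_n: float | None = None
    pi_s: float | None = None
    pi_n_over_pi_s: float | None = None
    n_sites_assayed: int | None = None
    n_variant_sites: int | None = None
    n_skipped_sites: int | None = None
    P_n: int | None = None
    P_s: int | None = None
    D_n: int | None = None
    D_s: int | None = None
    d_n: float | None = None
    d_s: float | None = None
    alpha: float | None = None
    omega_a: float | None = None
    omega_na: float | None = None
    fst_mean: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = ";".join(self.flags)
        return d
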