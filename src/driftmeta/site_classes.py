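"""Codon-aware site classification and Nei-Gojobori site counting.

Given a reference FASTA and a CDS annotation (GFF3 or GTF), this module
classifies point variants as synonymous / nonsynonymous / nonsense /
noncoding, and tallies the synonymous and nonsynonymous *site* totals that
serve as denominators for pi_N, pi_S, d_N and d_S.

Site counting follows the classic Nei-Gojobori scheme: for every codon,
each of the nine possible single-base changes is classified by whether the
encoded amino acid changes, each position contributing ``changes/3`` sites
to each class (no transition/transversion weighting). By default a change
that creates a stop codon counts as nonsynonymous; set
``stop_policy="exclude"`` to drop such changes from the opportunity counts
instead.

Coordinates are 1-based inclusive externally (GFF3 convention) and 0-based
half-open internally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import AnnotationError, DataIntegrityError

__all__ = [
    "GeneticCode",
    "CdsModel",
    "SiteClassTable",
    "standard_code",
    "codon_site_counts",
    "classify_variant",
    "cds_site_totals",
    "read_fasta",
    "read_cds_annotation",
]

BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus its stop-codon set."""

    forward: Mapping[str, str]
    stops: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.forward) != 61 or len(self.stops) != 3:
            raise ValueError("expected 61 sense codons and 3 stops")

    def translate(self, codon: str) -> str:
        """Amino acid for a codon; ``"*"`` for a stop."""
        codon = codon.upper()
        if codon in self.stops:
            return "*"
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stops

    def is_sense(self, codon: str) -> bool:
        return codon.upper() in self.forward


def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    return GeneticCode(dict(table.forward_table), frozenset(table.stop_codons))


_STANDARD = standard_code()


def codon_site_counts(
    codon: str,
    code: GeneticCode = _STANDARD,
    stop_policy: str = "nonsynonymous",
) -> tuple[float, float]:
    """Nei-Gojobori synonymous / nonsynonymous site counts for one codon.

    Enumerates the nine single-base changes; a change is synonymous iff the
    amino acid is unchanged. Changes creating a stop codon count as
    nonsynonymous under the default policy, or are excluded from both
    classes under ``stop_policy="exclude"`` (then syn + nonsyn < 3).

    Raises ``ValueError`` for codons containing ambiguous bases or for stop
    codons; callers flag and exclude such codons from totals.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon has no site counts: {codon!r}")
    if stop_policy not in ("nonsynonymous", "exclude"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    aa = code.translate(codon)
    syn = 0.0
    nonsyn = 0.0
    for i, alt in itertools.product(range(3), BASES):
        if alt == codon[i]:
            continue
        mutant = codon[:i] + alt + codon[i + 1 :]
        if code.is_stop(mutant):
            if stop_policy == "nonsynonymous":
                nonsyn += 1.0
            continue
        if code.translate(mutant) == aa:
            syn += 1.0
        else:
            nonsyn += 1.0
    return syn / 3.0, nonsyn / 3.0


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CdsModel:
    """One CDS (transcript) as ordered exon intervals on a reference seq.

    ``exons`` are (start, end) pairs, 1-based inclusive in genomic
    coordinates, listed in transcription order (ascending starts on the
    plus strand, descending on the minus strand). ``phase`` is the number
    of bases to skip at the 5' end to reach the first complete codon.
    """

    gene_id: str
    seqid: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.phase not in (0, 1, 2):
            raise AnnotationError(f"{self.gene_id}: phase must be 0, 1 or 2")
        for start, end in self.exons:
            if not 1 <= start <= end:
                raise AnnotationError(
                    f"{self.gene_id}: bad interval ({start}, {end})"
                )
        # transcription order: 5'->3' along the mRNA
        starts = [s for s, _ in self.exons]
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise AnnotationError(
                f"{self.gene_id}: exons not in transcription order"
            )

    @property
    def genomic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def coding_length(self) -> int:
        return self.genomic_length - self.phase

    def validate_frame(self) -> None:
        if self.coding_length() % 3 != 0:
            raise AnnotationError(
                f"{self.gene_id}: CDS length {self.coding_length()} "
                "not divisible by 3"
            )

    def cds_sequence(self, refseq: str) -> str:
        """Phase-trimmed coding sequence, 5'->3' on the coding strand."""
        parts = []
        for start, end in self.exons:
            chunk = refseq[start - 1 : end]  # to 0-based half-open
            parts.append(_revcomp(chunk) if self.strand == "-" else chunk)
        return "".join(parts).upper()[self.phase :]

    def genomic_to_cds_index(self, pos: int) -> int | None:
        """0-based index into the phase-trimmed CDS, or None if outside."""
        offset = 0
        for start, end in self.exons:
            if start <= pos <= end:
                within = (pos - start) if self.strand == "+" else (end - pos)
                idx = offset + within - self.phase
                return idx if idx >= 0 else None
            offset += end - start + 1
        return None


def classify_variant(
    cds: CdsModel | Iterable[CdsModel],
    refseq: str | Mapping[str, str],
    pos: int,
    ref: str,
    alt: str,
    code: GeneticCode = _STANDARD,
) -> str:
    """Class of a biallelic SNP: synonymous / nonsynonymous / nonsense / noncoding.

    ``pos`` is 1-based on the reference sequence. With several CDS models,
    the first (in input order) whose intervals contain the position is used
    (per-transcript assignment). Raises ``DataIntegrityError`` when ``ref``
    disagrees with the reference sequence.
    """
    models = [cds] if isinstance(cds, CdsModel) else list(cds)
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_variant handles single-base SNPs only")
    for model in models:
        seq = refseq[model.seqid] if isinstance(refseq, Mapping) else refseq
        base = seq[pos - 1].upper()
        if base != ref:
            raise DataIntegrityError(
                f"{model.seqid}:{pos}: VCF REF {ref!r} != reference {base!r}"
            )
        idx = model.genomic_to_cds_index(pos)
        if idx is None:
            continue
        cds_seq = model.cds_sequence(seq)
        codon_start = (idx // 3) * 3
        codon = cds_seq[codon_start : codon_start + 3]
        if len(codon) < 3 or any(b not in BASES for b in codon):
            continue  # incomplete/ambiguous codon: treat as unclassifiable
        alt_coding = alt.translate(_COMPLEMENT) if model.strand == "-" else alt
        offset = idx % 3
        mutant = codon[:offset] + alt_coding + codon[offset + 1 :]
        if code.is_stop(codon):
            continue  # reference stop codon: not classified
        if code.is_stop(mutant):
            return "nonsense"
        if code.translate(mutant) == code.translate(codon):
            return "synonymous"
        return "nonsynonymous"
    return "noncoding"


@dataclass
class SiteClassTable:
    """Synonymous / nonsynonymous site totals plus a variant classifier.

    ``per_gene`` has one row per CDS with columns ``gene``, ``s_syn``,
    ``s_nonsyn``, ``n_codons_skipped``; ``s_syn``/``s_nonsyn`` are the
    genome-wide totals. ``classify`` maps (chrom, pos, ref, alt) to a
    variant class and is used by the diversity and divergence stages; for
    synthetic data it may be backed by a plain per-site lookup instead of
    an annotation.
    """

    per_gene: pd.DataFrame
    s_syn: float
    s_nonsyn: float
    classify: Callable[[str, int, str, str], str] | None = None
    _models: list[CdsModel] = field(default_factory=list, repr=False)

    @classmethod
    def from_annotation(
        cls,
        models: Iterable[CdsModel],
        refseqs: Mapping[str, str],
        code: GeneticCode = _STANDARD,
        stop_policy: str = "nonsynonymous",
    ) -> "SiteClassTable":
        return cds_site_totals(models, refseqs, code=code, stop_policy=stop_policy)

    @classmethod
    def from_site_classes(
        cls,
        classes_by_site: Mapping[tuple[str, int], str],
        s_syn: float,
        s_nonsyn: float,
    ) -> "SiteClassTable":
        """Build from an explicit (chrom, pos) -> class map (synthetic data)."""

        def _classify(chrom: str, pos: int, ref: str, alt: str) -> str:
            return classes_by_site.get((chrom, pos), "noncoding")

        per_gene = pd.DataFrame(
            [{"gene": "synthetic", "s_syn": s_syn, "s_nonsyn": s_nonsyn,
              "n_codons_skipped": 0}]
        )
        return cls(per_gene=per_gene, s_syn=s_syn, s_nonsyn=s_nonsyn,
                   classify=_classify)

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene.copy()


def cds_site_totals(
    models: Iterable[CdsModel],
    refseqs: Mapping[str, str],
    code: GeneticCode = _STANDARD,
    stop_policy: str = "nonsynonymous",
) -> SiteClassTable:
    """Sum per-codon site counts over all CDS models.

    Codons containing ambiguous bases, and internal stop codons, are
    skipped and tallied per gene. A CDS whose phase-trimmed length is not a
    multiple of 3 raises ``AnnotationError`` naming the gene.
    """
    models = list(models)
    rows = []
    for model in models:
        model.validate_frame()
        seq = refseqs[model.seqid]
        cds_seq = model.cds_sequence(seq)
        syn = nonsyn = 0.0
        skipped = 0
        for k in range(0, len(cds_seq) - 2, 3):
            codon = cds_seq[k : k + 3]
            try:
                s, n = codon_site_counts(codon, code, stop_policy)
            except ValueError:
                skipped += 1
                continue
            syn += s
            nonsyn += n
        rows.append(
            {"gene": model.gene_id, "s_syn": syn, "s_nonsyn": nonsyn,
             "n_codons_skipped": skipped}
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene", "s_syn", "s_nonsyn", "n_codons_skipped"]
    )
    total_syn = float(per_gene["s_syn"].sum()) if len(per_gene) else 0.0
    total_nonsyn = float(per_gene["s_nonsyn"].sum()) if len(per_gene) else 0.0

    def _classify(chrom: str, pos: int, ref: str, alt: str) -> str:
        relevant = [m for m in models if m.seqid == chrom]
        if not relevant:
            return "noncoding"
        return classify_variant(relevant, refseqs, pos, ref, alt, code)

    return SiteClassTable(
        per_gene=per_gene,
        s_syn=total_syn,
        s_nonsyn=total_nonsyn,
        classify=_classify,
        _models=models,
    )


def read_fasta(path) -> dict[str, str]:
    """Reference sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_cds_annotation(path, fmt: str | None = None) -> list[CdsModel]:
    """CDS models from a GFF3 or GTF file (``CDS`` features, phase honored).

    Features are grouped by their ``Parent`` attribute (GFF3) or
    ``transcript_id`` (GTF), falling back to ``ID``/``gene_id``. The frame
    offset of each model is the phase of its 5'-most CDS feature.
    """
    import gffutils

    path = str(path)
    if fmt is None:
        fmt = "gtf" if path.endswith((".gtf", ".GTF")) else "gff3"
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        if "Parent" in feat.attributes:
            key = feat.attributes["Parent"][0]
        elif "transcript_id" in feat.attributes:
            key = feat.attributes["transcript_id"][0]
        elif "ID" in feat.attributes:
            key = feat.attributes["ID"][0]
        else:
            key = feat.attributes.get("gene_id", [feat.id])[0]
        groups.setdefault(key, []).append(feat)

    models = []
    for gene_id, feats in groups.items():
        strand = feats[0].strand if feats[0].strand in "+-" else "+"
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        first_phase = feats[0].frame
        phase = int(first_phase) if first_phase not in (None, ".") else 0
        models.append(
            CdsModel(
                gene_id=gene_id,
                seqid=feats[0].seqid,
                exons=[(f.start, f.end) for f in feats],
                strand=strand,
                phase=phase,
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models


def synonymous_fraction_of_position(codon: str, position: int,
                                    code: GeneticCode = _STANDARD) -> float:
    """Fraction of the 3 changes at one codon position that are synonymous."""
    codon = codon.upper()
    aa = code.translate(codon)
    syn = 0
    for alt in BASES:
        if alt == codon[position]:
            continue
        mutant = codon[:position] + alt + codon[position + 1 :]
        if not code.is_stop(mutant) and code.translate(mutant) == aa:
            syn += 1
    return syn / 3.0


# re-export for callers that want Biopython translation as a cross-check
def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())
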