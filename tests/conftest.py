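"""Shared fixtures: a tiny annotated genome and small variant tables."""

from __future__ import annotations

import numpy as np
import pytest

from driftmeta.pool_diversity import VariantTable
from driftmeta.site_classes import CdsModel

# A 120 bp contig. Positions 31-90 carry a plus-strand CDS of 20 codons;
# positions 1-30 and 91-120 are noncoding.
PLUS_CDS = (
    "ATG" "GGG" "TTT" "TGG" "AAA" "CCC" "GAT" "CGT" "ACG" "TCA"
    "ATC" "GGA" "CTG" "TTA" "CAC" "GTG" "AGC" "TAC" "AAG" "GAA"
)
CONTIG = ("ACGTACGTAC" * 3) + PLUS_CDS + ("TTGCAAGCTT" * 3)


@pytest.fixture(scope="session")
def refseqs() -> dict[str, str]:
    return {"contig_1": CONTIG}


@pytest.fixture(scope="session")
def plus_cds() -> CdsModel:
    return CdsModel(gene_id="gene_plus", seqid="contig_1",
                    exons=[(31, 90)], strand="+")


@pytest.fixture(scope="session")
def split_cds() -> CdsModel:
    """Same CDS split into three exons (intron-free split for testing)."""
    return CdsModel(gene_id="gene_split", seqid="contig_1",
                    exons=[(31, 45), (46, 72), (73, 90)], strand="+")


@pytest.fixture(scope="session")
def minus_cds() -> CdsModel:
    """A minus-strand CDS on the same contig.

    Its coding sequence is the reverse complement of positions 31-90, so
    classifications must mirror the plus-strand CDS of the reverse
    complement contig.
    """
    return CdsModel(gene_id="gene_minus", seqid="contig_1",
                    exons=[(31, 90)], strand="-")


@pytest.fixture()
def fasta_gff(tmp_path, refseqs):
    """Write the fixture genome as FASTA + GFF3 files."""
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">contig_1\n" + refseqs["contig_1"] + "\n")
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "contig_1\ttest\tmRNA\t31\t90\t.\t+\t.\tID=tx1\n"
        "contig_1\ttest\tCDS\t31\t60\t.\t+\t0\tID=cds1;Parent=tx1\n"
        "contig_1\ttest\tCDS\t61\t90\t.\t+\t0\tID=cds2;Parent=tx1\n"
    )
    return fasta, gff


def make_table(ad_by_sample: dict[str, list[tuple[int, int]]],
               pos=None, ref=None, alt=None, **info) -> VariantTable:
    """Small biallelic SNV table from per-sample (ad_ref, ad_alt) lists."""
    samples = list(ad_by_sample)
    n = len(next(iter(ad_by_sample.values())))
    ad = np.array([ad_by_sample[s] for s in samples])  # (S, n, 2)
    return VariantTable.from_arrays(
        chrom=["contig_1"] * n,
        pos=pos if pos is not None else np.arange(1, n + 1),
        ref=ref if ref is not None else ["A"] * n,
        alt=alt if alt is not None else ["G"] * n,
        samples=samples,
        ad_ref=ad[:, :, 0].T,
        ad_alt=ad[:, :, 1].T,
        **info,
    )
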