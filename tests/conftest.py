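"""Shared fixtures: hand-built gene models, strand mirroring, a demo panel."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import HealthCheck, settings

from selfscan.effect_annotator import CdsSegment, GeneModel
from selfscan.synthetic_data import PanelConfig, generate_dataset
from selfscan.variant import Variant

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_gene(cds: str, strand: str = "+", chrom: str = "chrT", upstream: int = 60,
               downstream: int = 60, intron_len: int = 40):
    """Two-exon gene with the given CDS; returns (GeneModel, {chrom: sequence}).

    The CDS is split mid-sequence (not necessarily at a codon boundary) by one
    GT..AG intron; flanks are fixed pseudo-random sequence, so the fixture is
    deterministic.
    """
    assert len(cds) % 3 == 0 and cds.startswith("ATG")
    rng = np.random.default_rng(99)
    rand = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    split = len(cds) // 2
    intron = "GT" + rand(intron_len - 4) + "AG"
    transcript = cds[:split] + intron + cds[split:]
    genomic = transcript if strand == "+" else str(Seq(transcript).reverse_complement())
    seq = rand(upstream) + genomic + rand(downstream)

    start = upstream + 1
    phases = [0, (3 - split % 3) % 3]
    if strand == "+":
        seg1 = CdsSegment(start, start + split - 1, phases[0])
        seg2_start = start + split + intron_len
        seg2 = CdsSegment(seg2_start, seg2_start + (len(cds) - split) - 1, phases[1])
        segments = (seg1, seg2)
    else:
        end = start + len(transcript) - 1
        seg1 = CdsSegment(end - split + 1, end, phases[0])  # first in translation order
        seg2_end = end - split - intron_len
        seg2 = CdsSegment(seg2_end - (len(cds) - split) + 1, seg2_end, phases[1])
        segments = (seg2, seg1)
    gene = GeneModel(
        gene_id="toy_gene", transcript_id="toy_gene.t1", chrom=chrom,
        strand=strand, cds=segments,
    )
    return gene, {chrom: seq}


def mirror_fixture(gene: GeneModel, reference: dict, variant: Variant):
    """Reverse-complement the whole fixture: sequence, gene and variant.

    The mirrored gene lies on the opposite strand of the mirrored chromosome;
    annotation of the mirrored variant must reproduce the original call.
    """
    chrom = gene.chrom
    seq = reference[chrom]
    L = len(seq)
    mseq = str(Seq(seq).reverse_complement())
    msegs = tuple(
        sorted(
            (CdsSegment(L - s.end + 1, L - s.start + 1, s.phase) for s in gene.cds),
            key=lambda s: s.start,
        )
    )
    mgene = GeneModel(
        gene_id=gene.gene_id, transcript_id=gene.transcript_id, chrom=chrom,
        strand="-" if gene.strand == "+" else "+", cds=msegs,
    )
    if variant.is_snv:
        mpos = L - variant.pos + 1
        mvariant = Variant(chrom, mpos, str(Seq(variant.ref).complement()),
                           str(Seq(variant.alt).complement()))
    elif len(variant.ref) == 1:  # anchored insertion
        mpos = L - variant.pos
        ins = variant.alt[1:]
        ref = mseq[mpos - 1]
        mvariant = Variant(chrom, mpos, ref, ref + str(Seq(ins).reverse_complement()))
    else:
        raise NotImplementedError("only SNVs and insertions are mirrored")
    return mgene, {chrom: mseq}, mvariant


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """One default synthetic panel shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("panel")
    return generate_dataset(PanelConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def demo_partition():
    return (["mutant_a", "mutant_b"], ["mutant_c", "wild_1", "wild_2", "wild_3", "wild_4"])
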