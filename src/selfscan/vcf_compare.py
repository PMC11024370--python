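"""Genotype-matrix construction and near-isogenic set operations on VCFs.

The module ingests a multi-sample VCF into a dense genotype matrix (records x
accessions, calls coded hom_ref / het / hom_alt / missing, multi-allelic
records split into biallelic rows), extracts target-specific variant sets
(homozygous-alt in every target, homozygous-ref in every comparator — any
heterozygous or missing call among the involved accessions excludes the site,
matching pure-line biology), and computes the pairwise genomic difference
rate: the count of positions at which two accessions carry different alleles
divided by the reference genome length. Because that formula measures a
difference density, the rate is reported as ``difference_rate`` with its
complement ``similarity = 1 - difference_rate`` alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .variant import Variant
from .vcfio import write_vcf


class Genotype(IntEnum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


class VcfOrderError(ValueError):
    """Input records are not position-sorted within a chromosome."""


GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


@dataclass
class GenotypeMatrix:
    """Split biallelic variant records x accession genotype calls."""

    records: list  # list[Variant], row order preserved from the VCF
    samples: list
    calls: np.ndarray  # (n_records, n_samples) int8 of Genotype codes
    reference_length: int

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.records), len(self.samples)):
            raise ValueError("calls shape does not match records x samples")
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise ValueError(f"unknown accession {name!r}; panel has {self.samples}") from None


@dataclass
class VariantSet:
    """A reproducible selection of matrix rows with the partition behind it."""

    matrix: GenotypeMatrix
    indices: np.ndarray
    targets: frozenset
    comparators: frozenset

    @property
    def records(self) -> list:
        return [self.matrix.records[i] for i in self.indices]

    def __len__(self) -> int:
        return len(self.indices)

    def write_vcf(self, path: str, contigs: Optional[dict] = None) -> None:
        if contigs is None:
            chroms = {r.chrom for r in self.matrix.records}
            contigs = {c: self.matrix.reference_length for c in sorted(chroms)}
        rows = []
        for i in self.indices:
            rec = self.matrix.records[i]
            gts = [GT_STRINGS[Genotype(c)] for c in self.matrix.calls[i]]
            rows.append((rec.chrom, rec.pos, rec.ref, [rec.alt], gts, None))
        write_vcf(path, contigs, self.matrix.samples, rows)


def load_matrix(vcf_path: str, reference_length: int) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one row per ALT allele, each sample's
    call re-coded by its copy number of that allele (alleles other than the
    row's ALT count as reference). Any missing allele in a genotype yields a
    missing call. Input must be position-sorted within each chromosome and
    carry GT for every sample.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{vcf_path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        records = []
        rows = []
        last_pos: dict = {}
        for rec in vcf:
            prev = last_pos.get(rec.chrom)
            if prev is not None and rec.pos < prev:
                raise VcfOrderError(
                    f"{vcf_path}: record {rec.chrom}:{rec.pos} out of order "
                    f"(previous position {prev})"
                )
            last_pos[rec.chrom] = rec.pos
            alts = rec.alts or ()
            gts = []
            for s in samples:
                sample = rec.samples[s]
                if "GT" not in sample or sample["GT"] is None:
                    raise ValueError(f"{vcf_path}: missing GT at {rec.chrom}:{rec.pos}")
                gts.append(sample["GT"])
            for k, alt in enumerate(alts, start=1):
                codes = []
                for gt in gts:
                    if any(a is None for a in gt) or len(gt) == 0:
                        codes.append(Genotype.MISSING)
                        continue
                    copies = sum(1 for a in gt if a == k)
                    codes.append(
                        Genotype.HOM_ALT
                        if copies == len(gt) and len(gt) > 0
                        else Genotype.HET
                        if copies > 0
                        else Genotype.HOM_REF
                    )
                records.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
                rows.append(codes)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        records=records, samples=samples, calls=calls, reference_length=reference_length
    )


def target_specific(
    matrix: GenotypeMatrix,
    targets: Iterable[str],
    comparators: Iterable[str],
) -> VariantSet:
    """Variants homozygous-alt in every target and homozygous-ref in every comparator.

    Heterozygous or missing calls among the involved accessions exclude a
    record. After the biallelic split, "the same allele in every target" is
    guaranteed per row. The selection depends only on the partition, not on
    accession or record order.
    """
    targets = frozenset(targets)
    comparators = frozenset(comparators)
    if not targets or not comparators:
        raise ValueError("both targets and comparators must be non-empty")
    if targets & comparators:
        raise ValueError(f"targets and comparators overlap: {sorted(targets & comparators)}")
    t_idx = [matrix.sample_index(n) for n in sorted(targets)]
    c_idx = [matrix.sample_index(n) for n in sorted(comparators)]
    calls = matrix.calls
    mask = np.all(calls[:, t_idx] == Genotype.HOM_ALT, axis=1) & np.all(
        calls[:, c_idx] == Genotype.HOM_REF, axis=1
    )
    return VariantSet(
        matrix=matrix,
        indices=np.flatnonzero(mask),
        targets=targets,
        comparators=comparators,
    )


def pairwise_difference_rate(
    matrix: GenotypeMatrix,
    accession_a: str,
    accession_b: str,
    hom_only: bool = False,
) -> float:
    """Genomic difference rate between two accessions.

    Counts positions (a multi-allelic position counts once) where the two
    accessions' genotype calls differ, divided by the reference length. Rows
    where either call is missing are skipped — a missing call asserts no
    allele. ``hom_only=True`` restricts counting to rows where both calls are
    homozygous; the default also counts het-vs-hom differences.
    """
    ia = matrix.sample_index(accession_a)
    ib = matrix.sample_index(accession_b)
    differing = set()
    for rec, row in zip(matrix.records, matrix.calls):
        ca, cb = Genotype(row[ia]), Genotype(row[ib])
        if Genotype.MISSING in (ca, cb):
            continue
        if hom_only and Genotype.HET in (ca, cb):
            continue
        if ca != cb:
            differing.add((rec.chrom, rec.pos))
    return len(differing) / matrix.reference_length


def similarity_table(
    matrix: GenotypeMatrix,
    accessions: Optional[Sequence[str]] = None,
    hom_only: bool = False,
) -> pd.DataFrame:
    """Long-format table of difference rate and similarity for all pairs."""
    names = list(accessions) if accessions is not None else list(matrix.samples)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rate = pairwise_difference_rate(matrix, a, b, hom_only=hom_only)
            rows.append(
                {
                    "accession_a": a,
                    "accession_b": b,
                    "difference_rate": rate,
                    "similarity": 1.0 - rate,
                }
            )
    return pd.DataFrame(rows, columns=["accession_a", "accession_b", "difference_rate", "similarity"])
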