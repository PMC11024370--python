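"""SnpEff-style classification of variants against CDS-aware gene models.

Variants are classified per overlapping transcript into effect terms
(frameshift_variant, stop_gained, missense_variant, ...) and mapped onto the
conventional severity classes:

* HIGH       — frameshift_variant, stop_gained, stop_lost, start_lost,
               splice_site_variant
* MODERATE   — missense_variant, inframe_insertion, inframe_deletion
* LOW        — synonymous_variant
* MODIFIER   — intron_variant, utr_variant, intergenic_variant

SNVs are translated codon-aware on the coding strand (standard nuclear code);
coding indels are frameshifts iff their net CDS length change is not a
multiple of 3. The splice window is the common 2 bp on the intron side of each
CDS/intron boundary.

Gene models are read from GFF3 (gene -> mRNA -> CDS with phase) via
:func:`load_gene_models`; the reference is a plain mapping of chromosome name
to uppercase sequence string.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio.Seq import Seq

from .variant import Variant

SPLICE_WINDOW = 2


class Impact(IntEnum):
    """Severity classes ordered so that comparisons pick the worst effect."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


EFFECT_IMPACT: Mapping[str, Impact] = {
    "frameshift_variant": Impact.HIGH,
    "stop_gained": Impact.HIGH,
    "stop_lost": Impact.HIGH,
    "start_lost": Impact.HIGH,
    "splice_site_variant": Impact.HIGH,
    "missense_variant": Impact.MODERATE,
    "inframe_insertion": Impact.MODERATE,
    "inframe_deletion": Impact.MODERATE,
    "synonymous_variant": Impact.LOW,
    "intron_variant": Impact.MODIFIER,
    "utr_variant": Impact.MODIFIER,
    "intergenic_variant": Impact.MODIFIER,
}


class ReferenceMismatchError(ValueError):
    """REF allele disagrees with the reference sequence (coordinate bug guard)."""


@dataclass(frozen=True)
class CdsSegment:
    """One CDS segment, 1-based inclusive genomic coordinates."""

    start: int
    end: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS segment start {self.start} > end {self.end}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware transcript with ordered CDS segments.

    Segments are stored sorted in genomic order and must not overlap; the
    concatenated CDS must be a whole number of codons. ``tx_start``/``tx_end``
    default to the CDS span (no UTR) when not supplied.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: tuple
    tx_start: Optional[int] = None
    tx_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds:
            raise ValueError("gene model needs at least one CDS segment")
        segs = list(self.cds)
        if segs != sorted(segs, key=lambda s: s.start):
            raise ValueError("CDS segments must be sorted in genomic order")
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValueError("CDS segments must not overlap")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.cds)

    @property
    def span(self) -> tuple:
        start = self.tx_start if self.tx_start is not None else self.cds[0].start
        end = self.tx_end if self.tx_end is not None else self.cds[-1].end
        return (start, end)

    def segment_at(self, pos: int) -> Optional[CdsSegment]:
        for seg in self.cds:
            if seg.start <= pos <= seg.end:
                return seg
        return None

    def cds_index(self, pos: int) -> int:
        """0-based coding-strand coordinate of a genomic position inside CDS."""
        seg = self.segment_at(pos)
        if seg is None:
            raise ValueError(f"position {pos} is not in the CDS of {self.transcript_id}")
        if self.strand == "+":
            before = sum(s.length for s in self.cds if s.end < seg.start)
            return before + (pos - seg.start)
        before = sum(s.length for s in self.cds if s.start > seg.end)
        return before + (seg.end - pos)

    def genomic_position(self, cds_idx: int) -> int:
        """Genomic position (1-based) of a 0-based coding-strand coordinate."""
        if not 0 <= cds_idx < self.cds_length:
            raise ValueError(f"coding index {cds_idx} outside CDS of {self.transcript_id}")
        segs = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        offset = cds_idx
        for seg in segs:
            if offset < seg.length:
                return seg.start + offset if self.strand == "+" else seg.end - offset
            offset -= seg.length
        raise AssertionError("unreachable")

    def coding_sequence(self, reference: Mapping[str, str]) -> str:
        seq = reference[self.chrom]
        parts = [seq[s.start - 1 : s.end] for s in self.cds]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds.upper()

    def protein(self, reference: Mapping[str, str]) -> str:
        """Translation of the full CDS, terminal stop rendered as '*'."""
        return str(Seq(self.coding_sequence(reference)).translate())


@dataclass(frozen=True)
class ImpactCall:
    """One variant x transcript effect call."""

    variant: Variant
    gene_id: Optional[str]
    transcript_id: Optional[str]
    effect: str
    impact: Impact
    protein_change: Optional[str] = None
    protein_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_IMPACT:
            raise ValueError(f"unknown effect term {self.effect!r}")
        if EFFECT_IMPACT[self.effect] is not self.impact:
            raise ValueError(f"{self.effect} must be classed {EFFECT_IMPACT[self.effect].name}")


def load_gene_models(gff3_path: str) -> list:
    """Parse a GFF3 file (gene -> mRNA -> CDS with phase) into GeneModels."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        segs = []
        for c in db.children(mrna, featuretype="CDS", order_by="start"):
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            segs.append(CdsSegment(start=c.start, end=c.end, phase=phase))
        parents = mrna.attributes.get("Parent", [mrna.id])
        models.append(
            GeneModel(
                gene_id=parents[0],
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds=tuple(segs),
                tx_start=mrna.start,
                tx_end=mrna.end,
            )
        )
    return models


def _call(variant, gm, effect, protein_change=None, protein_pos=None) -> ImpactCall:
    return ImpactCall(
        variant=variant,
        gene_id=gm.gene_id if gm is not None else None,
        transcript_id=gm.transcript_id if gm is not None else None,
        effect=effect,
        impact=EFFECT_IMPACT[effect],
        protein_change=protein_change,
        protein_pos=protein_pos,
    )


def _near_splice(gm: GeneModel, positions: Iterable[int]) -> bool:
    """True if any position lies in the 2 bp intron window of a CDS boundary."""
    segs = gm.cds
    for pos in positions:
        for i, seg in enumerate(segs):
            if i + 1 < len(segs) and seg.end < pos <= seg.end + SPLICE_WINDOW:
                return True
            if i > 0 and seg.start - SPLICE_WINDOW <= pos < seg.start:
                return True
    return False


def _in_intron(gm: GeneModel, pos: int) -> bool:
    segs = gm.cds
    for a, b in zip(segs, segs[1:]):
        if a.end < pos < b.start:
            return True
    return False


def _classify_snv(variant: Variant, gm: GeneModel, reference: Mapping[str, str]) -> ImpactCall:
    pos = variant.pos
    if gm.segment_at(pos) is not None:
        i = gm.cds_index(pos)
        cds = gm.coding_sequence(reference)
        alt_base = variant.alt if gm.strand == "+" else str(Seq(variant.alt).complement())
        codon_i = i // 3
        ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        off = i % 3
        alt_codon = ref_codon[:off] + alt_base.upper() + ref_codon[off + 1 :]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        ppos = codon_i + 1
        change = f"{ref_aa}{ppos}{alt_aa}"
        if codon_i == 0:
            return _call(variant, gm, "start_lost", change, ppos)
        if ref_aa == "*":
            if alt_aa == "*":
                return _call(variant, gm, "synonymous_variant", change, ppos)
            return _call(variant, gm, "stop_lost", change, ppos)
        if alt_aa == "*":
            return _call(variant, gm, "stop_gained", change, ppos)
        if ref_aa == alt_aa:
            return _call(variant, gm, "synonymous_variant", change, ppos)
        return _call(variant, gm, "missense_variant", change, ppos)
    if _near_splice(gm, [pos]):
        return _call(variant, gm, "splice_site_variant")
    if _in_intron(gm, pos):
        return _call(variant, gm, "intron_variant")
    return _call(variant, gm, "utr_variant")


def _classify_indel(variant: Variant, gm: GeneModel, reference: Mapping[str, str]) -> ImpactCall:
    ins_len = max(variant.net_length, 0)
    deleted = list(range(variant.pos + 1, variant.pos + len(variant.ref)))

    # CDS bases removed, and whether the insertion point is intragenic coding
    del_in_cds = [p for p in deleted if gm.segment_at(p) is not None]
    anchor_seg = gm.segment_at(variant.pos)
    ins_in_cds = (
        ins_len > 0
        and anchor_seg is not None
        and gm.segment_at(variant.pos + 1) is anchor_seg
    )

    net_cds = (ins_len if ins_in_cds else 0) - len(del_in_cds)
    if net_cds != 0:
        if del_in_cds:
            first_idx = min(gm.cds_index(p) for p in del_in_cds)
        else:
            # pure insertion: first altered coding base is the one after the
            # later (in coding order) of the two flanking bases
            first_idx = min(gm.cds_index(variant.pos), gm.cds_index(variant.pos + 1)) + 1
        codon = first_idx // 3 + 1
        protein = gm.protein(reference)
        ref_aa = protein[codon - 1] if codon - 1 < len(protein) else "*"
        if net_cds % 3 != 0:
            return _call(variant, gm, "frameshift_variant", f"{ref_aa}{codon}fs", codon)
        effect = "inframe_insertion" if net_cds > 0 else "inframe_deletion"
        return _call(variant, gm, effect, None, codon)

    # No net CDS change: intronic / splice-window / UTR territory.
    probe = deleted if deleted else [variant.pos, variant.pos + 1]
    if _near_splice(gm, probe):
        return _call(variant, gm, "splice_site_variant")
    if any(_in_intron(gm, p) for p in probe):
        return _call(variant, gm, "intron_variant")
    return _call(variant, gm, "utr_variant")


def annotate(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list:
    """Classify one variant against every overlapping transcript.

    Returns one :class:`ImpactCall` per overlapping transcript, or a single
    intergenic call when none overlaps. The REF allele is checked against the
    reference sequence first; a mismatch raises
    :class:`ReferenceMismatchError`.
    """
    seq = reference.get(variant.chrom) if hasattr(reference, "get") else reference[variant.chrom]
    if seq is None:
        raise KeyError(f"chromosome {variant.chrom!r} not in reference")
    observed = seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)].upper()
    if observed != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant}: reference has {observed!r} at this position, not {variant.ref!r}"
        )

    calls = []
    for gm in gene_models:
        if gm.chrom != variant.chrom:
            continue
        lo, hi = gm.span
        if variant.end < lo - SPLICE_WINDOW or variant.pos > hi + SPLICE_WINDOW:
            continue
        if variant.is_snv:
            calls.append(_classify_snv(variant, gm, reference))
        else:
            calls.append(_classify_indel(variant, gm, reference))
    if not calls:
        calls.append(_call(variant, None, "intergenic_variant"))
    return calls


def filter_by_impact(
    calls: Iterable[ImpactCall],
    accepted_classes: frozenset = frozenset({Impact.HIGH, Impact.MODERATE}),
) -> list:
    """Keep variant x gene pairs whose maximal impact is in ``accepted_classes``.

    Calls are deduplicated by (variant, gene), keeping the most severe call;
    the result is sorted by genomic position then gene for determinism.
    """
    best = {}
    for call in calls:
        key = (call.variant, call.gene_id)
        prev = best.get(key)
        if prev is None or call.impact > prev.impact:
            best[key] = call
    kept = [c for c in best.values() if c.impact in accepted_classes]
    kept.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt, c.gene_id or ""))
    return kept
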