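"""Minimal VCF 4.2 text emission for GT-only multi-sample records."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence


def write_vcf(
    path: str,
    contigs: Mapping[str, int],
    samples: Sequence[str],
    rows: Iterable[tuple],
    extra_header: Sequence[str] = (),
) -> None:
    """Write records as VCF 4.2.

    ``rows`` yields ``(chrom, pos, ref, alts, genotypes, info)`` where ``alts``
    is a sequence of ALT alleles, ``genotypes`` one GT string (e.g. "0/1") per
    sample, and ``info`` an INFO string or None.
    """
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.extend(extra_header)
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(samples)
    lines.append("\t".join(header))
    for chrom, pos, ref, alts, genotypes, info in rows:
        row = [
            chrom,
            str(pos),
            ".",
            ref,
            ",".join(alts),
            ".",
            "PASS",
            info if info else ".",
            "GT",
        ]
        row.extend(genotypes)
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
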