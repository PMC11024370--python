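"""A minimal, hashable variant record shared across modules.

Coordinates follow the VCF convention: ``pos`` is 1-based and indels carry an
anchor base (REF and ALT share their first base). All internal interval
arithmetic elsewhere in the package is 0-based half-open; conversion happens at
the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def net_length(self) -> int:
        """Length change introduced by the variant (insertions > 0)."""
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        """Last reference position touched (1-based, inclusive)."""
        return self.pos + len(self.ref) - 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"
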