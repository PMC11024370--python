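"""Self-contained toy datasets for a panel of near-isogenic selfed accessions.

The generator emulates the study design in which a spontaneous mutant is
compared against relatives with almost identical genomes: a toy reference
(single chromosome, ~15% coding), GFF3 gene models (multi-exon, both strands,
intact start/stop codons), a multi-sample GT-only VCF in which each accession
carries Poisson(g * N/2) private fixed homozygous mutations (g generations of
divergence at N new heterozygous mutations per generation, of which half fix
over time), clade-shared variants for accessions with shared post-divergence
ancestry, and one planted causal HIGH/MODERATE variant with known coordinates.

Alongside the sequence data it writes a protein alignment across a land-plant
panel (conserved at the planted residue), a per-gene expression table, and a
JSON truth manifest that records every planted fact — so downstream modules
can be tested end-to-end against known ground truth.

Coordinates on disk are 1-based inclusive (VCF/GFF3); internal arithmetic is
0-based half-open. Indels use the VCF anchor-base convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio.Seq import Seq

from .effect_annotator import CdsSegment, GeneModel
from .variant import Variant
from .vcfio import write_vcf

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
CODONS_NO_STOP = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Comparative land-plant panel used for the toy conservation alignment.
LAND_PLANT_SPECIES = (
    "Arabidopsis_thaliana",
    "Glycine_max",
    "Solanum_lycopersicum",
    "Zea_mays",
    "Sorghum_bicolor",
    "Setaria_italica",
    "Panicum_virgatum",
    "Selaginella_moellendorffii",
    "Physcomitrium_patens",
)

PLANTED_EFFECTS = ("frameshift_insertion", "stop_gained", "missense")

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=n)].tobytes().decode("ascii")



@dataclass(frozen=True)
class AccessionSpec:
    name: str
    role: str  # "mutant" | "comparator"
    generations: int = 50

    def __post_init__(self) -> None:
        if self.role not in ("mutant", "comparator"):
            raise ValueError(f"role must be 'mutant' or 'comparator', got {self.role!r}")
        if self.generations < 1:
            raise ValueError("generations_since_divergence must be >= 1")


@dataclass(frozen=True)
class CladeSpec:
    """Accessions sharing a post-divergence branch of the given length."""

    members: tuple
    generations: int = 25


@dataclass(frozen=True)
class PlantedVariantSpec:
    carriers: tuple
    effect: str = "frameshift_insertion"
    gene_index: Optional[int] = None  # default: the middle gene

    def __post_init__(self) -> None:
        if self.effect not in PLANTED_EFFECTS:
            raise ValueError(f"planted effect must be one of {PLANTED_EFFECTS}")


def _default_accessions() -> tuple:
    mutants = tuple(AccessionSpec(f"mutant_{c}", "mutant") for c in "abc")
    wilds = tuple(AccessionSpec(f"wild_{i}", "comparator") for i in range(1, 5))
    return mutants + wilds


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults give the three-mutant / four-comparator design with two mutants
    sharing a branch that carries the planted causal variant, a 1 Mb genome
    with ~15% coding sequence, and N = 0.09 new heterozygous mutations per
    generation on the toy genome (so each accession fixes Poisson(2.25)
    private variants over its 50 generations of divergence).
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_genes: int = 60
    coding_fraction: float = 0.15
    n_per_generation: float = 0.09
    accessions: tuple = field(default_factory=_default_accessions)
    clades: tuple = field(
        default_factory=lambda: (CladeSpec(members=("mutant_a", "mutant_b")),)
    )
    planted: Optional[PlantedVariantSpec] = field(
        default_factory=lambda: PlantedVariantSpec(carriers=("mutant_a", "mutant_b"))
    )
    het_noise_fraction: float = 0.03
    missing_noise_fraction: float = 0.02
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        names = [a.name for a in self.accessions]
        if len(set(names)) != len(names):
            raise ValueError("accession names must be unique")
        roles = {a.role for a in self.accessions}
        if "mutant" not in roles or "comparator" not in roles:
            raise ValueError("panel needs at least one mutant and one comparator")
        mutants = {a.name for a in self.accessions if a.role == "mutant"}
        if self.planted is not None:
            missing = set(self.planted.carriers) - mutants
            if missing:
                raise ValueError(f"planted carriers must be mutants: {sorted(missing)}")
            if self.planted.gene_index is not None and not (
                0 <= self.planted.gene_index < self.n_genes
            ):
                raise ValueError("planted gene index out of range")
        for clade in self.clades:
            unknown = set(clade.members) - set(names)
            if unknown:
                raise ValueError(f"clade members not in panel: {sorted(unknown)}")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding_fraction must lie in [0, 1]")
        if self.n_per_generation < 0:
            raise ValueError("n_per_generation must be >= 0")

    @property
    def sample_names(self) -> list:
        return [a.name for a in self.accessions]

    @classmethod
    def from_dict(cls, data: Mapping) -> "PanelConfig":
        data = dict(data)
        if "accessions" in data:
            data["accessions"] = tuple(AccessionSpec(**a) for a in data["accessions"])
        if "clades" in data:
            data["clades"] = tuple(
                CladeSpec(members=tuple(c["members"]), generations=c.get("generations", 25))
                for c in data["clades"]
            )
        if data.get("planted") is not None:
            p = dict(data["planted"])
            p["carriers"] = tuple(p["carriers"])
            data["planted"] = PlantedVariantSpec(**p)
        return cls(**data)


@dataclass
class Reference:
    chrom: str
    sequence: str
    genes: list

    @property
    def coding_length(self) -> int:
        return sum(g.cds_length for g in self.genes)

    def as_mapping(self) -> dict:
        return {self.chrom: self.sequence}


# ---------------------------------------------------------------------------
# reference construction


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(CODONS_NO_STOP), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(CODONS_NO_STOP[i] for i in body) + stop


def _split_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list:
    """Random composition of ``total`` into ``parts`` pieces of >= minimum."""
    free = total - parts * minimum
    if free < 0:
        raise ValueError("cannot split")
    cuts = np.sort(rng.integers(0, free + 1, size=parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [free])))
    return [int(p) + minimum for p in pieces]


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    n_codons: int,
    strand: str,
) -> tuple:
    """Construct one multi-exon gene; returns (GeneModel, genomic sequence)."""
    cds = _random_cds(rng, n_codons)
    n_exons = int(rng.integers(2, 5))
    exon_lengths = _split_lengths(rng, len(cds), n_exons, minimum=30)
    intron_lengths = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]

    # pre-mRNA in transcript orientation: exon1 intron1 exon2 ...
    pieces = []
    offset = 0
    for i, elen in enumerate(exon_lengths):
        pieces.append(cds[offset : offset + elen])
        offset += elen
        if i < n_exons - 1:
            ilen = intron_lengths[i]
            intron = _rand_seq(rng, ilen)
            intron = "GT" + intron[2:-2] + "AG"
            pieces.append(intron)
    transcript = "".join(pieces)

    genomic = transcript if strand == "+" else str(Seq(transcript).reverse_complement())

    # CDS segments in genomic coordinates; phase follows translation order
    phases = []
    cum = 0
    for elen in exon_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += elen
    segments = []
    if strand == "+":
        cursor = start
        for i, elen in enumerate(exon_lengths):
            segments.append(CdsSegment(cursor, cursor + elen - 1, phases[i]))
            cursor += elen
            if i < n_exons - 1:
                cursor += intron_lengths[i]
    else:
        end = start + len(transcript) - 1
        cursor = end
        for i, elen in enumerate(exon_lengths):
            segments.append(CdsSegment(cursor - elen + 1, cursor, phases[i]))
            cursor -= elen
            if i < n_exons - 1:
                cursor -= intron_lengths[i]
        segments.sort(key=lambda s: s.start)

    model = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        cds=tuple(segments),
    )
    return model, genomic


def generate_reference(config: PanelConfig) -> Reference:
    """Build the toy reference: random background plus non-overlapping genes."""
    rng = np.random.default_rng([config.seed, 0])
    L = config.genome_length

    if config.n_genes == 0:
        seq = _rand_seq(rng, L)
        return Reference(chrom=config.chrom, sequence=seq, genes=[])

    mean_codons = config.coding_fraction * L / (3 * config.n_genes)
    if mean_codons < 60:
        raise ValueError(
            f"{config.n_genes} genes infeasible for genome_length {L} at "
            f"coding_fraction {config.coding_fraction}"
        )
    n_codons = np.maximum(
        60, np.round(rng.normal(mean_codons, 0.12 * mean_codons, size=config.n_genes))
    ).astype(int)

    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    if len(set(strands.tolist())) == 1:  # both strands must be represented
        strands[-1] = "+" if strands[0] == "-" else "-"

    # build genes first so footprints are known, then distribute the gaps
    built = []
    for i in range(config.n_genes):
        model, genomic = _build_gene(
            rng, f"gene_{i:04d}", config.chrom, start=1, n_codons=int(n_codons[i]),
            strand=str(strands[i]),
        )
        built.append((model, genomic))
    footprint = sum(len(g) for _, g in built)
    spare = L - footprint
    min_gap = 50
    if spare < (config.n_genes + 1) * min_gap:
        raise ValueError(
            f"{config.n_genes} genes infeasible for genome_length {L}: "
            f"gene footprint {footprint} bp leaves no room for intergenic spacers"
        )
    gaps = _split_lengths(rng, spare, config.n_genes + 1, minimum=min_gap)

    parts = []
    genes = []
    cursor = 1  # 1-based
    for i, (model, genomic) in enumerate(built):
        gap = gaps[i]
        parts.append(_rand_seq(rng, gap))
        cursor += gap
        shift = cursor - 1
        shifted = GeneModel(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            chrom=model.chrom,
            strand=model.strand,
            cds=tuple(
                CdsSegment(s.start + shift, s.end + shift, s.phase) for s in model.cds
            ),
        )
        parts.append(genomic)
        cursor += len(genomic)
        genes.append(shifted)
    parts.append(_rand_seq(rng, gaps[-1]))

    sequence = "".join(parts)
    assert len(sequence) == L
    return Reference(chrom=config.chrom, sequence=sequence, genes=genes)


def write_reference(reference: Reference, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{reference.chrom}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")

    gff = outdir / "genes.gff3"
    lines = ["##gff-version 3"]
    for gm in reference.genes:
        lo, hi = gm.span
        c = reference.chrom
        lines.append(
            f"{c}\tselfscan\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gm.gene_id}"
        )
        lines.append(
            f"{c}\tselfscan\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
            f"ID={gm.transcript_id};Parent={gm.gene_id}"
        )
        for k, seg in enumerate(gm.cds):
            lines.append(
                f"{c}\tselfscan\tCDS\t{seg.start}\t{seg.end}\t.\t{gm.strand}\t{seg.phase}\t"
                f"ID={gm.transcript_id}.cds{k};Parent={gm.transcript_id}"
            )
    with open(gff, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"fasta": fasta, "gff3": gff}


# ---------------------------------------------------------------------------
# planted causal variant construction


def _complement(base: str) -> str:
    return str(Seq(base).complement())


def _plant_frameshift(rng, gm: GeneModel, seq: str) -> dict:
    mid = gm.cds_length // 2
    pos = gm.genomic_position(mid)
    seg = gm.segment_at(pos)
    if pos == seg.end:  # need pos and pos+1 inside the same segment
        pos -= 1
    ins = _rand_seq(rng, 4)
    ref = seq[pos - 1]
    first = min(gm.cds_index(pos), gm.cds_index(pos + 1)) + 1
    codon = first // 3 + 1
    return {
        "pos": pos,
        "ref": ref,
        "alt": ref + ins,
        "effect": "frameshift_variant",
        "impact": "HIGH",
        "protein_pos": codon,
        "protein_change": None,
    }


def _plant_stop_gained(rng, gm: GeneModel, seq: str, cds: str) -> dict:
    n_codons = len(cds) // 3
    for ci in rng.permutation(np.arange(2, n_codons - 1)):
        codon = cds[ci * 3 : ci * 3 + 3]
        for stop in STOP_CODONS:
            mismatches = [o for o in range(3) if codon[o] != stop[o]]
            if len(mismatches) == 1:
                o = mismatches[0]
                idx = int(ci) * 3 + o
                pos = gm.genomic_position(idx)
                alt_coding = stop[o]
                alt = alt_coding if gm.strand == "+" else _complement(alt_coding)
                aa = str(Seq(codon).translate())
                return {
                    "pos": pos,
                    "ref": seq[pos - 1],
                    "alt": alt,
                    "effect": "stop_gained",
                    "impact": "HIGH",
                    "protein_pos": int(ci) + 1,
                    "protein_change": f"{aa}{int(ci) + 1}*",
                }
    raise RuntimeError("no codon one substitution away from a stop codon")


def _plant_missense(rng, gm: GeneModel, seq: str, cds: str) -> dict:
    n_codons = len(cds) // 3
    for ci in rng.permutation(np.arange(2, n_codons - 1)):
        codon = cds[ci * 3 : ci * 3 + 3]
        aa = str(Seq(codon).translate())
        for o in rng.permutation(3):
            for base in BASES:
                if base == codon[o]:
                    continue
                alt_codon = codon[:o] + base + codon[o + 1 :]
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa != aa and alt_aa != "*":
                    idx = int(ci) * 3 + int(o)
                    pos = gm.genomic_position(idx)
                    alt = base if gm.strand == "+" else _complement(base)
                    return {
                        "pos": pos,
                        "ref": seq[pos - 1],
                        "alt": alt,
                        "effect": "missense_variant",
                        "impact": "MODERATE",
                        "protein_pos": int(ci) + 1,
                        "protein_change": f"{aa}{int(ci) + 1}{alt_aa}",
                    }
    raise RuntimeError("no missense substitution found")


def _make_planted(rng, config: PanelConfig, reference: Reference) -> dict:
    spec = config.planted
    idx = spec.gene_index if spec.gene_index is not None else len(reference.genes) // 2
    if not 0 <= idx < len(reference.genes):
        raise ValueError(f"planted gene index {idx} out of range")
    gm = reference.genes[idx]
    cds = gm.coding_sequence(reference.as_mapping())
    if spec.effect == "frameshift_insertion":
        info = _plant_frameshift(rng, gm, reference.sequence)
    elif spec.effect == "stop_gained":
        info = _plant_stop_gained(rng, gm, reference.sequence, cds)
    else:
        info = _plant_missense(rng, gm, reference.sequence, cds)
    info.update(
        {
            "chrom": reference.chrom,
            "gene_id": gm.gene_id,
            "gene_index": idx,
            "carriers": list(spec.carriers),
        }
    )
    return info


# ---------------------------------------------------------------------------
# panel construction


def generate_panel(
    config: PanelConfig, reference: Reference, seed: Optional[int] = None
) -> dict:
    """Draw the panel's fixed variants and assemble VCF rows plus the manifest.

    Each accession receives Poisson(g * N/2) private homozygous SNVs at
    uniform positions; each clade receives the same for its shared branch; the
    planted causal variant is set homozygous-alt in its carriers. A configured
    fraction of background sites is then perturbed to heterozygous or missing
    in one random accession to exercise downstream filters (the planted
    variant is never perturbed).
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    samples = config.sample_names
    L = config.genome_length
    seq = reference.sequence

    used = set()
    planted = None
    if config.planted is not None:
        planted = _make_planted(rng, config, reference)
        for p in range(planted["pos"] - 6, planted["pos"] + 7):
            used.add(p)

    def draw_snvs(count: int) -> list:
        out = []
        for _ in range(count):
            while True:
                pos = int(rng.integers(1, L + 1))
                if pos not in used:
                    used.add(pos)
                    break
            ref = seq[pos - 1]
            alt = rng.permutation([b for b in BASES if b != ref])[0]
            out.append({"pos": pos, "ref": ref, "alt": str(alt)})
        return out

    lam = lambda g: g * config.n_per_generation / 2.0

    records = []  # {pos, ref, alt, genotypes: {name: gt}, origin}
    manifest_accessions = {}
    for acc in config.accessions:
        n = int(rng.poisson(lam(acc.generations)))
        variants = draw_snvs(n)
        manifest_accessions[acc.name] = {
            "role": acc.role,
            "generations": acc.generations,
            "private": variants,
        }
        for v in variants:
            gts = {s: "1/1" if s == acc.name else "0/0" for s in samples}
            records.append({**v, "genotypes": gts, "origin": f"private:{acc.name}"})

    manifest_clades = []
    for ci, clade in enumerate(config.clades):
        n = int(rng.poisson(lam(clade.generations)))
        variants = draw_snvs(n)
        manifest_clades.append(
            {
                "members": list(clade.members),
                "generations": clade.generations,
                "variants": variants,
            }
        )
        for v in variants:
            gts = {s: "1/1" if s in clade.members else "0/0" for s in samples}
            records.append({**v, "genotypes": gts, "origin": f"clade:{ci}"})

    if planted is not None:
        gts = {s: "1/1" if s in planted["carriers"] else "0/0" for s in samples}
        records.append(
            {
                "pos": planted["pos"],
                "ref": planted["ref"],
                "alt": planted["alt"],
                "genotypes": gts,
                "origin": "planted",
            }
        )

    noise = []
    for rec in records:
        if rec["origin"] == "planted":
            continue
        u = rng.random()
        if u < config.het_noise_fraction + config.missing_noise_fraction:
            target = samples[int(rng.integers(len(samples)))]
            gt = "0/1" if u < config.het_noise_fraction else "./."
            rec["genotypes"][target] = gt
            noise.append({"pos": rec["pos"], "accession": target, "genotype": gt})

    records.sort(key=lambda r: r["pos"])

    manifest = {
        "reference": {
            "chrom": reference.chrom,
            "length": L,
            "n_genes": len(reference.genes),
            "coding_length": reference.coding_length,
        },
        "samples": samples,
        "planted": planted,
        "accessions": manifest_accessions,
        "clades": manifest_clades,
        "noise": noise,
        "n_records": len(records),
    }
    return {"records": records, "manifest": manifest}


# ---------------------------------------------------------------------------
# companion evidence files


def _planted_or_middle_gene(config: PanelConfig, reference: Reference, manifest: dict):
    if manifest["planted"] is not None:
        return reference.genes[manifest["planted"]["gene_index"]], manifest["planted"]
    return reference.genes[len(reference.genes) // 2], None


def build_alignment(
    config: PanelConfig, reference: Reference, manifest: dict
) -> list:
    """Toy land-plant protein alignment for the planted gene.

    The reference protein is ungapped; each comparative species carries random
    substitutions (and occasional gaps) except at the planted residue, which
    is kept identical across the panel — a strongly conserved column.
    """
    rng = np.random.default_rng([config.seed, 2])
    gene, planted = _planted_or_middle_gene(config, reference, manifest)
    protein = gene.protein(reference.as_mapping()).rstrip("*")
    conserved = set()
    if planted is not None and planted.get("protein_pos"):
        p = planted["protein_pos"]
        conserved.update(range(max(1, p - 1), min(len(protein), p + 1) + 1))

    entries = [(gene.gene_id, protein)]
    for species in LAND_PLANT_SPECIES:
        residues = []
        for col, aa in enumerate(protein, start=1):
            if col in conserved:
                residues.append(aa)
                continue
            u = rng.random()
            if u < 0.03:
                residues.append("-")
            elif u < 0.20:
                residues.append(AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
            else:
                residues.append(aa)
        entries.append((species, "".join(residues)))
    return entries


def build_expression(config: PanelConfig, reference: Reference, manifest: dict) -> list:
    """Per-gene expression evidence; the planted gene is always flagged."""
    rng = np.random.default_rng([config.seed, 3])
    planted_gene = (
        manifest["planted"]["gene_id"] if manifest["planted"] is not None else None
    )
    rows = []
    for gm in reference.genes:
        if gm.gene_id == planted_gene:
            flag = 1
        else:
            flag = int(rng.random() < 0.3)
        value = float(np.round(rng.lognormal(mean=2.0, sigma=1.0), 3))
        rows.append((gm.gene_id, flag, value))
    return rows


# ---------------------------------------------------------------------------
# top-level emission


def generate_dataset(config: PanelConfig, outdir) -> dict:
    """Generate and write the full dataset; returns paths and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = generate_reference(config)
    paths = write_reference(reference, outdir)

    panel = generate_panel(config, reference)
    manifest = panel["manifest"]

    vcf_path = outdir / "panel.vcf"
    rows = (
        (
            config.chrom,
            r["pos"],
            r["ref"],
            [r["alt"]],
            [r["genotypes"][s] for s in config.sample_names],
            None,
        )
        for r in panel["records"]
    )
    write_vcf(
        str(vcf_path),
        contigs={config.chrom: config.genome_length},
        samples=config.sample_names,
        rows=rows,
    )
    paths["vcf"] = vcf_path

    if reference.genes:
        aln_path = outdir / "alignment.faa"
        with open(aln_path, "w") as fh:
            for name, aligned in build_alignment(config, reference, manifest):
                fh.write(f">{name}\n{aligned}\n")
        paths["alignment"] = aln_path

        expr_path = outdir / "expression.tsv"
        with open(expr_path, "w") as fh:
            fh.write("gene_id\ttissue_flag\tvalue\n")
            for gene_id, flag, value in build_expression(config, reference, manifest):
                fh.write(f"{gene_id}\t{flag}\t{value}\n")
        paths["expression"] = expr_path

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path

    return {"paths": paths, "manifest": manifest, "reference": reference}


def planted_variant(manifest: Mapping) -> Optional[Variant]:
    """The planted causal variant of a manifest as a :class:`Variant`."""
    p = manifest.get("planted")
    if p is None:
        return None
    return Variant(chrom=p["chrom"], pos=p["pos"], ref=p["ref"], alt=p["alt"])
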