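"""End-to-end orchestration: compare -> annotate -> filter -> prioritize.

Given a multi-sample VCF, reference FASTA, GFF3 gene models and an accession
partition (targets vs comparators), the pipeline extracts target-specific
homozygous polymorphisms, classifies their impact, keeps HIGH/MODERATE
candidates and ranks them with conservation and expression evidence. Every
intermediate is written to the output directory together with a run manifest
(package version, seed, config hash) so a run is reproducible from its
directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import pyfaidx
import yaml

from . import __version__
from .effect_annotator import annotate, filter_by_impact, load_gene_models
from .prioritizer import (
    ConservationProfile,
    Weights,
    rank_candidates,
    read_expression_table,
)
from .variant import Variant
from .vcf_compare import load_matrix, target_specific

logger = logging.getLogger("selfscan")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    vcf: str
    fasta: str
    gff3: str
    targets: list
    comparators: list
    outdir: str = "selfscan_out"
    alignments: list = field(default_factory=list)  # aligned FASTA per gene
    expression: Optional[str] = None
    truth: Optional[str] = None  # synthetic truth manifest, marks is_planted
    weights: Weights = field(default_factory=Weights)
    reference_length: Optional[int] = None  # default: sum of FASTA lengths
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "weights" in data:
            data["weights"] = Weights(**data["weights"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return inner

    return wrap


def _load_reference(fasta_path: str) -> dict:
    fasta = pyfaidx.Fasta(str(fasta_path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and return the ranked candidate report.

    Writes ``specific_variants.vcf``, ``annotations.tsv``, ``candidates.tsv``,
    ``report.tsv`` and ``run_manifest.json`` under ``config.outdir``. An empty
    candidate set is a warning, not an error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = _stage("load_reference")(_load_reference)(config.fasta)
    ref_length = config.reference_length or sum(len(s) for s in reference.values())

    matrix = _stage("load_matrix")(load_matrix)(config.vcf, ref_length)
    unknown = (set(config.targets) | set(config.comparators)) - set(matrix.samples)
    if unknown:
        raise PipelineError(f"stage 'partition': accessions not in VCF header: {sorted(unknown)}")

    selection = _stage("target_specific")(target_specific)(
        matrix, config.targets, config.comparators
    )
    selection.write_vcf(str(outdir / "specific_variants.vcf"))
    logger.info("target-specific variants: %d", len(selection))

    gene_models = _stage("load_gene_models")(load_gene_models)(config.gff3)

    @_stage("annotate")
    def _annotate_all():
        calls = []
        for rec in selection.records:
            calls.extend(annotate(rec, gene_models, reference))
        return calls

    calls = _annotate_all()
    ann = pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "gene": c.gene_id,
                "transcript": c.transcript_id,
                "effect": c.effect,
                "impact": c.impact.name,
                "protein_change": c.protein_change,
            }
            for c in calls
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "transcript", "effect",
                 "impact", "protein_change"],
    )
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    candidates = _stage("filter_by_impact")(filter_by_impact)(calls)
    if not candidates:
        logger.warning("no HIGH/MODERATE candidate remains after filtering")
    pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "gene": c.gene_id,
                "effect": c.effect,
                "impact": c.impact.name,
            }
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "effect", "impact"],
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    @_stage("evidence")
    def _load_evidence():
        profiles = {}
        for path in config.alignments:
            profile = ConservationProfile.from_fasta(path)
            profiles[profile.reference_id] = profile
        expression = read_expression_table(config.expression) if config.expression else {}
        return profiles, expression

    profiles, expression = _load_evidence()

    planted = None
    if config.truth:
        with open(config.truth) as fh:
            manifest = json.load(fh)
        p = manifest.get("planted")
        if p:
            planted = Variant(p["chrom"], p["pos"], p["ref"], p["alt"])

    report = _stage("prioritize")(rank_candidates)(
        candidates, profiles, expression, config.weights, planted
    )
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)

    manifest_out = {
        "selfscan_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_variants": len(matrix),
        "n_target_specific": len(selection),
        "n_candidates": len(candidates),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
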