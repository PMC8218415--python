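"""End-to-end pipeline: call -> quantify -> concordance -> export.

Configuration is a YAML/JSON-serializable dataclass; every run writes a
machine-readable manifest (tool version, config hash, per-stage counts)
next to its outputs so results are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .amplicon_model import LocusMap, read_bed_panel, read_fasta, build_locus_map, write_locus_map_tsv
from .read_calling import AssayType, CallingParams, build_call_matrix, read_matrix_tsv, write_matrix_tsv
from .site_quant import noncpg_conversion_qc, site_table
from .concordance import (
    export_read_profiles,
    or_matrix,
    or_vs_distance,
    write_or_matrix_tsv,
    write_pairwise_tsv,
    DEFAULT_MIN_INFORMATIVE,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "ConfigError", "DataError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 3)."""


@dataclass
class PipelineConfig:
    panel: str
    reference: str
    out_dir: str
    alignments: str | None = None
    matrix: str | None = None
    assay: str = "BS"
    min_base_quality: int = 30
    min_mapping_quality: int = 0
    mate_overlap_policy: str = "consensus_or_N"
    ci_level: float = 0.95
    ci_method: str = "clopper-pearson"
    or_correction: str = "none"
    min_reads_per_pair: int = DEFAULT_MIN_INFORMATIVE
    run_conversion_qc: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from None

    def validate(self) -> None:
        if self.assay not in ("BS", "PB"):
            raise ConfigError(f"assay must be BS or PB, got {self.assay!r}")
        if (self.alignments is None) == (self.matrix is None):
            raise ConfigError("exactly one of 'alignments' or 'matrix' must be set")
        for label, path in (("panel", self.panel), ("reference", self.reference),
                            ("alignments", self.alignments), ("matrix", self.matrix)):
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{label} file not found: {path}")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    started: float
    finished: float | None = None
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run call -> quantify -> concordance -> export for every amplicon.

    Writes, per amplicon: the call-matrix TSV, the per-site proportion
    table, the pairwise OR table, the OR matrix, the OR-vs-distance
    table, and the per-read M/U/N profiles; plus a locus map, optional
    conversion QC, and the run manifest.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__, config_hash=config.digest(), started=time.time()
    )
    assay = AssayType(config.assay)
    params = CallingParams(
        min_base_quality=config.min_base_quality,
        min_mapping_quality=config.min_mapping_quality,
        mate_overlap_policy=config.mate_overlap_policy,
    )

    panel = read_bed_panel(config.panel)
    reference = read_fasta(config.reference)
    locus = build_locus_map(panel, reference)
    write_locus_map_tsv(locus, os.path.join(config.out_dir, "locus_map.tsv"))
    manifest.record("locus_map", n_amplicons=len(panel), n_cpgs=locus.n_sites)
    logger.info("locus map: %d amplicons, %d CpGs", len(panel), locus.n_sites)

    matrices = {}
    if config.matrix is not None:
        mat = read_matrix_tsv(config.matrix, assay=assay)
        # map header indices onto the locus's sites when they agree
        by_index = {s.global_index: s for s in locus.sites}
        if all(s.global_index in by_index for s in mat.sites):
            mat.sites = [by_index[s.global_index] for s in mat.sites]
        name = mat.sites[0].amplicon if mat.sites else "matrix"
        matrices[name] = mat
        manifest.record("call", source="matrix_tsv", n_reads=mat.n_reads)
    else:
        total_in = total_dropped = 0
        for amp in panel:
            try:
                mat = build_call_matrix(config.alignments, amp, locus, assay, params)
            except ValueError as e:
                raise DataError(f"stage call, amplicon {amp.name!r}: {e}") from e
            matrices[amp.name] = mat
            total_in += mat.metadata["n_input_fragments"]
            total_dropped += mat.metadata["n_dropped_all_n"] + mat.metadata["n_skipped_mapq"]
        manifest.record(
            "call",
            source="alignments",
            n_input_fragments=total_in,
            n_dropped=total_dropped,
            n_retained=sum(m.n_reads for m in matrices.values()),
        )

    for name, mat in matrices.items():
        prefix = os.path.join(config.out_dir, name)
        write_matrix_tsv(mat, f"{prefix}.calls.tsv")
        manifest.outputs.append(f"{name}.calls.tsv")

        table = site_table(mat, level=config.ci_level, method=config.ci_method)
        table.to_csv(f"{prefix}.sites.tsv", sep="\t", index=False, na_rep="NA")
        manifest.outputs.append(f"{name}.sites.tsv")

        if mat.n_sites >= 2 and mat.n_reads > 0:
            orm = or_matrix(mat, correction=config.or_correction,
                            min_informative=config.min_reads_per_pair)
            write_pairwise_tsv(orm, f"{prefix}.pairs.tsv")
            write_or_matrix_tsv(orm, f"{prefix}.or_matrix.tsv")
            dist = or_vs_distance(orm)
            dist.to_csv(f"{prefix}.or_vs_distance.tsv", sep="\t", index=False)
            manifest.outputs += [f"{name}.pairs.tsv", f"{name}.or_matrix.tsv",
                                 f"{name}.or_vs_distance.tsv"]
            manifest.record(
                f"concord:{name}",
                n_pairs=len(orm.results),
                n_informative_pairs=sum(
                    1 for r in orm.results.values() if not r.missing
                ),
            )
        with open(f"{prefix}.profiles.tsv", "w") as fh:
            fh.write("read_id\tprofile\n")
            for rid, prof in zip(mat.read_ids, export_read_profiles(mat)):
                fh.write(f"{rid}\t{prof}\n")
        manifest.outputs.append(f"{name}.profiles.tsv")

    if config.run_conversion_qc and config.alignments is not None and assay == AssayType.BS:
        qc_rows = []
        for amp in panel:
            try:
                qc = noncpg_conversion_qc(config.alignments, amp, reference, params, assay)
            except ValueError:
                continue
            qc_rows.append((amp.name, qc.n_converted, qc.n_unconverted, qc.efficiency))
        if qc_rows:
            with open(os.path.join(config.out_dir, "conversion_qc.tsv"), "w") as fh:
                fh.write("amplicon\tn_converted\tn_unconverted\tefficiency\n")
                for row in qc_rows:
                    fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]:.6g}\n")
            manifest.outputs.append("conversion_qc.tsv")
            manifest.record("qc", n_amplicons=len(qc_rows))

    manifest.finished = time.time()
    manifest.write(os.path.join(config.out_dir, "manifest.json"))
    return manifest
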