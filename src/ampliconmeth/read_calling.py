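"""Convert aligned BS-seq / PB-seq reads into per-read x per-CpG call matrices.

A call matrix has one row per sequenced fragment and one column per CpG of
an amplicon. Cells hold raw calls:

* ``C`` — the analysed cytosine read as C (protected from conversion),
* ``T`` — read as T (converted),
* ``N`` — uninformative: any other base, a deletion, a base below the
  quality threshold, a site the read does not cover, or a read whose
  conversion strand is the opposite strand.

For BS-seq, C means 5mC/5hmC and T means unmodified C/5fC/5caC; for
PB-seq (pyridine borane / TAPS-style chemistry), C means C/5mC/5hmC and
T means 5fC/5caC. The matrix itself is chemistry-agnostic; the assay tag
is carried along so quantification can apply the right semantics.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .amplicon_model import AmpliconDef, CpGSite, LocusMap

__all__ = [
    "AssayType",
    "CallingParams",
    "ReadCallMatrix",
    "call_read",
    "build_call_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

logger = logging.getLogger(__name__)

CALLS = ("C", "T", "N")


class AssayType(str, Enum):
    BS = "BS"
    PB = "PB"


@dataclass
class CallingParams:
    """Thresholds and policies for read-to-call conversion.

    ``mate_overlap_policy``: how overlapping mate pairs are merged —
    ``consensus_or_N`` counts agreeing calls once and turns disagreements
    into N (never double-counts a fragment); ``first_mate`` takes the
    first mate's call wherever it is informative.

    ``conversion_strand_source``: where the converted strand of a read is
    read from — ``tag`` (mapper tags ZS/XG), ``flag`` (SAM orientation
    flags), or ``config`` (``default_conversion_strand`` applies to all
    reads). The automatic default tries tag, then flag.
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 0
    mate_overlap_policy: str = "consensus_or_N"
    conversion_strand_source: str = "auto"
    default_conversion_strand: str = "+"

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.mate_overlap_policy not in ("first_mate", "consensus_or_N"):
            raise ValueError(f"unknown mate_overlap_policy {self.mate_overlap_policy!r}")
        if self.conversion_strand_source not in ("auto", "tag", "flag", "config"):
            raise ValueError(
                f"unknown conversion_strand_source {self.conversion_strand_source!r}"
            )


@dataclass
class ReadCallMatrix:
    """Per-read x per-CpG raw calls for one amplicon.

    ``calls`` is an (n_reads, n_sites) array of single characters in
    {C, T, N}; column order follows ``sites`` (ascending global index).
    """

    assay: AssayType
    sites: list[CpGSite]
    calls: np.ndarray
    read_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.ndim != 2:
            self.calls = self.calls.reshape(-1, len(self.sites))
        if self.calls.shape[1] != len(self.sites):
            raise ValueError(
                f"call matrix has {self.calls.shape[1]} columns for {len(self.sites)} sites"
            )
        bad = set(np.unique(self.calls)) - set(CALLS)
        if bad:
            raise ValueError(f"invalid call symbols {sorted(bad)}; expected C/T/N")
        if len(self.read_ids) != self.calls.shape[0]:
            raise ValueError("read_ids length does not match number of rows")

    @property
    def n_reads(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def column(self, site_index: int) -> np.ndarray:
        return self.calls[:, site_index]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadCallMatrix):
            return NotImplemented
        return (
            self.assay == other.assay
            and [s.pos for s in self.sites] == [s.pos for s in other.sites]
            and self.calls.shape == other.calls.shape
            and bool((self.calls == other.calls).all())
        )


def _strand_from_tags(read: pysam.AlignedSegment) -> str | None:
    # BSMAP writes ZS (++/+-/-+/--, first char = converted strand);
    # Bismark-style mappers write XG (CT = top, GA = bottom).
    if read.has_tag("ZS"):
        zs = str(read.get_tag("ZS"))
        return "+" if zs.startswith("+") else "-"
    if read.has_tag("XG"):
        return "+" if str(read.get_tag("XG")) == "CT" else "-"
    return None


def _strand_from_flags(read: pysam.AlignedSegment) -> str:
    # Directional protocol: R1 orientation gives the converted strand.
    if read.is_paired and read.is_read2:
        return "-" if read.is_reverse else "+"
    return "-" if read.is_reverse else "+"


def conversion_strand(read: pysam.AlignedSegment, params: CallingParams) -> str:
    """Determine which genomic strand a read reports conversion for."""
    src = params.conversion_strand_source
    if src == "config":
        return params.default_conversion_strand
    if src in ("auto", "tag"):
        tagged = _strand_from_tags(read)
        if tagged is not None:
            return tagged
        if src == "tag":
            return params.default_conversion_strand
    return _strand_from_flags(read)


def call_read(
    read: pysam.AlignedSegment,
    sites: Sequence[CpGSite],
    assay: AssayType,
    params: CallingParams,
    analysed_strand: str = "+",
) -> list[str]:
    """Call C/T/N at each CpG site for one aligned read.

    Reads converted on the opposite strand of the analysed cytosines
    carry no direct evidence about them and yield N everywhere. Bases
    other than C/T (sequencing errors, deletions) and bases below the
    quality threshold also yield N.
    """
    n = len(sites)
    if read.is_unmapped:
        raise ValueError(f"read {read.query_name!r} is unmapped")
    if conversion_strand(read, params) != analysed_strand:
        return ["N"] * n

    seq = read.query_sequence
    quals = read.query_qualities
    pos_to_query = {
        ref: q for q, ref in read.get_aligned_pairs(matches_only=True) if ref is not None
    }
    calls = []
    for site in sites:
        q = pos_to_query.get(site.pos)
        if q is None or seq is None:
            calls.append("N")
            continue
        if quals is not None and quals[q] < params.min_base_quality:
            calls.append("N")
            continue
        base = seq[q].upper()
        if analysed_strand == "-":
            # bottom-strand cytosine appears as G (protected) / A (converted)
            # in top-strand reference coordinates
            base = {"G": "C", "A": "T"}.get(base, "N")
        calls.append(base if base in ("C", "T") else "N")
    return calls


def _merge_mate_calls(rows: list[list[str]], policy: str) -> list[str]:
    if len(rows) == 1:
        return rows[0]
    merged = []
    for cells in zip(*rows):
        informative = [c for c in cells if c != "N"]
        if not informative:
            merged.append("N")
        elif policy == "first_mate":
            merged.append(informative[0])
        else:  # consensus_or_N
            merged.append(informative[0] if len(set(informative)) == 1 else "N")
    return merged


def _iter_alignments(alignments, amplicon: AmpliconDef) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str,)):
        mode = "rb" if str(alignments).endswith(".bam") else "r"
        with pysam.AlignmentFile(alignments, mode) as af:
            if af.has_index():
                yield from af.fetch(amplicon.chrom, amplicon.start, amplicon.end)
            else:
                for read in af:
                    if read.is_unmapped:
                        continue
                    if (
                        read.reference_name == amplicon.chrom
                        and read.reference_start < amplicon.end
                        and read.reference_end is not None
                        and read.reference_end > amplicon.start
                    ):
                        yield read
    else:
        yield from alignments


def build_call_matrix(
    alignments,
    amplicon: AmpliconDef,
    locus: LocusMap,
    assay: AssayType,
    params: CallingParams | None = None,
    metadata: dict | None = None,
) -> ReadCallMatrix:
    """Build the per-read call matrix for one amplicon.

    ``alignments`` may be a SAM/BAM path or an iterable of mapped
    pysam records. Mate pairs are merged into one fragment row per
    ``params.mate_overlap_policy``; all-N rows are dropped (and counted
    in ``metadata['n_dropped_all_n']``).
    """
    params = params or CallingParams()
    sites = locus.sites_of(amplicon.name)
    if not sites:
        raise ValueError(f"amplicon {amplicon.name!r} has no CpG sites in the locus map")

    per_fragment: dict[str, list[list[str]]] = {}
    order: list[str] = []
    n_skipped_mapq = 0
    chrom_names = set()
    for read in _iter_alignments(alignments, amplicon):
        chrom_names.add(read.reference_name)
        if read.reference_name != amplicon.chrom:
            raise ValueError(
                f"chromosome mismatch: alignments use {sorted(chrom_names)}, "
                f"panel uses {amplicon.chrom!r}"
            )
        if read.mapping_quality < params.min_mapping_quality:
            n_skipped_mapq += 1
            continue
        row = call_read(read, sites, assay, params, analysed_strand=amplicon.strand)
        name = read.query_name or f"read_{len(order)}"
        if name not in per_fragment:
            per_fragment[name] = []
            order.append(name)
        per_fragment[name].append(row)

    rows: list[list[str]] = []
    ids: list[str] = []
    n_all_n = 0
    for name in order:
        merged = _merge_mate_calls(per_fragment[name], params.mate_overlap_policy)
        if all(c == "N" for c in merged):
            n_all_n += 1
            continue
        rows.append(merged)
        ids.append(name)

    if n_skipped_mapq or n_all_n:
        logger.info(
            "%s: skipped %d reads below mapq %d, dropped %d all-N fragments",
            amplicon.name, n_skipped_mapq, params.min_mapping_quality, n_all_n,
        )
    meta = dict(metadata or {})
    meta.update(
        amplicon=amplicon.name,
        n_input_fragments=len(order),
        n_skipped_mapq=n_skipped_mapq,
        n_dropped_all_n=n_all_n,
    )
    calls = (
        np.array(rows, dtype="<U1")
        if rows
        else np.empty((0, len(sites)), dtype="<U1")
    )
    return ReadCallMatrix(assay=assay, sites=sites, calls=calls, read_ids=ids, metadata=meta)


def write_matrix_tsv(matrix: ReadCallMatrix, path: str) -> None:
    """Write a call matrix as TSV: read_id, then one column per CpG
    (headed by the global index)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id"] + [str(s.global_index) for s in matrix.sites])
        for rid, row in zip(matrix.read_ids, matrix.calls):
            writer.writerow([rid] + list(row))


def read_matrix_tsv(
    path: str,
    assay: AssayType = AssayType.BS,
    sites: Sequence[CpGSite] | None = None,
) -> ReadCallMatrix:
    """Read a call matrix from TSV (inverse of :func:`write_matrix_tsv`).

    If ``sites`` is not given, placeholder sites are created from the
    header's global indices (positions unknown, set to the index).
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (expected a header row)") from None
        n_sites = len(header) - 1
        rows: list[list[str]] = []
        ids: list[str] = []
        for r, record in enumerate(reader):
            if len(record) != n_sites + 1:
                raise ValueError(f"{path}: row {r + 1} has {len(record)} fields, expected {n_sites + 1}")
            for c, cell in enumerate(record[1:]):
                if cell not in CALLS:
                    raise ValueError(
                        f"{path}: invalid call {cell!r} at row {r + 1}, column {header[c + 1]}"
                    )
            ids.append(record[0])
            rows.append(record[1:])
    if sites is None:
        sites = [
            CpGSite(chrom="unknown", pos=int(h), amplicon="unknown", global_index=int(h))
            for h in header[1:]
        ]
    calls = np.array(rows, dtype="<U1") if rows else np.empty((0, n_sites), dtype="<U1")
    return ReadCallMatrix(assay=assay, sites=list(sites), calls=calls, read_ids=ids)
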