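"""Amplicon panels, CpG site detection, and locus-wide CpG numbering.

An amplicon panel is a set of PCR-amplified target intervals on one locus.
Within each amplicon the CpG dinucleotides are detected from the reference
sequence, and all CpGs across the panel receive a locus-wide 1-based index
in genomic coordinate order, so that downstream tables can refer to
"CpG 27" of a locus rather than a raw genomic position.

All internal coordinates are 0-based half-open (BED convention); SAM
positions are converted on ingestion elsewhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AmpliconDef",
    "CpGSite",
    "LocusMap",
    "detect_cpgs",
    "build_locus_map",
    "read_bed_panel",
    "read_fasta",
    "write_locus_map_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR amplicon interval.

    ``strand`` is the analysed cytosine strand: "+" quantifies the
    top-strand C of each CpG (the default; one cytosine per CpG
    dinucleotide is quantified).
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"amplicon {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"amplicon {self.name!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGSite:
    """A single CpG dinucleotide within an amplicon.

    ``pos`` is the 0-based position of the C on the analysed strand.
    ``global_index`` is the locus-wide 1-based number (assigned by
    :func:`build_locus_map`; 0 until then).
    """

    chrom: str
    pos: int
    amplicon: str
    global_index: int = 0


@dataclass
class LocusMap:
    """Ordered amplicons and their CpG sites with locus-wide numbering."""

    amplicons: list[AmpliconDef]
    sites: list[CpGSite]
    counts_per_amplicon: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sites_of(self, amplicon_name: str) -> list[CpGSite]:
        return [s for s in self.sites if s.amplicon == amplicon_name]

    def amplicon(self, name: str) -> AmpliconDef:
        for amp in self.amplicons:
            if amp.name == name:
                return amp
        raise KeyError(f"no amplicon named {name!r} in panel")

    def site_by_index(self, global_index: int) -> CpGSite:
        for s in self.sites:
            if s.global_index == global_index:
                return s
        raise KeyError(f"no CpG with global index {global_index}")


def detect_cpgs(reference_sequence: str | Mapping[str, str], amplicon: AmpliconDef) -> list[CpGSite]:
    """Detect every CpG dinucleotide of an amplicon on its analysed strand.

    For a "+" amplicon a site is a position ``p`` in ``[start, end-1)``
    with reference base C at ``p`` and G at ``p+1``; for a "-" amplicon the
    analysed C is the bottom-strand C, i.e. the G of the top-strand CpG,
    and the reported ``pos`` is the position of that G. Matching is
    case-insensitive; ambiguous bases (N) never match.
    """
    if isinstance(reference_sequence, Mapping):
        try:
            seq = reference_sequence[amplicon.chrom]
        except KeyError:
            raise ValueError(
                f"amplicon {amplicon.name!r}: chromosome {amplicon.chrom!r} not in reference"
            ) from None
    else:
        seq = reference_sequence
    if amplicon.end > len(seq):
        raise ValueError(
            f"amplicon {amplicon.name!r} interval [{amplicon.start},{amplicon.end}) "
            f"extends past reference of length {len(seq)}"
        )
    seq = seq.upper()
    sites: list[CpGSite] = []
    for p in range(amplicon.start, amplicon.end - 1):
        if seq[p : p + 2] == "CG":
            # top-strand C at p; bottom-strand C pairs with the G at p+1
            pos = p if amplicon.strand == "+" else p + 1
            sites.append(CpGSite(chrom=amplicon.chrom, pos=pos, amplicon=amplicon.name))
    return sites


def build_locus_map(
    panel: Sequence[AmpliconDef],
    reference_sequence: str | Mapping[str, str],
    dedup: bool = False,
) -> LocusMap:
    """Detect CpGs for every amplicon and assign locus-wide indices 1..N.

    Amplicons must lie on one chromosome. Overlapping amplicons that would
    count the same CpG twice raise an error unless ``dedup`` is set, in
    which case the site is attributed to the first amplicon (panel order).
    """
    if not panel:
        raise ValueError("empty amplicon panel")
    chroms = {a.chrom for a in panel}
    if len(chroms) > 1:
        raise ValueError(f"panel spans multiple chromosomes: {sorted(chroms)}")
    names = [a.name for a in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate amplicon names in panel")

    seen: dict[tuple[str, int], str] = {}
    all_sites: list[CpGSite] = []
    for amp in panel:
        for site in detect_cpgs(reference_sequence, amp):
            key = (site.chrom, site.pos)
            if key in seen:
                if not dedup:
                    raise ValueError(
                        f"CpG at {site.chrom}:{site.pos} detected in both "
                        f"{seen[key]!r} and {amp.name!r}; pass dedup=True to keep the first"
                    )
                continue
            seen[key] = amp.name
            all_sites.append(site)

    all_sites.sort(key=lambda s: s.pos)
    numbered = [
        CpGSite(chrom=s.chrom, pos=s.pos, amplicon=s.amplicon, global_index=i + 1)
        for i, s in enumerate(all_sites)
    ]
    counts: dict[str, int] = {a.name: 0 for a in panel}
    for s in numbered:
        counts[s.amplicon] += 1
    return LocusMap(amplicons=list(panel), sites=numbered, counts_per_amplicon=counts)


def read_bed_panel(path: str) -> list[AmpliconDef]:
    """Read an amplicon panel from BED (name in col 4, strand in col 6)."""
    panel: list[AmpliconDef] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"amplicon_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            panel.append(AmpliconDef(name=name, chrom=chrom, start=start, end=end, strand=strand))
    return panel


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into a {name: sequence} dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_locus_map_tsv(locus: LocusMap, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "amplicon", "global_index"])
        for s in locus.sites:
            writer.writerow([s.chrom, s.pos, s.amplicon, s.global_index])
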