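"""Per-CpG modification proportions with binomial confidence intervals.

For BS-seq the protected fraction is reported: p = nC/(nC+nT), the
percentage of (5mC+5hmC)/total C. For PB-seq the converted fraction is
reported after the opposite-strand redundancy compensation: protected
molecules contribute reads from both strands while converted (5fC/5caC)
positions contribute from one, so the C count is halved before forming
the proportion, p = nT/(0.5*nC + nT), the percentage of (5fC+5caC)/total C.

Confidence intervals follow the binomial model. The default is the exact
Clopper-Pearson interval, evaluated through the beta quantile function,
which generalizes smoothly to the non-integer effective counts that the
PB compensation produces. Wilson score intervals are available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon_model import AmpliconDef, CpGSite, LocusMap
from .read_calling import AssayType, CallingParams, ReadCallMatrix, call_read, _iter_alignments

__all__ = [
    "SiteCounts",
    "SiteProportion",
    "ConversionQC",
    "count_calls",
    "binomial_ci",
    "quantify_bs",
    "quantify_pb",
    "quantify_matrix",
    "site_table",
    "conversion_efficiency",
    "noncpg_conversion_qc",
]


@dataclass(frozen=True)
class SiteCounts:
    """Raw C/T call counts at one CpG site."""

    site: CpGSite
    nC: int
    nT: int

    def __post_init__(self) -> None:
        if self.nC < 0 or self.nT < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SiteProportion:
    """A modification proportion with its binomial confidence interval.

    ``p`` is NaN when the site has no informative depth (reported as
    missing, never as 0%). ``effective_n`` is the CI denominator: nC+nT
    for BS, 0.5*nC+nT for PB (may be non-integer).
    """

    site: CpGSite
    assay: AssayType
    p: float
    ci_low: float
    ci_high: float
    effective_n: float
    level: float = 0.95

    @property
    def missing(self) -> bool:
        return math.isnan(self.p)


@dataclass(frozen=True)
class ConversionQC:
    """Conversion-efficiency estimate from QC positions.

    BS efficiency is assessed at non-CpG cytosines (assumed unmodified,
    so they should all convert); PB efficiency at an unmodified spike-in.
    """

    assay: AssayType
    n_converted: int
    n_unconverted: int

    @property
    def efficiency(self) -> float:
        total = self.n_converted + self.n_unconverted
        if total == 0:
            raise ValueError(
                "no QC observations: supply non-CpG cytosine positions (BS) "
                "or a spike-in reference (PB)"
            )
        return self.n_converted / total


def count_calls(matrix: ReadCallMatrix) -> list[SiteCounts]:
    """Count C and T calls per site; N calls are ignored."""
    out = []
    for j, site in enumerate(matrix.sites):
        col = matrix.column(j)
        out.append(SiteCounts(site=site, nC=int((col == "C").sum()), nT=int((col == "T").sum())))
    return out


def binomial_ci(k: float, n: float, level: float = 0.95, method: str = "clopper-pearson") -> tuple[float, float]:
    """Two-sided binomial CI for k successes in n trials.

    ``clopper-pearson`` uses the exact beta-quantile form,
    low = B(alpha/2; k, n-k+1), high = B(1-alpha/2; k+1, n-k), which is
    well defined for real-valued k and n (needed for PB effective
    counts). ``wilson`` is the score interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        low = 0.0 if k <= 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k >= n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return low, high
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        phat = k / n
        denom = 1 + z * z / n
        center = (phat + z * z / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
        return max(0.0, center - half), min(1.0, center + half)
    raise ValueError(f"unknown CI method {method!r}")


def quantify_bs(
    counts: SiteCounts, level: float = 0.95, method: str = "clopper-pearson"
) -> SiteProportion:
    """BS proportion: p = nC/(nC+nT) = (5mC+5hmC)/total C."""
    n = counts.nC + counts.nT
    if n == 0:
        return SiteProportion(counts.site, AssayType.BS, math.nan, math.nan, math.nan, 0.0, level)
    p = counts.nC / n
    low, high = binomial_ci(counts.nC, n, level, method)
    return SiteProportion(counts.site, AssayType.BS, p, low, high, float(n), level)


def quantify_pb(
    counts: SiteCounts, level: float = 0.95, method: str = "clopper-pearson"
) -> SiteProportion:
    """PB proportion with strand-redundancy compensation.

    Protected cytosines are counted from both strands, converted
    (5fC/5caC) ones from one, so nC is halved: p = nT/(0.5*nC + nT) =
    (5fC+5caC)/total C. The CI uses the same effective counts.
    """
    n_eff = 0.5 * counts.nC + counts.nT
    if n_eff == 0:
        return SiteProportion(counts.site, AssayType.PB, math.nan, math.nan, math.nan, 0.0, level)
    p = counts.nT / n_eff
    low, high = binomial_ci(counts.nT, n_eff, level, method)
    return SiteProportion(counts.site, AssayType.PB, p, low, high, n_eff, level)


def quantify_matrix(
    matrix: ReadCallMatrix, level: float = 0.95, method: str = "clopper-pearson"
) -> list[SiteProportion]:
    quantify = quantify_bs if matrix.assay == AssayType.BS else quantify_pb
    return [quantify(c, level, method) for c in count_calls(matrix)]


def site_table(
    matrix: ReadCallMatrix, level: float = 0.95, method: str = "clopper-pearson"
) -> pd.DataFrame:
    """Per-site table on the percent scale (missing sites as NaN)."""
    counts = count_calls(matrix)
    props = quantify_matrix(matrix, level, method)
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in counts],
            "pos": [c.site.pos for c in counts],
            "global_index": [c.site.global_index for c in counts],
            "amplicon": [c.site.amplicon for c in counts],
            "assay": matrix.assay.value,
            "nC": [c.nC for c in counts],
            "nT": [c.nT for c in counts],
            "effective_n": [p.effective_n for p in props],
            "p_percent": [100 * p.p for p in props],
            "ci_low_percent": [100 * p.ci_low for p in props],
            "ci_high_percent": [100 * p.ci_high for p in props],
        }
    )


def conversion_efficiency(qc_calls, assay: AssayType) -> ConversionQC:
    """Conversion efficiency from calls (or counts) at QC positions.

    ``qc_calls`` is either an iterable of C/T/N calls at QC cytosines
    (non-CpG cytosines for BS; spike-in cytosines for PB) or a
    ``(n_converted, n_unconverted)`` pair. Efficiency is the fraction of
    convertible cytosines observed as converted (T).
    """
    if isinstance(qc_calls, tuple) and len(qc_calls) == 2:
        n_t, n_c = int(qc_calls[0]), int(qc_calls[1])
    else:
        arr = np.asarray(list(qc_calls), dtype="<U1")
        n_t = int((arr == "T").sum())
        n_c = int((arr == "C").sum())
    qc = ConversionQC(assay=assay, n_converted=n_t, n_unconverted=n_c)
    qc.efficiency  # raise early on zero QC observations
    return qc


def noncpg_conversion_qc(
    alignments,
    amplicon: AmpliconDef,
    reference_sequence,
    params: CallingParams | None = None,
    assay: AssayType = AssayType.BS,
) -> ConversionQC:
    """BS conversion-efficiency QC from non-CpG cytosines in an amplicon.

    Non-CpG cytosines are essentially unmethylated in mammalian somatic
    DNA, so any C call at them reflects conversion failure. Counts C/T
    observations at every analysed-strand non-CpG cytosine position.
    """
    params = params or CallingParams()
    if not isinstance(reference_sequence, str):
        reference_sequence = reference_sequence[amplicon.chrom]
    seq = reference_sequence.upper()
    qc_positions = []
    for p in range(amplicon.start, amplicon.end):
        if amplicon.strand == "+":
            if seq[p] == "C" and not (p + 1 < len(seq) and seq[p + 1] == "G"):
                qc_positions.append(p)
        else:
            if seq[p] == "G" and not (p >= 1 and seq[p - 1] == "C"):
                qc_positions.append(p)
    if not qc_positions:
        raise ValueError(
            f"amplicon {amplicon.name!r} has no non-CpG cytosines; "
            "supply an explicit QC/spike-in definition"
        )
    pseudo_sites = [
        CpGSite(chrom=amplicon.chrom, pos=p, amplicon=amplicon.name) for p in qc_positions
    ]
    n_t = n_c = 0
    for read in _iter_alignments(alignments, amplicon):
        if read.mapping_quality < params.min_mapping_quality:
            continue
        for call in call_read(read, pseudo_sites, assay, params, analysed_strand=amplicon.strand):
            if call == "T":
                n_t += 1
            elif call == "C":
                n_c += 1
    return conversion_efficiency((n_t, n_c), assay)
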