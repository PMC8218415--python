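"""Read-level co-methylation concordance via pairwise odds ratios.

For a pair of CpG sites, every read with a definitive call at both sites
falls into one cell of a 2x2 contingency table: both methylated (MM,
call C at both), both unmethylated (UU, call T at both), or discordant
(MU / UM). The odds ratio

    OR = MM * UU / (UM * MU)

is 0 when demethylation is exclusive (the two sites are never
demethylated on the same molecule), 1 when sites demethylate
independently, and +inf when demethylation is perfectly concordant
(always co-occurring), making it a quantitative read-level measure of
concordant demethylation — the methylation analogue of linkage
disequilibrium within a sequencing read.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplicon_model import LocusMap
from .read_calling import ReadCallMatrix

__all__ = [
    "PairContingency",
    "OddsRatioResult",
    "ORMatrix",
    "pair_contingency",
    "odds_ratio",
    "or_matrix",
    "or_vs_distance",
    "export_read_profiles",
    "write_pairwise_tsv",
    "write_or_matrix_tsv",
]

DEFAULT_MIN_INFORMATIVE = 10


@dataclass(frozen=True)
class PairContingency:
    """2x2 read counts for a CpG pair (M = call C, U = call T)."""

    i: int
    j: int
    MM: int
    MU: int
    UM: int
    UU: int

    def __post_init__(self) -> None:
        if min(self.MM, self.MU, self.UM, self.UU) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_informative(self) -> int:
        return self.MM + self.MU + self.UM + self.UU

    def transposed(self) -> "PairContingency":
        return PairContingency(self.j, self.i, self.MM, self.UM, self.MU, self.UU)


@dataclass(frozen=True)
class OddsRatioResult:
    """An odds ratio with its provenance.

    ``odds_ratio`` may be 0, +inf, or NaN (missing: 0/0 form or too few
    informative reads; ``reason`` says which). ``log_or_se`` is the
    Woolf standard error of log OR, finite only when all cells > 0.
    """

    pair: PairContingency
    odds_ratio: float
    log_or_se: float
    correction: str
    distance_bp: int | None = None
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return math.isnan(self.odds_ratio)


def pair_contingency(matrix: ReadCallMatrix, i: int, j: int) -> PairContingency:
    """Count MM/MU/UM/UU over reads with definitive calls at sites i, j.

    ``i`` and ``j`` are global CpG indices. Reads with N at either site
    are excluded.
    """
    if i == j:
        raise ValueError(f"pair requires two distinct sites, got i=j={i}")
    index = {s.global_index: k for k, s in enumerate(matrix.sites)}
    try:
        ci, cj = index[i], index[j]
    except KeyError as e:
        raise KeyError(f"global CpG index {e.args[0]} not in matrix") from None
    a, b = matrix.column(ci), matrix.column(cj)
    keep = (a != "N") & (b != "N")
    a, b = a[keep], b[keep]
    return PairContingency(
        i=i,
        j=j,
        MM=int(((a == "C") & (b == "C")).sum()),
        MU=int(((a == "C") & (b == "T")).sum()),
        UM=int(((a == "T") & (b == "C")).sum()),
        UU=int(((a == "T") & (b == "T")).sum()),
    )


def odds_ratio(
    ct: PairContingency,
    correction: str = "none",
    min_informative: int = 0,
    distance_bp: int | None = None,
) -> OddsRatioResult:
    """OR = MM*UU/(UM*MU) with the raw 0 / 1 / +inf semantics.

    ``correction="haldane"`` adds 0.5 to every cell first (useful for
    log-scale plotting). With no correction, an indeterminate 0/0 form
    or an empty table yields a missing value with a reason.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    mm, mu, um, uu = float(ct.MM), float(ct.MU), float(ct.UM), float(ct.UU)
    se = (
        math.sqrt(1 / mm + 1 / mu + 1 / um + 1 / uu)
        if min(mm, mu, um, uu) > 0
        else math.nan
    )
    if ct.n_informative == 0:
        return OddsRatioResult(ct, math.nan, se, correction, distance_bp, "no informative reads")
    if ct.n_informative < min_informative:
        return OddsRatioResult(
            ct, math.nan, se, correction, distance_bp,
            f"fewer than {min_informative} informative reads",
        )
    if correction == "haldane":
        mm, mu, um, uu = mm + 0.5, mu + 0.5, um + 0.5, uu + 0.5
    num, den = mm * uu, um * mu
    if den == 0 and num == 0:
        return OddsRatioResult(ct, math.nan, se, correction, distance_bp, "indeterminate 0/0")
    if den == 0:
        return OddsRatioResult(ct, math.inf, se, correction, distance_bp)
    return OddsRatioResult(ct, num / den, se, correction, distance_bp)


@dataclass
class ORMatrix:
    """Symmetric matrix of pairwise odds ratios over an amplicon's CpGs."""

    indices: list[int]
    results: dict[tuple[int, int], OddsRatioResult]

    def get(self, i: int, j: int) -> OddsRatioResult:
        return self.results[(min(i, j), max(i, j))]

    def values(self) -> np.ndarray:
        """Dense array (NaN diagonal and missing pairs)."""
        n = len(self.indices)
        pos = {g: k for k, g in enumerate(self.indices)}
        arr = np.full((n, n), np.nan)
        for (i, j), res in self.results.items():
            arr[pos[i], pos[j]] = arr[pos[j], pos[i]] = res.odds_ratio
        return arr


def or_matrix(
    matrix: ReadCallMatrix,
    correction: str = "none",
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> ORMatrix:
    """Odds ratio for every unordered CpG pair in the matrix."""
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 CpG sites for pairwise concordance")
    indices = [s.global_index for s in matrix.sites]
    positions = {s.global_index: s.pos for s in matrix.sites}
    results: dict[tuple[int, int], OddsRatioResult] = {}
    for a in range(len(indices)):
        for b in range(a + 1, len(indices)):
            i, j = indices[a], indices[b]
            ct = pair_contingency(matrix, i, j)
            dist = abs(positions[j] - positions[i])
            results[(i, j)] = odds_ratio(ct, correction, min_informative, dist)
    return ORMatrix(indices=indices, results=results)


def or_vs_distance(orm: ORMatrix, locus: LocusMap | None = None) -> pd.DataFrame:
    """Finite-OR pairs as (distance_bp, odds_ratio) records for scatter
    plotting; infinite and missing pairs are counted but not listed."""
    pos = None
    if locus is not None:
        pos = {s.global_index: s.pos for s in locus.sites}
    rows = []
    n_inf = n_missing = 0
    for (i, j), res in sorted(orm.results.items()):
        if res.missing:
            n_missing += 1
            continue
        if math.isinf(res.odds_ratio):
            n_inf += 1
            continue
        d = res.distance_bp if pos is None else abs(pos[j] - pos[i])
        rows.append((i, j, d, res.odds_ratio))
    df = pd.DataFrame(rows, columns=["i", "j", "distance_bp", "odds_ratio"])
    df.attrs["n_infinite"] = n_inf
    df.attrs["n_missing"] = n_missing
    return df


def export_read_profiles(matrix: ReadCallMatrix, ordering: str = "input") -> list[str]:
    """Per-read M/U/N profile strings (the per-read lollipop rendering:
    one row per read, M = methylated/protected, U = converted).

    ``ordering``: ``input`` preserves row order;
    ``by_methylation_count_desc`` puts the most-methylated reads first
    (stable within ties).
    """
    if ordering not in ("input", "by_methylation_count_desc"):
        raise ValueError(f"unknown ordering {ordering!r}")
    trans = {"C": "M", "T": "U", "N": "N"}
    profiles = ["".join(trans[c] for c in row) for row in matrix.calls]
    if ordering == "by_methylation_count_desc":
        order = sorted(range(len(profiles)), key=lambda k: -profiles[k].count("M"))
        profiles = [profiles[k] for k in order]
    return profiles


def _fmt_or(x: float) -> str:
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_pairwise_tsv(orm: ORMatrix, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["i", "j", "distance_bp", "MM", "MU", "UM", "UU", "OR", "log2_OR", "log_or_se"])
        for (i, j), res in sorted(orm.results.items()):
            ct = res.pair
            log2_or = (
                math.log2(res.odds_ratio)
                if res.odds_ratio not in (0.0,) and not math.isnan(res.odds_ratio)
                else (-math.inf if res.odds_ratio == 0.0 else math.nan)
            )
            w.writerow(
                [i, j, res.distance_bp, ct.MM, ct.MU, ct.UM, ct.UU,
                 _fmt_or(res.odds_ratio), _fmt_or(log2_or), _fmt_or(res.log_or_se)]
            )


def write_or_matrix_tsv(orm: ORMatrix, path: str) -> None:
    arr = orm.values()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["global_index"] + [str(g) for g in orm.indices])
        for g, row in zip(orm.indices, arr):
            w.writerow([str(g)] + [_fmt_or(x) for x in row])
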