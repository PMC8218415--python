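"""Truth-labelled synthetic amplicon reads and an exact expectation oracle.

Generative regimes for read-level demethylation across the CpGs of an
amplicon (one read = one DNA molecule = one epiallele):

* ``independent`` — each site demethylates independently with its own
  probability ``u_s``; every pairwise odds ratio is exactly 1.
* ``exclusive`` — at most one site per molecule demethylates (site s
  with probability ``u_s``); UU never occurs, so every OR is 0.
* ``concordant`` — a latent per-molecule state D ~ Bernoulli(pi)
  switches the whole molecule between a demethylated epiallele (site s
  demethylated with probability ``u_s``) and a methylated one
  (demethylated only with the small ``leak_s``); ORs grow without bound
  as u -> 1 and leak -> 0.
* ``mixture`` — with weight ``rho`` a molecule follows the concordant
  channel, otherwise an independent channel with the *same marginal*
  demethylation rates (pi*u_s + (1-pi)*leak_s), so rho tunes concordance
  at fixed per-site methylation levels.

Noise (applied only to the observed matrix, never the truth):
``conversion_failure`` leaves a convertible base unconverted (read as
C), ``inappropriate_conversion`` converts a protected base (read as T),
``seq_error`` replaces the base with a non-informative one (call N).

The expectation oracle (:func:`expected_contingency`,
:func:`expected_or`) computes exact pair-cell probabilities on the
truth states by enumeration over the latent state, independent of the
sampling code paths it is used to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam

from .amplicon_model import AmpliconDef, CpGSite, detect_cpgs
from .read_calling import AssayType, ReadCallMatrix

__all__ = [
    "DemethylationModel",
    "PBStrandModel",
    "simulate_matrix",
    "simulate_alignments",
    "simulate_composite_matrix",
    "simulate_distance_decay_matrix",
    "simulate_pb_counts",
    "expected_contingency",
    "expected_or",
    "expected_or_markov",
    "or_from_cells",
]


def _as_probs(x, n_sites: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n_sites,)).copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


@dataclass
class DemethylationModel:
    """Parameters of one generative regime (see module docstring).

    ``u`` are per-site demethylation probabilities (for PB-seq, read
    "demethylated" as "carrying 5fC/5caC", the converted T-state).
    ``depth`` is the default number of reads per amplicon.
    """

    mode: str
    u: Sequence[float] | float
    n_sites: int | None = None
    pi: float = 0.5
    rho: float = 1.0
    leak: Sequence[float] | float = 0.0
    assay: AssayType = AssayType.BS
    # default noise magnitudes are placeholders typical of well-converted
    # amplicon libraries; set them explicitly (or to 0) for controlled runs
    conversion_failure: float = 0.005
    inappropriate_conversion: float = 0.0
    seq_error: float = 0.001
    depth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exclusive", "independent", "concordant", "mixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_sites is None:
            self.n_sites = np.atleast_1d(np.asarray(self.u, dtype=float)).size
        self.u = _as_probs(np.atleast_1d(np.asarray(self.u, dtype=float)), self.n_sites, "u")
        self.leak = _as_probs(self.leak, self.n_sites, "leak")
        for name in ("pi", "rho", "conversion_failure", "inappropriate_conversion", "seq_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mode == "exclusive" and self.u.sum() > 1 + 1e-12:
            raise ValueError(
                f"exclusive mode requires sum(u) <= 1 (at most one event per read), "
                f"got {self.u.sum():.4g}"
            )
        self.assay = AssayType(self.assay)

    def marginals(self) -> np.ndarray:
        """Per-site truth demethylation probability under this model."""
        if self.mode in ("independent", "exclusive"):
            return self.u.copy()
        # the mixture's independent channel uses the same marginals, so
        # concordant and mixture share them
        return self.pi * self.u + (1 - self.pi) * self.leak


@dataclass(frozen=True)
class PBStrandModel:
    """Count-level strand-redundancy rule for PB-seq.

    Each molecule contributes 2 countable C units when its cytosine is
    protected (C/5mC/5hmC: both strands retain the evidence) and 1
    countable T unit when it is 5fC/5caC (only the converted strand
    carries it). Under this rule nT/(0.5*nC + nT) equals the true
    5fC/5caC molecule fraction exactly — the generative assumption under
    which the 0.5 compensation is an identity.
    """

    c_units_protected: int = 2
    t_units_converted: int = 1


def _default_sites(n: int, spacing: int = 10, start: int = 100) -> list[CpGSite]:
    return [
        CpGSite(chrom="synthetic", pos=start + k * spacing, amplicon="synthetic", global_index=k + 1)
        for k in range(n)
    ]


def _sample_truth(model: DemethylationModel, n_reads: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_reads, n_sites) truth: True = demethylated (T-state)."""
    s = model.n_sites
    if model.mode == "independent":
        return rng.random((n_reads, s)) < model.u
    if model.mode == "exclusive":
        probs = np.append(model.u, max(0.0, 1.0 - model.u.sum()))
        probs = probs / probs.sum()
        choice = rng.choice(s + 1, size=n_reads, p=probs)
        truth = np.zeros((n_reads, s), dtype=bool)
        hit = choice < s
        truth[np.nonzero(hit)[0], choice[hit]] = True
        return truth
    # concordant / mixture
    latent_channel = (
        np.ones(n_reads, dtype=bool)
        if model.mode == "concordant"
        else rng.random(n_reads) < model.rho
    )
    d = rng.random(n_reads) < model.pi
    per_site = np.where(d[:, None], model.u[None, :], model.leak[None, :])
    marg = model.pi * model.u + (1 - model.pi) * model.leak
    probs = np.where(latent_channel[:, None], per_site, marg[None, :])
    return rng.random((n_reads, s)) < probs


def _apply_noise(
    truth: np.ndarray, model: DemethylationModel, rng: np.random.Generator
) -> np.ndarray:
    """Truth states -> observed C/T/N calls under the assay noise model."""
    n, s = truth.shape
    calls = np.where(truth, "T", "C").astype("<U1")
    if model.conversion_failure > 0:
        flip = truth & (rng.random((n, s)) < model.conversion_failure)
        calls[flip] = "C"
    if model.inappropriate_conversion > 0:
        flip = ~truth & (rng.random((n, s)) < model.inappropriate_conversion)
        calls[flip] = "T"
    if model.seq_error > 0:
        calls[rng.random((n, s)) < model.seq_error] = "N"
    return calls


def simulate_matrix(
    model: DemethylationModel,
    n_reads: int | None = None,
    seed: int | None = None,
    sites: Sequence[CpGSite] | None = None,
) -> tuple[ReadCallMatrix, ReadCallMatrix]:
    """Draw (truth, observed) call matrices from the model.

    The truth matrix encodes the molecule states (C = methylated,
    T = demethylated, no N); the observed matrix adds assay noise.
    Reproducible for a given (model, seed).
    """
    n_reads = model.depth if n_reads is None else n_reads
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    site_list = list(sites) if sites is not None else _default_sites(model.n_sites)
    if len(site_list) != model.n_sites:
        raise ValueError(f"{len(site_list)} sites supplied for a {model.n_sites}-site model")
    truth_states = _sample_truth(model, n_reads, rng)
    truth_calls = np.where(truth_states, "T", "C").astype("<U1")
    observed_calls = _apply_noise(truth_states, model, rng)
    ids = [f"read_{k:06d}" for k in range(n_reads)]
    meta = {"mode": model.mode, "seed": seed, "source": "simulate_matrix"}
    truth = ReadCallMatrix(model.assay, site_list, truth_calls, list(ids), dict(meta, kind="truth"))
    observed = ReadCallMatrix(model.assay, site_list, observed_calls, list(ids), dict(meta, kind="observed"))
    return truth, observed


def simulate_composite_matrix(
    models: Sequence[DemethylationModel],
    n_reads: int,
    seed: int,
    spacing: int = 10,
) -> ReadCallMatrix:
    """Concatenate independent blocks drawn from several models.

    Each model contributes its own columns; blocks are mutually
    independent, so cross-block pairs have expected OR 1. Sites are laid
    out left to right with ``spacing`` bp between consecutive CpGs and
    renumbered 1..N. Returns the truth matrix.
    """
    rng = np.random.default_rng(seed)
    blocks = [_sample_truth(m, n_reads, rng) for m in models]
    truth = np.concatenate(blocks, axis=1)
    calls = np.where(truth, "T", "C").astype("<U1")
    total = truth.shape[1]
    sites = _default_sites(total, spacing=spacing)
    ids = [f"read_{k:06d}" for k in range(n_reads)]
    meta = {"source": "simulate_composite_matrix", "block_sizes": [m.n_sites for m in models]}
    return ReadCallMatrix(models[0].assay, sites, calls, ids, meta)


def simulate_distance_decay_matrix(
    positions: Sequence[int],
    marginal: float,
    corr_length_bp: float,
    n_reads: int,
    seed: int,
    chrom: str = "synthetic",
) -> ReadCallMatrix:
    """Truth matrix whose pairwise concordance decays with distance.

    Site states form a stationary binary Markov chain along the
    amplicon: every site is demethylated with marginal probability
    ``marginal``, and the correlation between neighbouring sites at
    distance d is exp(-d / corr_length_bp), so the correlation (and the
    expected OR) between any two sites decays with their separation.
    """
    if not 0 < marginal < 1:
        raise ValueError("marginal must lie in (0, 1)")
    if corr_length_bp <= 0:
        raise ValueError("corr_length_bp must be positive")
    pos = np.asarray(positions, dtype=int)
    if (np.diff(pos) <= 0).any():
        raise ValueError("positions must be strictly increasing")
    rng = np.random.default_rng(seed)
    s = len(pos)
    truth = np.zeros((n_reads, s), dtype=bool)
    truth[:, 0] = rng.random(n_reads) < marginal
    for k in range(1, s):
        r = math.exp(-(pos[k] - pos[k - 1]) / corr_length_bp)
        p_if_u = marginal + r * (1 - marginal)
        p_if_m = marginal * (1 - r)
        p = np.where(truth[:, k - 1], p_if_u, p_if_m)
        truth[:, k] = rng.random(n_reads) < p
    calls = np.where(truth, "T", "C").astype("<U1")
    sites = [
        CpGSite(chrom=chrom, pos=int(p), amplicon="synthetic", global_index=k + 1)
        for k, p in enumerate(pos)
    ]
    ids = [f"read_{k:06d}" for k in range(n_reads)]
    return ReadCallMatrix(
        AssayType.BS, sites, calls, ids,
        {"source": "simulate_distance_decay_matrix", "corr_length_bp": corr_length_bp},
    )


def simulate_pb_counts(
    f: float, n_molecules: int, seed: int, strand_model: PBStrandModel | None = None
) -> tuple[int, int]:
    """Draw (nC, nT) counts at one site under the PB strand-redundancy rule.

    Each of ``n_molecules`` carries 5fC/5caC with probability ``f``;
    protected molecules contribute 2 C units, converted ones 1 T unit.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    sm = strand_model or PBStrandModel()
    rng = np.random.default_rng(seed)
    n_converted = int(rng.binomial(n_molecules, f))
    n_protected = n_molecules - n_converted
    return sm.c_units_protected * n_protected, sm.t_units_converted * n_converted


# ---------------------------------------------------------------------------
# Aligned-read simulation


def simulate_alignments(
    model: DemethylationModel,
    amplicon: AmpliconDef,
    reference_sequence,
    out_sam: str,
    seed: int | None = None,
    n_reads: int | None = None,
) -> tuple[ReadCallMatrix, ReadCallMatrix]:
    """Write mapped SAM records realizing the model and return
    (truth, observed) matrices.

    Each read spans the whole amplicon. CpG cytosines carry the observed
    call (N is encoded as a non-informative A); non-CpG cytosines are
    unmodified, hence converted to T for BS (each escaping with
    probability ``conversion_failure``) and left as C for PB. Reads are
    tagged with their conversion strand (XG) so the caller can recover
    it. Byte-identical output for a fixed (model, seed).
    """
    if not isinstance(reference_sequence, str):
        reference_sequence = reference_sequence[amplicon.chrom]
    ref = reference_sequence.upper()
    sites = detect_cpgs(ref, amplicon)
    sites = [replace(s, global_index=k + 1) for k, s in enumerate(sites)]
    if len(sites) != model.n_sites:
        raise ValueError(
            f"amplicon {amplicon.name!r} has {len(sites)} CpGs but the model has "
            f"{model.n_sites} sites"
        )
    if amplicon.strand != "+":
        raise NotImplementedError("alignment simulation covers '+'-strand amplicons")

    seed = model.seed if seed is None else seed
    truth, observed = simulate_matrix(model, n_reads=n_reads, seed=seed, sites=sites)
    rng = np.random.default_rng(seed + 1)  # separate stream for non-CpG conversion

    site_pos = {s.pos for s in sites}
    # non-CpG top-strand cytosines inside the amplicon (conversion QC positions)
    noncpg_c = [
        p
        for p in range(amplicon.start, amplicon.end)
        if ref[p] == "C" and not (p + 1 < len(ref) and ref[p + 1] == "G") and p not in site_pos
    ]

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": amplicon.chrom, "LN": len(ref)}],
        }
    )
    length = amplicon.end - amplicon.start
    base_seq = list(ref[amplicon.start : amplicon.end])
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for row_idx in range(observed.n_reads):
            seq = base_seq.copy()
            for s, call in zip(sites, observed.calls[row_idx]):
                offset = s.pos - amplicon.start
                seq[offset] = call if call in ("C", "T") else "A"
            if model.assay == AssayType.BS:
                escape = rng.random(len(noncpg_c)) < model.conversion_failure
                for p, esc in zip(noncpg_c, escape):
                    seq[p - amplicon.start] = "C" if esc else "T"
            a = pysam.AlignedSegment(header)
            a.query_name = observed.read_ids[row_idx]
            a.query_sequence = "".join(seq)
            a.flag = 0
            a.reference_id = 0
            a.reference_start = amplicon.start
            a.mapping_quality = 60
            a.cigartuples = [(0, length)]
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            a.set_tag("XG", "CT", value_type="Z")
            out.write(a)
    return truth, observed


# ---------------------------------------------------------------------------
# Exact expectation oracle


def _pair_cells_factorized(ui: float, uj: float) -> dict[str, float]:
    # independent Bernoulli demethylation at the two sites
    return {
        "MM": (1 - ui) * (1 - uj),
        "MU": (1 - ui) * uj,
        "UM": ui * (1 - uj),
        "UU": ui * uj,
    }


def expected_contingency(model: DemethylationModel, i: int, j: int) -> dict[str, float]:
    """Exact MM/MU/UM/UU truth-state probabilities for sites i, j.

    ``i`` and ``j`` are 1-based site indices (matching the global
    numbering of matrices the model generates). Computed by enumeration
    over the latent state; the noise fields are ignored (the oracle is
    defined on true modification states).
    """
    if i == j:
        raise ValueError("pair requires two distinct sites")
    for k in (i, j):
        if not 1 <= k <= model.n_sites:
            raise ValueError(f"site index {k} outside 1..{model.n_sites}")
    ui, uj = model.u[i - 1], model.u[j - 1]
    if model.mode == "independent":
        return _pair_cells_factorized(ui, uj)
    if model.mode == "exclusive":
        return {"MM": max(0.0, 1 - ui - uj), "MU": uj, "UM": ui, "UU": 0.0}
    li, lj = model.leak[i - 1], model.leak[j - 1]
    demeth = _pair_cells_factorized(ui, uj)
    meth = _pair_cells_factorized(li, lj)
    latent = {k: model.pi * demeth[k] + (1 - model.pi) * meth[k] for k in demeth}
    if model.mode == "concordant":
        return latent
    mi = model.pi * ui + (1 - model.pi) * li
    mj = model.pi * uj + (1 - model.pi) * lj
    indep = _pair_cells_factorized(mi, mj)
    return {k: model.rho * latent[k] + (1 - model.rho) * indep[k] for k in latent}


def or_from_cells(cells: dict[str, float]) -> float:
    """MM*UU/(MU*UM) on cell probabilities; 0 and +inf permitted."""
    num = cells["MM"] * cells["UU"]
    den = cells["MU"] * cells["UM"]
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def expected_or(model: DemethylationModel, i: int, j: int) -> float:
    """Exact odds ratio implied by the model for the pair (i, j)."""
    return or_from_cells(expected_contingency(model, i, j))


def expected_or_markov(marginal: float, corr: float) -> float:
    """Exact OR for two binary sites with equal marginals and
    correlation ``corr`` (the pair law of the distance-decay chain)."""
    m, r = marginal, corr
    cells = {
        "UU": m * m + r * m * (1 - m),
        "MM": (1 - m) ** 2 + r * m * (1 - m),
        "UM": m * (1 - m) * (1 - r),
        "MU": m * (1 - m) * (1 - r),
    }
    return or_from_cells(cells)
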