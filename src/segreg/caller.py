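"""Log-likelihood-ratio minor-allele detection and the filter battery.

At each pileup site the candidate minor allele is the non-major allele with
the most reads.  With per-read error rates epsilon_j derived from the
(recalibrated) phred scores, the site likelihood of a minor allele
frequency f is

    L(f) = prod_{j=1..l} [(1-f) eps_j + f (1-eps_j)]
         * prod_{j=1..k} [(1-f) (1-eps_j) + f eps_j]

over the l minor-allele reads and k major-allele reads.  The MAF is
estimated by maximum likelihood over f in [0, 0.5] and the evidence
statistic is LLR = log10(L(f_hat) / L(0)), floored at 0.

The filter battery follows high-coverage heteroplasmy practice: bases below
phred 20 are not counted; at least 2 minor-allele reads per strand; ML MAF
>= 0.1 %; LLR > 3; Fisher strand-bias score SB < 1 (equivalent to p > 0.01);
read-position rank-sum z > -3; and sites inside masked repetitive regions
(rCRS defaults 302-316, 513-526, 566-573, 16181-16194) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .alignment_io import BASES, Pileup, PileupSite, phred_to_error

#: rCRS repetitive regions prone to misalignment and frequent indels
DEFAULT_MASKED_REGIONS = ((302, 316), (513, 526), (566, 573), (16181, 16194))

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(slots=True)
class SiteEvidence:
    """Per-site read-level evidence for the likelihood model."""

    minor_errors: np.ndarray        # eps_j of the l minor-allele reads
    major_errors: np.ndarray        # eps_j of the k major-allele reads
    minor_fwd: int = 0
    minor_rev: int = 0
    major_fwd: int = 0
    major_rev: int = 0
    minor_read_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    major_read_positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.minor_errors = np.asarray(self.minor_errors, dtype=float)
        self.major_errors = np.asarray(self.major_errors, dtype=float)
        for eps in (self.minor_errors, self.major_errors):
            if eps.size and (np.any(eps <= 0) or np.any(eps >= 1)):
                raise ValueError("error rates must lie strictly in (0, 1)")

    @property
    def l(self) -> int:
        return int(self.minor_errors.size)

    @property
    def k(self) -> int:
        return int(self.major_errors.size)


#: error-rate lookup for integer phred scores 0..90
_EPS_TABLE = 10.0 ** (-np.arange(91) / 10.0)


def _compressed(evidence: SiteEvidence):
    """Unique (eps, count) per class — phred-derived eps values repeat."""
    me, mc = np.unique(evidence.minor_errors, return_counts=True)
    Me, Mc = np.unique(evidence.major_errors, return_counts=True)
    return me, mc.astype(float), Me, Mc.astype(float)


def _loglik_grid(f: np.ndarray, me, mc, Me, Mc) -> np.ndarray:
    """log L(f) (natural log) for a vector of frequencies."""
    f = np.atleast_1d(np.asarray(f, dtype=float))[:, None]
    out = np.zeros(f.shape[0])
    if me.size:
        out += (mc * np.log((1 - f) * me + f * (1 - me))).sum(axis=1)
    if Me.size:
        out += (Mc * np.log((1 - f) * (1 - Me) + f * Me)).sum(axis=1)
    return out


def site_log_likelihood(f: float, evidence: SiteEvidence) -> float:
    """Natural-log site likelihood, computed in log space."""
    if not 0 <= f <= 0.5:
        raise ValueError("f must lie in [0, 0.5]")
    return float(_loglik_grid(np.array([f]), *_compressed(evidence))[0])


def site_likelihood(f: float, evidence: SiteEvidence) -> float:
    """L(f) as a probability (may underflow to 0 for very deep sites)."""
    return math.exp(site_log_likelihood(f, evidence))


_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


def _loglik_scalar(f: float, terms) -> float:
    """log L(f) from [(eps, count, is_minor), ...] — fast for few unique eps."""
    out = 0.0
    for eps, cnt, is_minor in terms:
        if is_minor:
            out += cnt * math.log((1 - f) * eps + f * (1 - eps))
        else:
            out += cnt * math.log((1 - f) * (1 - eps) + f * eps)
    return out


def _mle_compressed(me, mc, Me, Mc, grid_points: int = 512,
                    tol: float = 1e-6) -> tuple[float, float]:
    """(f_hat, LLR in log10) via coarse grid + golden-section refinement."""
    if me.size == 0 and Me.size == 0:
        return 0.0, 0.0
    grid = np.linspace(0.0, 0.5, grid_points)
    ll = _loglik_grid(grid, me, mc, Me, Mc)
    i = int(np.argmax(ll))
    terms = [(float(e), float(c), True) for e, c in zip(me, mc)] + \
            [(float(e), float(c), False) for e, c in zip(Me, Mc)]
    ll0 = float(ll[0])
    a = float(grid[max(i - 1, 0)])
    b = float(grid[min(i + 1, grid_points - 1)])
    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    fc = _loglik_scalar(c, terms)
    fd = _loglik_scalar(d, terms)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLD * (b - a)
            fc = _loglik_scalar(c, terms)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLD * (b - a)
            fd = _loglik_scalar(d, terms)
    f_hat = 0.5 * (a + b)
    best = max(_loglik_scalar(f_hat, terms), float(ll[i]))
    if float(ll[i]) >= best:
        f_hat = float(grid[i])
    if ll0 >= best:
        return 0.0, 0.0
    return float(f_hat), max((best - ll0) / math.log(10.0), 0.0)


def _mle_from_hists(minor_hist: np.ndarray, major_hist: np.ndarray
                    ) -> tuple[float, float]:
    """MLE/LLR from integer-phred histograms (index = phred score)."""
    mq = np.flatnonzero(minor_hist)
    Mq = np.flatnonzero(major_hist)
    return _mle_compressed(_EPS_TABLE[mq], minor_hist[mq].astype(float),
                           _EPS_TABLE[Mq], major_hist[Mq].astype(float))


def _maf_and_llr(evidence: SiteEvidence, grid_points: int = 512,
                 tol: float = 1e-6) -> tuple[float, float]:
    """(f_hat, LLR in log10) for one site's evidence."""
    me, mc, Me, Mc = _compressed(evidence)
    return _mle_compressed(me, mc, Me, Mc, grid_points=grid_points, tol=tol)


def estimate_maf(evidence: SiteEvidence, tol: float = 1e-6) -> float:
    """Maximum-likelihood minor allele frequency over f in [0, 0.5]."""
    return _maf_and_llr(evidence, tol=tol)[0]


def llr(evidence: SiteEvidence) -> float:
    """log10(L(f_hat) / L(0)), floored at 0."""
    return _maf_and_llr(evidence)[1]


def strand_bias(minor_fwd: int, minor_rev: int,
                major_fwd: int, major_rev: int) -> float:
    """Strand-bias score from a two-sided Fisher exact test on the 2x2
    minor/major x forward/reverse table: ``-log10(p) / 2``, so a score of 1
    corresponds exactly to p = 0.01 and the pass condition SB < 1 to p > 0.01."""
    table = np.array([[minor_fwd, minor_rev], [major_fwd, major_rev]])
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    if table.sum() == 0:
        raise ValueError("strand-bias test undefined for an all-zero table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    p = max(float(p), 1e-300)
    return -math.log10(p) / 2.0


def pos_rank_sum(minor_read_positions, major_read_positions) -> float | None:
    """Tie-corrected normal-approximation z of the Mann-Whitney U comparing
    minor- vs major-allele read positions.

    The sign convention makes z negative when minor-allele bases cluster
    toward late cycles (read ends, where errors concentrate), so the filter
    z > -3 guards against end-clustered artifacts.  Returns None
    (indeterminate, treated as a pass) when either list is empty.
    """
    x = np.asarray(minor_read_positions, dtype=float)
    y = np.asarray(major_read_positions, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        return None
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0        # large when minor positions are high
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 0.0
    return float((mu - u1) / math.sqrt(var))


def signal_score(qualities) -> float:
    """Sum over phred scores of x_i / e_i, with x_i the number of reads whose
    base quality is i and e_i = 10^(-i/10); accepts a quality array or a
    {quality: count} histogram."""
    if isinstance(qualities, dict):
        items = qualities.items()
        return float(sum(c / phred_to_error(q) for q, c in items))
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    return float(np.sum(1.0 / phred_to_error(q)))


@dataclass(slots=True)
class CallThresholds:
    """Filter thresholds; defaults follow the high-coverage mtDNA pipeline."""

    min_base_quality: int = 20
    min_strand_reads: int = 2
    min_llr: float = 3.0
    min_maf: float = 0.001
    max_strand_bias: float = 1.0
    min_pos_rank_sum: float = -3.0


@dataclass(slots=True)
class SiteCall:
    """Per-site minor-allele result with all filter flags (True = pass)."""

    position: int
    major_allele: str
    minor_allele: str
    depth: int
    minor_count: int
    major_count: int
    raw_maf: float
    ml_maf: float
    llr: float
    strand_bias: float
    pos_rank_sum: float             # nan when indeterminate
    signal: float
    flags: dict
    passed: bool


def _in_masked(position: int, masked_regions) -> bool:
    return any(lo <= position <= hi for lo, hi in masked_regions)


def call_minor_alleles(pileup: Pileup | Iterable[PileupSite],
                       thresholds: CallThresholds | None = None,
                       masked_regions=DEFAULT_MASKED_REGIONS,
                       recalibrated: bool = True,
                       filter_statistics: bool = True) -> list[SiteCall]:
    """Score every site with at least one counted minor-allele read.

    All sites with a candidate are reported with their per-filter flags; the
    passing subset is marked via ``passed``.  ``recalibrated=False`` flags in
    the output that the caller ran on raw qualities (the statistics are
    computed identically).  ``filter_statistics=False`` skips the strand-bias
    and rank-sum tests (their flags become indeterminate passes), which is
    substantially faster when only the LLR ranking is needed, e.g. for ROC
    evaluation.
    """
    th = thresholds or CallThresholds()
    calls: list[SiteCall] = []
    for site in pileup:
        counted = site.qual >= th.min_base_quality
        if not counted.any():
            continue
        allele = site.allele[counted]
        rev = site.is_reverse[counted]
        qual = site.qual[counted]
        rpos = site.read_pos[counted]
        totals = np.bincount(allele.astype(np.int64), minlength=4)
        major = int(np.argmax(totals))          # ties -> lowest code (A<C<G<T)
        rest = totals.copy()
        rest[major] = -1
        minor = int(np.argmax(rest))
        l = int(totals[minor])
        if l == 0:
            continue
        k = int(totals[major])
        depth = int(counted.sum())
        mm = allele == minor
        MM = allele == major
        q = np.clip(qual.astype(np.int64), 0, 90)
        minor_fwd = int((mm & ~rev).sum())
        minor_rev_ = int((mm & rev).sum())
        major_fwd = int((MM & ~rev).sum())
        major_rev_ = int((MM & rev).sum())
        f_hat, llr_val = _mle_from_hists(np.bincount(q[mm], minlength=91),
                                         np.bincount(q[MM], minlength=91))
        if filter_statistics:
            sb = strand_bias(minor_fwd, minor_rev_, major_fwd, major_rev_)
            prs = pos_rank_sum(rpos[mm], rpos[MM])
        else:
            sb, prs = float("nan"), None
        flags = {
            "min_strand_reads": (minor_fwd >= th.min_strand_reads
                                 and minor_rev_ >= th.min_strand_reads),
            "min_maf": f_hat >= th.min_maf,
            "min_llr": llr_val > th.min_llr,
            "strand_bias": True if math.isnan(sb) else sb < th.max_strand_bias,
            "pos_rank_sum": True if prs is None else prs > th.min_pos_rank_sum,
            "masked_region": not _in_masked(site.position, masked_regions),
            "biallelic": depth == l + k,
            "recalibrated_input": recalibrated,
        }
        passed = all(flags[name] for name in
                     ("min_strand_reads", "min_maf", "min_llr", "strand_bias",
                      "pos_rank_sum", "masked_region"))
        calls.append(SiteCall(
            position=site.position,
            major_allele=BASES[major],
            minor_allele=BASES[minor],
            depth=depth, minor_count=l, major_count=k,
            raw_maf=l / depth, ml_maf=f_hat, llr=llr_val,
            strand_bias=sb,
            pos_rank_sum=float("nan") if prs is None else prs,
            signal=float((np.bincount(q, minlength=91) / _EPS_TABLE).sum()),
            flags=flags, passed=passed))
    return calls


@dataclass(slots=True)
class TiTvResult:
    ratio: float                    # nan when no transversions (undefined)
    transitions: int
    transversions: int

    @property
    def defined(self) -> bool:
        return self.transversions > 0


def titv_ratio(calls: Sequence[SiteCall]) -> TiTvResult:
    """Transition/transversion ratio over called (major -> minor) substitutions;
    an elevated ratio indicates true mtDNA variation, ~0.5 indicates error."""
    if len(calls) == 0:
        raise ValueError("no calls supplied")
    ti = sum(1 for c in calls if (c.major_allele, c.minor_allele) in TRANSITIONS)
    tv = len(calls) - ti
    return TiTvResult(ti / tv if tv else float("nan"), ti, tv)


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

CALL_COLUMNS = ("position", "major", "minor", "depth", "minor_count",
                "major_count", "raw_maf", "ml_maf", "llr", "strand_bias",
                "pos_rank_sum", "signal", "failed_filters", "pass")


def write_call_table(calls: Sequence[SiteCall], path, header_lines=()) -> None:
    """Tab-separated call table, 1-based positions, '#'-prefixed headers."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            failed = ",".join(k for k, v in c.flags.items()
                              if k != "recalibrated_input" and not v) or "."
            fh.write(f"{c.position}\t{c.major_allele}\t{c.minor_allele}\t"
                     f"{c.depth}\t{c.minor_count}\t{c.major_count}\t"
                     f"{c.raw_maf:.6g}\t{c.ml_maf:.6g}\t{c.llr:.4f}\t"
                     f"{c.strand_bias:.4f}\t{c.pos_rank_sum:.4f}\t"
                     f"{c.signal:.6g}\t{failed}\t{int(c.passed)}\n")


def write_vcf(calls: Sequence[SiteCall], path, contig: str = "chrM",
              contig_length: int | None = None) -> None:
    """Minimal VCF with the call statistics in INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=segreg\n")
        if contig_length:
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        for k, desc in (("MAF", "Maximum-likelihood minor allele frequency"),
                        ("LLR", "log10 likelihood ratio vs MAF=0"),
                        ("SB", "Strand-bias score, -log10(p)/2"),
                        ("PRS", "Read-position rank-sum z"),
                        ("DP", "Counted depth"), ("MC", "Minor-allele reads")):
            typ = "Integer" if k in ("DP", "MC") else "Float"
            fh.write(f'##INFO=<ID={k},Number=1,Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            filt = "PASS" if c.passed else ";".join(
                k for k, v in c.flags.items()
                if k != "recalibrated_input" and not v)
            info = (f"MAF={c.ml_maf:.6g};LLR={c.llr:.4f};SB={c.strand_bias:.4f};"
                    f"PRS={c.pos_rank_sum:.4f};DP={c.depth};MC={c.minor_count}")
            fh.write(f"{contig}\t{c.position}\t.\t{c.major_allele}\t"
                     f"{c.minor_allele}\t.\t{filt}\t{info}\n")
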