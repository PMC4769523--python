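"""Read simulation with planted, group-dependent error rates and
systematically miscalibrated emitted qualities.

The generator emulates a very-high-coverage resequencing experiment on a
small circular genome (mtDNA-like) or a spiked-in control: reads are drawn
uniformly over the circularised template (a copy of the first
``extension`` bases appended to the end), each base is substituted with a
true error rate that depends on machine cycle and sequence context, and the
emitted phred score reflects only the machine's *nominal* confidence — the
planted miscalibration that recalibration is meant to correct.

Default error model (one base): a nominal quality level is drawn from a
bimodal Illumina-like distribution (most bases Q37/Q40, small low-quality
tail, late cycles degraded), and the true error rate is

    eps_true = 10^(-q_nom/10) + ctx(prev, base) * (background + ramp * c/R)

with background 1e-3 by default — so for a nominal Q40 base the correct
score is 29.59, exactly the background-error arithmetic — plus a mild
cycle-linear ramp and deterministic context factors.  The emitted quality
is an affine map of the nominal score (identity by default).

All sampling comes from a single ``numpy.random.default_rng(seed)`` stream
in a fixed order (fragment starts, fragment lengths, quality levels,
downgrades, error draws, substitution draws), so outputs are byte-identical
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import edlib
import numpy as np
import pysam

from .alignment_io import (BASES, START_CODE, ObservationBatch,
                           complement_codes, decode_sequence, encode_sequence)

DEFAULT_EXTENSION = 1000

#: deterministic mild context factors, indexed [prev (A,C,G,T,START), base];
#: values chosen to span the ~2.5-fold context variation typical of Illumina
#: substitution-error tables (GG/GT-type contexts elevated).
DEFAULT_CONTEXT_FACTORS = np.array([
    # base:  A     C     G     T
    [0.80, 1.00, 1.10, 0.90],   # prev A
    [0.90, 0.70, 1.20, 1.00],   # prev C
    [1.30, 1.10, 1.60, 1.40],   # prev G
    [0.90, 1.00, 1.20, 0.80],   # prev T
    [1.00, 1.00, 1.00, 1.00],   # START
])


@dataclass
class ErrorProfile:
    """Planted error model and quality-emission (miscalibration) map.

    ``quality_levels``/``level_weights`` give the nominal per-base quality
    distribution; ``cycle_downgrade`` is the probability (at the last cycle,
    ramping linearly from 0) of dropping one level.  ``background_error`` and
    ``cycle_ramp`` are the systematic error components invisible to the
    basecaller; ``context_factors`` scales them per (previous true base,
    true base).  ``emission_slope``/``emission_offset`` apply an affine
    distortion to the emitted score.  ``fixed_error`` overrides the whole
    model with one uniform true error rate (emitted scores still follow the
    nominal draw), which is convenient for closed-form checks.
    """

    quality_levels: tuple = (2, 12, 22, 27, 32, 37, 40)
    level_weights: tuple = (0.03, 0.02, 0.01, 0.02, 0.07, 0.30, 0.55)
    cycle_downgrade: float = 0.10
    background_error: float = 1e-3
    cycle_ramp: float = 1e-3
    context_factors: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTEXT_FACTORS.copy())
    spectrum: np.ndarray | None = None      # (4, 4) row-stochastic off-diagonal, None = uniform
    emission_slope: float = 1.0
    emission_offset: float = 0.0
    #: fraction of bases emitted at the floor score (2) regardless of their
    #: true accuracy — basecaller pessimism that a quality-20 counting rule
    #: discards until recalibration restores them; applies only to bases
    #: whose nominal quality is at least ``pessimistic_min_nominal`` (truly
    #: uncertain bases already carry their own low level)
    pessimistic_fraction: float = 0.0
    pessimistic_min_nominal: int = 30
    fixed_error: float | None = None

    def __post_init__(self):
        w = np.asarray(self.level_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("level_weights must sum to 1")
        if self.spectrum is not None:
            s = np.asarray(self.spectrum, dtype=float)
            if s.shape != (4, 4) or not np.allclose(np.diag(s), 0) \
                    or not np.allclose(s.sum(axis=1), 1.0):
                raise ValueError("spectrum must be 4x4, zero diagonal, rows summing to 1")
        if self.fixed_error is not None and not 0 < self.fixed_error < 0.75:
            raise ValueError("fixed_error must lie in (0, 0.75)")

    @classmethod
    def uniform(cls, error_rate: float, emitted_quality: int = 40) -> "ErrorProfile":
        """One true error rate everywhere; emitted quality constant."""
        return cls(quality_levels=(emitted_quality,), level_weights=(1.0,),
                   cycle_downgrade=0.0, background_error=0.0, cycle_ramp=0.0,
                   context_factors=np.ones((5, 4)), fixed_error=error_rate)

    @classmethod
    def calibrated(cls, **kwargs) -> "ErrorProfile":
        """Emitted scores equal true scores (no systematic component)."""
        return cls(background_error=0.0, cycle_ramp=0.0,
                   context_factors=np.ones((5, 4)), **kwargs)

    @classmethod
    def legacy_basecaller(cls) -> "ErrorProfile":
        """Early-basecaller emission regime.

        Three miscalibration features of first-generation Illumina quality
        strings are planted: (i) a sizeable fraction of confidently read,
        accurate bases is emitted at the floor score (basecaller pessimism),
        so a phred>=20 counting rule throws them away until recalibration
        restores them; (ii) a small systematic background error is
        underestimated on the high-quality mass, inflating likelihood-ratio
        statistics computed from raw scores as depth grows; and (iii) a few
        sequence contexts (G-preceded motifs, A-read-as-C confusion) are
        error hotspots invisible in the emitted scores.  Truly uncertain
        bases carry their own low nominal level and stay below the counting
        threshold either way.
        """
        ctx = DEFAULT_CONTEXT_FACTORS.copy()
        ctx[2, 2] = 6.0     # G followed by G
        ctx[2, 3] = 12.0    # G followed by T (GGT-motif-like hotspot)
        ctx[0, 1] = 8.0     # A read as C confusion context
        return cls(quality_levels=(12, 22, 27, 32, 37, 40),
                   level_weights=(0.03, 0.01, 0.01, 0.03, 0.17, 0.75),
                   background_error=1e-4, cycle_ramp=1e-4,
                   context_factors=ctx, pessimistic_fraction=0.15)

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls.uniform(1e-12)           # effectively no errors


@dataclass(slots=True)
class TruthVariant:
    """One planted minor-allele site with its realised sampling outcome."""

    position: int                   # 1-based, major-template coordinates
    major_allele: str
    minor_allele: str
    planted_fraction: float
    realized_count: int             # minor-library reads covering the site
    depth: int
    realized_maf: float


@dataclass
class TruthSet:
    """Ground truth of a mixture: planted fraction plus per-site realised
    minor-read counts and MAFs."""

    planted_fraction: float
    variants: list

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tmajor\tminor\tplanted_fraction\t"
                     "realized_count\tdepth\trealized_maf\n")
            for v in self.variants:
                fh.write(f"{v.position}\t{v.major_allele}\t{v.minor_allele}\t"
                         f"{v.planted_fraction:.6g}\t{v.realized_count}\t"
                         f"{v.depth}\t{v.realized_maf:.6g}\n")


class ReadSet:
    """Columnar container of simulated (ungapped) reads on one template.

    ``seq``/``qual``/``is_error`` are (n, L) arrays in reference orientation;
    ``start`` is the 0-based position on the *extended* template; reads never
    cross the extended end.
    """

    def __init__(self, start, reverse, mate, frag, seq, qual, is_error,
                 genome_length, extension, template_name="sim"):
        self.start = np.asarray(start, dtype=np.int32)
        self.reverse = np.asarray(reverse, dtype=bool)
        self.mate = np.asarray(mate, dtype=np.int8)
        self.frag = np.asarray(frag, dtype=np.int32)
        self.seq = np.asarray(seq, dtype=np.uint8)
        self.qual = np.asarray(qual, dtype=np.uint8)
        self.is_error = np.asarray(is_error, dtype=bool)
        self.genome_length = int(genome_length)
        self.extension = int(extension)
        self.template_name = template_name

    @property
    def n_reads(self) -> int:
        return int(self.start.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.seq.shape[1])

    def subset(self, mask) -> "ReadSet":
        return ReadSet(self.start[mask], self.reverse[mask], self.mate[mask],
                       self.frag[mask], self.seq[mask], self.qual[mask],
                       self.is_error[mask], self.genome_length, self.extension,
                       self.template_name)

    @staticmethod
    def concat(a: "ReadSet", b: "ReadSet") -> "ReadSet":
        if a.genome_length != b.genome_length or a.read_length != b.read_length:
            raise ValueError("read sets are not on compatible templates")
        return ReadSet(
            np.concatenate([a.start, b.start]),
            np.concatenate([a.reverse, b.reverse]),
            np.concatenate([a.mate, b.mate]),
            np.concatenate([a.frag, b.frag + (a.frag.max() + 1 if a.n_reads else 0)]),
            np.concatenate([a.seq, b.seq]),
            np.concatenate([a.qual, b.qual]),
            np.concatenate([a.is_error, b.is_error]),
            a.genome_length, max(a.extension, b.extension), a.template_name)

    # -- per-site access ----------------------------------------------
    def covering(self, position0: int) -> np.ndarray:
        """Indices of reads covering 0-based circular position ``position0``
        (contributions through the appended extension are folded back)."""
        L = self.read_length
        direct = (self.start <= position0) & (position0 < self.start + L)
        wrapped = position0 + self.genome_length
        folded = (self.start <= wrapped) & (wrapped < self.start + L)
        return np.flatnonzero(direct | folded)

    def base_at(self, position0: int):
        """(codes, quals, reverse) of the covering reads at a circular site."""
        idx = self.covering(position0)
        off = position0 - self.start[idx]
        off = np.where(off < 0, off + self.genome_length, off)
        return (self.seq[idx, off], self.qual[idx, off], self.reverse[idx])

    # -- conversions ---------------------------------------------------
    def observation_batch(self, reference, fold_circular: bool = True) -> ObservationBatch:
        """Vectorised conversion to per-base observations.

        ``reference`` is the (unextended) template/consensus the mismatch
        flags are computed against; with ``fold_circular`` positions in the
        appended extension map back to the genome start.
        """
        ref = encode_sequence(reference) if isinstance(reference, str) else np.asarray(reference)
        n, L = self.seq.shape
        pos = self.start[:, None].astype(np.int64) + np.arange(L, dtype=np.int64)
        if fold_circular:
            pos %= self.genome_length
        allele = self.seq
        # machine orientation: reverse reads are complemented and flipped
        mach = np.where(self.reverse[:, None],
                        complement_codes(allele.ravel()).reshape(n, L)[:, ::-1],
                        allele)
        qual_m = np.where(self.reverse[:, None], self.qual[:, ::-1], self.qual)
        rpos_m = np.where(self.reverse[:, None],
                          pos[:, ::-1], pos)
        prev = np.concatenate(
            [np.full((n, 1), START_CODE, dtype=np.uint8), mach[:, :-1]], axis=1)
        cycle = np.broadcast_to(np.arange(1, L + 1, dtype=np.int32), (n, L))
        mismatch = allele != ref[pos % len(ref)]
        mismatch_m = np.where(self.reverse[:, None], mismatch[:, ::-1], mismatch)
        mate = np.broadcast_to(self.mate[:, None], (n, L))
        rev = np.broadcast_to(self.reverse[:, None], (n, L))
        return ObservationBatch(
            mate=mate.ravel(), cycle=cycle.ravel(), base=mach.ravel(),
            prev=prev.ravel(), qual=qual_m.ravel(), reverse=rev.ravel(),
            read_pos=cycle.ravel(), ref_pos=rpos_m.ravel().astype(np.int32),
            mismatch=mismatch_m.ravel())

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                seq = self.seq[i]
                qual = self.qual[i]
                if self.reverse[i]:
                    seq = complement_codes(seq)[::-1]
                    qual = qual[::-1]
                name = f"frag{self.frag[i]}/{self.mate[i]}"
                fh.write(f"@{name}\n{decode_sequence(seq)}\n+\n"
                         + "".join(chr(q + 33) for q in qual) + "\n")

    def to_sam(self, path, reference_name: str = "sim") -> None:
        """Coordinate-sorted SAM/BAM against the extended template."""
        L = self.read_length
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": reference_name,
                          "LN": self.genome_length + self.extension}]}
        order = np.argsort(self.start, kind="stable")
        mode = "wb" if str(path).endswith(".bam") else "wh"
        paired = bool((self.mate == 2).any())
        mate_start = {}
        if paired:
            for i in range(self.n_reads):
                mate_start[(int(self.frag[i]), int(self.mate[i]))] = int(self.start[i])
        with pysam.AlignmentFile(str(path), mode, header=header) as out:
            for i in order:
                a = pysam.AlignedSegment()
                a.query_name = f"frag{self.frag[i]}"
                flag = 0
                if paired:
                    flag |= 0x1 | 0x2
                    flag |= 0x40 if self.mate[i] == 1 else 0x80
                if self.reverse[i]:
                    flag |= 0x10
                if paired and not self.reverse[i]:
                    flag |= 0x20     # mate of a forward read is reverse
                a.flag = flag
                a.reference_id = 0
                a.reference_start = int(self.start[i])
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_sequence = decode_sequence(self.seq[i])
                a.query_qualities = [int(q) for q in self.qual[i]]
                if paired:
                    other = mate_start.get(
                        (int(self.frag[i]), 2 if self.mate[i] == 1 else 1))
                    if other is not None:
                        a.next_reference_id = 0
                        a.next_reference_start = other
                        tlen = (other + L) - int(self.start[i]) if other >= self.start[i] \
                            else other - (int(self.start[i]) + L)
                        a.template_length = tlen
                out.write(a)

    @classmethod
    def from_sam(cls, path, genome_length: int, extension: int = DEFAULT_EXTENSION) -> "ReadSet":
        """Load ungapped simulator-style alignments back into a ReadSet
        (reads with indels or clipping are rejected)."""
        starts, revs, mates, frags, seqs, quals = [], [], [], [], [], []
        mode = "rb" if str(path).endswith(".bam") else "r"
        frag_ids: dict = {}
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for r in af.fetch(until_eof=True):
                if r.is_unmapped or r.is_secondary or r.is_supplementary:
                    continue
                if len(r.cigartuples) != 1 or r.cigartuples[0][0] != 0:
                    raise ValueError("ReadSet.from_sam requires ungapped reads")
                starts.append(r.reference_start)
                revs.append(r.is_reverse)
                mates.append(2 if r.is_read2 else 1)
                frags.append(frag_ids.setdefault(r.query_name, len(frag_ids)))
                seqs.append(encode_sequence(r.query_sequence))
                quals.append(np.asarray(r.query_qualities, dtype=np.uint8))
        seq = np.vstack(seqs) if seqs else np.empty((0, 0), dtype=np.uint8)
        qual = np.vstack(quals) if quals else np.empty((0, 0), dtype=np.uint8)
        return cls(starts, revs, mates, frags, seq, qual,
                   np.zeros_like(seq, dtype=bool), genome_length, extension)


def _sample_spectrum(rng, true_codes, spectrum) -> np.ndarray:
    """Substituted base codes for error positions."""
    if spectrum is None:
        shift = rng.integers(1, 4, size=true_codes.shape)
        return ((true_codes.astype(np.int64) + shift) % 4).astype(np.uint8)
    cum = np.cumsum(spectrum, axis=1)
    u = rng.random(true_codes.shape)
    pick = (u[:, None] > cum[true_codes]).sum(axis=1)
    return pick.astype(np.uint8)


def simulate_reads(template: str, profile: ErrorProfile, coverage: float,
                   read_length: int = 100, paired: bool = True,
                   fragment_mean: float = 300.0, fragment_sd: float = 30.0,
                   extension: int = DEFAULT_EXTENSION, seed: int = 0) -> ReadSet:
    """Simulate reads uniformly over the circularised template.

    Coverage is the expected per-site depth; fragments start uniformly on
    the genome and extend into the appended first-``extension``-bases copy,
    so circular coverage is uniform.  Deterministic per seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    G = len(template)
    if G <= read_length:
        raise ValueError("template must be longer than the read length")
    ext = min(extension, G)
    codes_ext = encode_sequence(template + template[:ext])
    rng = np.random.default_rng(seed)
    L = read_length

    reads_per_frag = 2 if paired else 1
    n_frag = max(int(round(coverage * G / (L * reads_per_frag))), 1)
    fstart = rng.integers(0, G, size=n_frag).astype(np.int64)
    if paired:
        flen = np.clip(np.rint(rng.normal(fragment_mean, fragment_sd, n_frag)),
                       L, ext).astype(np.int64)
        start = np.concatenate([fstart, fstart + flen - L])
        reverse = np.concatenate([np.zeros(n_frag, bool), np.ones(n_frag, bool)])
        mate = np.concatenate([np.ones(n_frag, np.int8), np.full(n_frag, 2, np.int8)])
        frag = np.concatenate([np.arange(n_frag), np.arange(n_frag)])
    else:
        start = fstart
        reverse = rng.random(n_frag) < 0.5
        mate = np.ones(n_frag, np.int8)
        frag = np.arange(n_frag)
    n = start.shape[0]

    pos = start[:, None] + np.arange(L, dtype=np.int64)
    true_ref = codes_ext[pos]                       # reference orientation
    # machine orientation
    true_m = np.where(reverse[:, None],
                      complement_codes(true_ref.ravel()).reshape(n, L)[:, ::-1],
                      true_ref)
    prev_m = np.concatenate(
        [np.full((n, 1), START_CODE, dtype=np.uint8), true_m[:, :-1]], axis=1)

    levels = np.asarray(profile.quality_levels, dtype=np.int16)
    cumw = np.cumsum(np.asarray(profile.level_weights, dtype=float))
    lvl = np.searchsorted(cumw, rng.random((n, L)), side="right")
    lvl = np.minimum(lvl, len(levels) - 1)
    if profile.cycle_downgrade > 0 and L > 1:
        cyc_frac = np.arange(L, dtype=float) / (L - 1)
        down = rng.random((n, L)) < profile.cycle_downgrade * cyc_frac
        lvl = np.where(down, np.maximum(lvl - 1, 0), lvl)
    q_nom = levels[lvl]

    if profile.fixed_error is not None:
        eps_true = np.full((n, L), profile.fixed_error)
    else:
        cyc_frac = (np.arange(L, dtype=float) / (L - 1)) if L > 1 else np.zeros(L)
        ctx = np.asarray(profile.context_factors, dtype=float)[
            np.minimum(prev_m, 4), np.minimum(true_m, 3)]
        eps_true = (10.0 ** (-q_nom / 10.0)
                    + ctx * (profile.background_error
                             + profile.cycle_ramp * cyc_frac[None, :]))
    eps_true = np.clip(eps_true, 0.0, 0.75)

    err = rng.random((n, L)) < eps_true
    obs_m = true_m.copy()
    if err.any():
        obs_m[err] = _sample_spectrum(rng, true_m[err], profile.spectrum)

    q_emit = np.clip(np.rint(profile.emission_slope * q_nom
                             + profile.emission_offset), 2, 60).astype(np.uint8)
    if profile.pessimistic_fraction > 0:
        pess = (rng.random((n, L)) < profile.pessimistic_fraction) \
            & (q_nom >= profile.pessimistic_min_nominal)
        q_emit = np.where(pess, np.uint8(2), q_emit)

    # back to reference orientation
    seq = np.where(reverse[:, None],
                   complement_codes(obs_m.ravel()).reshape(n, L)[:, ::-1],
                   obs_m)
    qual = np.where(reverse[:, None], q_emit[:, ::-1], q_emit)
    is_err = np.where(reverse[:, None], err[:, ::-1], err)

    return ReadSet(start, reverse, mate, frag, seq.astype(np.uint8),
                   qual, is_err, G, ext)


# ---------------------------------------------------------------------------
# Template generation and pairwise truth
# ---------------------------------------------------------------------------

def generate_templates(n: int, length: int, divergence: float, seed: int = 0,
                       transition_fraction: float = 0.9,
                       indel_rate: float = 0.0,
                       max_indel_length: int = 4) -> tuple[str, list]:
    """One random ancestor plus ``n`` derived sequences.

    Each derived sequence carries Poisson(divergence * length) substitutions
    (transition-biased, as in mtDNA) and Poisson(indel_rate * length) short
    indels.  Deterministic per seed.
    """
    if not 0 <= divergence < 0.05:
        raise ValueError("divergence must lie in [0, 0.05)")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length).astype(np.uint8)
    out = []
    for _ in range(n):
        codes = anc.copy()
        n_sub = rng.poisson(divergence * length)
        if n_sub:
            sites = rng.choice(length, size=min(n_sub, length), replace=False)
            is_ti = rng.random(sites.shape[0]) < transition_fraction
            new = codes[sites].astype(np.int64)
            new[is_ti] ^= 2                          # A<->G, C<->T
            shift = rng.integers(0, 2, size=(~is_ti).sum())
            # transversion: pick one of the two non-self, non-transition bases
            tv_choices = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
            new[~is_ti] = tv_choices[codes[sites][~is_ti], shift]
            codes[sites] = new.astype(np.uint8)
        seq = list(codes)
        n_indel = rng.poisson(indel_rate * length)
        for _ in range(n_indel):
            p = int(rng.integers(0, len(seq)))
            ilen = int(rng.integers(1, max_indel_length + 1))
            if rng.random() < 0.5:
                del seq[p:p + ilen]
            else:
                seq[p:p] = list(rng.integers(0, 4, size=ilen).astype(np.uint8))
        out.append(decode_sequence(np.asarray(seq, dtype=np.uint8)))
    return decode_sequence(anc), out


@dataclass
class TemplateDiff:
    """Pairwise differences in a-coordinates (1-based)."""

    snps: list                      # (position, a_base, b_base) kept
    excluded_snps: list             # SNPs within the indel exclusion window
    indels: list                    # (position, kind '+'/'-', length)


def template_diff(template_a: str, template_b: str,
                  indel_window: int = 5) -> TemplateDiff:
    """Global pairwise alignment of two templates; SNPs within
    ``indel_window`` bp of any indel are excluded from the minor-allele
    truth list (they are misalignment-prone)."""
    if not template_a or not template_b:
        raise ValueError("templates must be non-empty")
    res = edlib.align(template_b, template_a, mode="NW", task="path")
    snps, indels = [], []
    apos = bpos = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        run = int(num)
        num = ""
        if ch in "=M":
            a_seg = template_a[apos:apos + run]
            b_seg = template_b[bpos:bpos + run]
            if a_seg != b_seg:
                seg_a = encode_sequence(a_seg)
                seg_b = encode_sequence(b_seg)
                for off in np.flatnonzero(seg_a != seg_b):
                    snps.append((apos + int(off) + 1, a_seg[off], b_seg[off]))
            apos += run
            bpos += run
        elif ch == "X":
            for off in range(run):
                snps.append((apos + off + 1, template_a[apos + off],
                             template_b[bpos + off]))
            apos += run
            bpos += run
        elif ch == "D":             # present in a, absent in b: deletion
            indels.append((apos + 1, "-", run))
            apos += run
        elif ch == "I":             # inserted in b relative to a
            indels.append((apos + 1, "+", run))
            bpos += run
        else:                       # pragma: no cover - unexpected op
            raise ValueError(f"unexpected CIGAR op {ch!r}")

    def near_indel(p: int) -> bool:
        for ip, kind, run in indels:
            lo = ip - indel_window
            hi = (ip + run - 1 if kind == "-" else ip) + indel_window
            if lo <= p <= hi:
                return True
        return False

    kept = [s for s in snps if not near_indel(s[0])]
    excl = [s for s in snps if near_indel(s[0])]
    return TemplateDiff(snps=kept, excluded_snps=excl, indels=indels)


def make_mixture(library_major: ReadSet, library_minor: ReadSet,
                 fraction: float, truth_variants, seed: int = 0
                 ) -> tuple[ReadSet, TruthSet]:
    """Mix a minor library into a major one by binomial fragment thinning.

    Every minor-library *fragment* (both mates) is included independently
    with probability ``fraction``, so realised per-site MAFs vary binomially
    around the planted value.  ``truth_variants`` are (position, major_base,
    minor_base) triples in major-template coordinates (e.g. the kept SNPs of
    :func:`template_diff`); the returned :class:`TruthSet` records realised
    counts and MAFs at those sites.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    frags = np.unique(library_minor.frag)
    frag_keep = rng.random(frags.shape[0]) < fraction
    keep = frag_keep[np.searchsorted(frags, library_minor.frag)]
    minor_kept = library_minor.subset(keep)
    mixed = ReadSet.concat(library_major, minor_kept)

    variants = []
    for pos, a_base, b_base in truth_variants:
        p0 = pos - 1
        realized = int(minor_kept.covering(p0).size)
        depth = int(library_major.covering(p0).size) + realized
        variants.append(TruthVariant(
            position=pos, major_allele=a_base, minor_allele=b_base,
            planted_fraction=fraction, realized_count=realized, depth=depth,
            realized_maf=realized / depth if depth else 0.0))
    return mixed, TruthSet(planted_fraction=fraction, variants=variants)
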