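"""SEGREG: base-quality recalibration by per-group segmented regression.

Training stratifies the bases of a spiked-in control (e.g. phiX174) into
groups keyed by (mate index, machine cycle, observed base, previous-cycle
base) — 2*R*4*4 four-valued-context groups for paired-end reads of length R,
plus the cycle-1 START-context groups.  Within a group, bases are binned by
raw phred score; each bin contributes its empirical quality

    xe_i = -10*log10((errors + 0.5) / (bases + 0.5))

weighted by its base count w_i (bins with w_i below ``min_bin_count``,
default 100, are masked).  A two-segment weighted least-squares regression

    min over a0,b0,a1,b1,bk of
        sum_{xr_i <  bk} w_i*(xe_i - a0*xr_i - b0)^2
      + sum_{xr_i >= bk} w_i*(xe_i - a1*xr_i - b1)^2

is fitted per group by exhaustive search over candidate breakpoints (the
segments are not constrained to meet at bk).  Applying the model maps each
base of the user's data to its group and evaluates the group's fitted line,
rounding to the nearest integer and clamping to [2, 60]; groups without a
usable fit fall back to the raw score.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .alignment_io import (BASES, START, START_CODE, PREV_N_CODE, PREV_LABELS,
                           BaseObservation, ObservationBatch, phred_to_error)

log = logging.getLogger(__name__)

FITTED = "FITTED"
FALLBACK = "FALLBACK"

MAX_QUALITY = 60          # highest raw phred score tracked in bins
DEFAULT_CLAMP = (2, 60)
DEFAULT_MIN_BIN_COUNT = 100


class GroupKey(NamedTuple):
    """The conditioning unit of SEGREG."""

    mate: int               # 1 or 2
    cycle: int              # >= 1
    observed_base: str      # A/C/G/T
    previous_base: str      # A/C/G/T or START (cycle 1)


def enumerate_groups(read_length: int, paired: bool = True,
                     include_start_context: bool = False) -> list[GroupKey]:
    """All possible group keys for a read structure.

    By default only the four-valued-context keys are enumerated
    (2*R*4*4 = 3200 for paired-end length 100); ``include_start_context``
    adds the cycle-1 START-context keys, which are trained like any other
    but counted separately.
    """
    mates = (1, 2) if paired else (1,)
    keys = [GroupKey(m, c, b, p)
            for m in mates
            for c in range(1, read_length + 1)
            for b in BASES
            for p in BASES]
    if include_start_context:
        keys += [GroupKey(m, 1, b, START) for m in mates for b in BASES]
    return keys


def assign_group(obs: BaseObservation) -> GroupKey:
    """Deterministic group key for one observation; base N is ineligible."""
    if obs.observed_base not in BASES:
        raise ValueError("observations with base N are ineligible for grouping")
    return GroupKey(obs.mate, obs.cycle, obs.observed_base, obs.previous_base)


def empirical_phred(error_count, base_count):
    """Empirical phred score with a +0.5 continuity pseudocount.

    ``-10*log10((errors + 0.5) / (bases + 0.5))``, clamped at 0; finite even
    for zero errors, so large zero-error bins stay usable.  Accepts scalars
    or arrays; ``base_count`` must be >= 1.
    """
    err = np.asarray(error_count, dtype=float)
    n = np.asarray(base_count, dtype=float)
    if np.any(n < 1):
        raise ValueError("base_count must be >= 1")
    val = -10.0 * np.log10((err + 0.5) / (n + 0.5))
    val = np.maximum(val, 0.0)
    return float(val) if val.ndim == 0 else val


def combine_error_rates(raw_quality, background_error: float):
    """Phred score after adding a systematic background error rate.

    ``-10*log10(10^(-q/10) + background)``: the correction for a basecaller
    that underestimates a background error, e.g. Q40 with background 1e-3
    gives 29.59 (total error rate 0.0011) while Q10 gives 9.96.
    """
    if not 0 <= background_error < 1:
        raise ValueError("background_error must be in [0, 1)")
    val = -10.0 * np.log10(phred_to_error(raw_quality) + background_error)
    return float(val) if np.ndim(val) == 0 else val


@dataclass(slots=True)
class QualityBin:
    """One (group, raw score) cell of the training table."""

    group: GroupKey
    raw_quality: int
    base_count: int
    error_count: int
    empirical_quality: float | None     # None when masked
    masked: bool

    @classmethod
    def build(cls, group, raw_quality, base_count, error_count,
              min_bin_count=DEFAULT_MIN_BIN_COUNT) -> "QualityBin":
        masked = base_count < min_bin_count
        return cls(group, int(raw_quality), int(base_count), int(error_count),
                   None if masked else float(empirical_phred(error_count, base_count)),
                   masked)


def tabulate_bins(observations, known_variant_positions=frozenset(),
                  min_bin_count: int = DEFAULT_MIN_BIN_COUNT) -> dict[GroupKey, list[QualityBin]]:
    """Tabulate per-group quality bins from training observations.

    All differences from the supplied consensus are treated as sequence
    errors; observations at ``known_variant_positions`` (1-based) are
    excluded entirely, as are observations with base N or an N context.
    Bins with fewer than ``min_bin_count`` bases are marked masked.
    """
    if not isinstance(observations, ObservationBatch):
        observations = ObservationBatch.from_observations(observations)
    if len(observations) == 0:
        raise ValueError("empty training data")
    keep = observations.eligible
    if known_variant_positions:
        excl = np.asarray(sorted(known_variant_positions), dtype=np.int64) - 1
        keep &= ~np.isin(observations.ref_pos, excl)
    batch = observations.subset(keep)

    n_cycles = int(batch.cycle.max()) if len(batch) else 0
    bins: dict[GroupKey, list[QualityBin]] = {}
    if n_cycles == 0:
        return bins
    # flat index: (((mate-1)*C + cycle-1)*4 + base)*5 + prev, then * quality
    grp = (((batch.mate.astype(np.int64) - 1) * n_cycles + batch.cycle - 1) * 4
           + batch.base) * 5 + np.minimum(batch.prev, 4)
    q = np.clip(batch.qual.astype(np.int64), 0, MAX_QUALITY)
    flat = grp * (MAX_QUALITY + 1) + q
    size = 2 * n_cycles * 4 * 5 * (MAX_QUALITY + 1)
    counts = np.bincount(flat, minlength=size)
    errors = np.bincount(flat[batch.mismatch], minlength=size)

    nz = np.flatnonzero(counts)
    for idx in nz:
        g, qv = divmod(int(idx), MAX_QUALITY + 1)
        g, prev = divmod(g, 5)
        g, base = divmod(g, 4)
        mate, cyc = divmod(g, n_cycles)
        key = GroupKey(mate + 1, cyc + 1, BASES[base], PREV_LABELS[prev])
        bins.setdefault(key, []).append(
            QualityBin.build(key, qv, counts[idx], errors[idx], min_bin_count))
    for blist in bins.values():
        blist.sort(key=lambda b: b.raw_quality)
    return bins


@dataclass(slots=True)
class SegmentedFit:
    """Two weighted least-squares lines split at breakpoint ``bk``."""

    a0: float = 1.0
    b0: float = 0.0
    a1: float = 1.0
    b1: float = 0.0
    bk: float = 0.0
    sse: float = float("nan")
    status: str = FALLBACK

    def predict(self, raw_quality):
        """Unrounded recalibrated value; FALLBACK returns the input."""
        q = np.asarray(raw_quality, dtype=float)
        if self.status != FITTED:
            out = q
        else:
            out = np.where(q < self.bk, self.a0 * q + self.b0,
                           self.a1 * q + self.b1)
        return float(out) if out.ndim == 0 else out


def _wls_line(sw, swx, swy, swxx, swxy, swyy):
    """Closed-form weighted least squares; returns (a, b, sse)."""
    denom = sw * swxx - swx * swx
    if denom <= 0:
        # all x identical: flat line through the weighted mean
        a, b = 0.0, swy / sw
    else:
        a = (sw * swxy - swx * swy) / denom
        b = (swy - a * swx) / sw
    sse = (swyy - 2 * a * swxy - 2 * b * swy + a * a * swxx
           + 2 * a * b * swx + b * b * sw)
    return a, b, max(sse, 0.0)


def fit_segmented(bins: Iterable[QualityBin],
                  min_bin_count: int = DEFAULT_MIN_BIN_COUNT) -> SegmentedFit:
    """Fit the two-segment weighted regression for one group.

    Masked bins (base_count < min_bin_count) are excluded first.  Candidate
    breakpoints are the midpoints between consecutive distinct raw scores
    with at least two usable bins on each side; the globally minimal
    weighted SSE wins, ties broken by the smaller breakpoint.  Fewer than 4
    usable bins yields a FALLBACK fit (raw scores pass through unchanged).
    """
    usable = [b for b in bins if b.base_count >= min_bin_count]
    if len(usable) < 4:
        return SegmentedFit(status=FALLBACK)
    usable.sort(key=lambda b: b.raw_quality)
    x = np.array([b.raw_quality for b in usable], dtype=float)
    y = np.array([b.empirical_quality if b.empirical_quality is not None
                  else empirical_phred(b.error_count, b.base_count)
                  for b in usable], dtype=float)
    w = np.array([b.base_count for b in usable], dtype=float)

    csw = np.concatenate([[0.0], np.cumsum(w)])
    cswx = np.concatenate([[0.0], np.cumsum(w * x)])
    cswy = np.concatenate([[0.0], np.cumsum(w * y)])
    cswxx = np.concatenate([[0.0], np.cumsum(w * x * x)])
    cswxy = np.concatenate([[0.0], np.cumsum(w * x * y)])
    cswyy = np.concatenate([[0.0], np.cumsum(w * y * y)])
    tot = len(usable)

    def side(lo, hi):
        return _wls_line(csw[hi] - csw[lo], cswx[hi] - cswx[lo],
                         cswy[hi] - cswy[lo], cswxx[hi] - cswxx[lo],
                         cswxy[hi] - cswxy[lo], cswyy[hi] - cswyy[lo])

    best = None
    for s in range(2, tot - 1):          # >= 2 bins on each side
        bk = 0.5 * (x[s - 1] + x[s])
        a0, b0, sse0 = side(0, s)
        a1, b1, sse1 = side(s, tot)
        sse = sse0 + sse1
        if best is None or sse < best.sse - 1e-9 * max(1.0, best.sse):
            best = SegmentedFit(float(a0), float(b0), float(a1),
                                float(b1), float(bk), float(sse), FITTED)
    return best


class RecalibrationModel:
    """The trained SEGREG artifact: one :class:`SegmentedFit` per group.

    Serialises losslessly to a tab-separated text table, one row per group,
    with ``#key=value`` header lines carrying the training parameters.
    """

    def __init__(self, fits: dict[GroupKey, SegmentedFit],
                 min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
                 clamp: tuple[int, int] = DEFAULT_CLAMP,
                 metadata: dict | None = None):
        self.fits = fits
        self.min_bin_count = int(min_bin_count)
        self.clamp = (int(clamp[0]), int(clamp[1]))
        self.metadata = dict(metadata or {})
        self.fallback_events = 0
        self._table = None
        self._warned_unseen = False

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_fitted(self) -> int:
        return sum(1 for f in self.fits.values() if f.status == FITTED)

    @property
    def n_fallback(self) -> int:
        return sum(1 for f in self.fits.values() if f.status != FITTED)

    def max_cycle(self) -> int:
        return max((k.cycle for k in self.fits), default=0)

    # -- application ---------------------------------------------------
    def recalibrate(self, group: GroupKey, raw_quality: int) -> int:
        """Recalibrated integer phred for one base (clamped to the model's
        output range); FALLBACK/unknown groups return the raw score."""
        fit = self.fits.get(group)
        if fit is None or fit.status != FITTED:
            self.fallback_events += 1
            return int(raw_quality)
        val = fit.predict(float(raw_quality))
        return int(np.clip(np.floor(val + 0.5), self.clamp[0], self.clamp[1]))

    def lookup_table(self) -> np.ndarray:
        """Dense int16 table ``[mate-1, cycle-1, base, prev, raw_q] -> recal_q``
        for vectorised application; unfitted cells hold the raw score."""
        if self._table is not None:
            return self._table
        n_cycles = self.max_cycle()
        qs = np.arange(MAX_QUALITY + 1, dtype=float)
        table = np.broadcast_to(
            qs.astype(np.int16), (2, n_cycles, 4, 5, MAX_QUALITY + 1)).copy()
        bidx = {b: i for i, b in enumerate(BASES)}
        pidx = {**{b: i for i, b in enumerate(BASES)}, START: START_CODE}
        for key, fit in self.fits.items():
            if fit.status != FITTED:
                continue
            vals = np.clip(np.floor(fit.predict(qs) + 0.5),
                           self.clamp[0], self.clamp[1]).astype(np.int16)
            table[key.mate - 1, key.cycle - 1, bidx[key.observed_base],
                  pidx[key.previous_base]] = vals
        self._table = table
        return table

    def recalibrate_batch(self, batch: ObservationBatch) -> np.ndarray:
        """Vectorised recalibrated qualities for a batch; bases at unseen
        cycles, N bases and N contexts fall back to the raw score."""
        table = self.lookup_table()
        n_cycles = table.shape[1]
        out = batch.qual.astype(np.int16).copy()
        ok = (batch.base < 4) & (batch.prev <= START_CODE) & \
             (batch.cycle >= 1) & (batch.cycle <= n_cycles) & \
             (batch.qual >= 0) & (batch.qual <= MAX_QUALITY)
        if not ok.all() and not self._warned_unseen:
            log.warning("%d bases at unseen cycles or with N context kept raw",
                        int((~ok).sum()))
            self._warned_unseen = True
        out[ok] = table[batch.mate[ok] - 1, batch.cycle[ok] - 1,
                        batch.base[ok], batch.prev[ok], batch.qual[ok]]
        return out

    # -- serialisation -------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#segreg_model\tv1\n")
            fh.write(f"#min_bin_count={self.min_bin_count}\n")
            fh.write(f"#clamp={self.clamp[0]},{self.clamp[1]}\n")
            for k, v in sorted(self.metadata.items()):
                fh.write(f"#meta:{k}={v}\n")
            fh.write("mate\tcycle\tbase\tprev\ta0\tb0\ta1\tb1\tbk\tsse\tstatus\n")
            for key in sorted(self.fits):
                f = self.fits[key]
                fh.write(f"{key.mate}\t{key.cycle}\t{key.observed_base}\t"
                         f"{key.previous_base}\t{float(f.a0)!r}\t"
                         f"{float(f.b0)!r}\t{float(f.a1)!r}\t{float(f.b1)!r}\t"
                         f"{float(f.bk)!r}\t{float(f.sse)!r}\t{f.status}\n")

    @classmethod
    def load(cls, path) -> "RecalibrationModel":
        fits: dict[GroupKey, SegmentedFit] = {}
        min_bin_count = DEFAULT_MIN_BIN_COUNT
        clamp = DEFAULT_CLAMP
        metadata: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if line.startswith("#min_bin_count="):
                        min_bin_count = int(line.split("=", 1)[1])
                    elif line.startswith("#clamp="):
                        lo, hi = line.split("=", 1)[1].split(",")
                        clamp = (int(lo), int(hi))
                    elif line.startswith("#meta:"):
                        k, v = line[len("#meta:"):].split("=", 1)
                        metadata[k] = v
                    continue
                if line.startswith("mate\t") or not line:
                    continue
                parts = line.split("\t")
                key = GroupKey(int(parts[0]), int(parts[1]), parts[2], parts[3])
                fits[key] = SegmentedFit(float(parts[4]), float(parts[5]),
                                         float(parts[6]), float(parts[7]),
                                         float(parts[8]), float(parts[9]),
                                         parts[10])
        return cls(fits, min_bin_count=min_bin_count, clamp=clamp,
                   metadata=metadata)


def recalibrate_quality(group: GroupKey, raw_quality: int,
                        model: RecalibrationModel) -> int:
    """Functional wrapper around :meth:`RecalibrationModel.recalibrate`."""
    return model.recalibrate(group, raw_quality)


def train_model(control_alignments, control_consensus,
                known_variant_positions=frozenset(), *,
                min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
                clamp: tuple[int, int] = DEFAULT_CLAMP,
                metadata: dict | None = None) -> RecalibrationModel:
    """Train SEGREG on a control-sequence alignment.

    ``control_alignments`` may be a SAM/BAM path, an open AlignmentFile, or a
    ready-made :class:`ObservationBatch` (whose mismatch flags must already be
    relative to the control consensus).  ``control_consensus`` is the control
    sequence string (or ``{contig: sequence}``).
    """
    if isinstance(control_alignments, ObservationBatch):
        batch = control_alignments
        source = "<in-memory batch>"
    else:
        batch = ObservationBatch.from_alignments(control_alignments,
                                                 control_consensus)
        source = str(control_alignments)
    if len(batch) == 0:
        raise ValueError("control alignments are empty")
    bins = tabulate_bins(batch, known_variant_positions,
                         min_bin_count=min_bin_count)
    fits = {key: fit_segmented(blist, min_bin_count=min_bin_count)
            for key, blist in bins.items()}
    meta = {
        "training_file": source,
        "date": datetime.date.today().isoformat(),
        "n_observations": len(batch),
        "n_known_variants_excluded": len(known_variant_positions),
    }
    meta.update(metadata or {})
    model = RecalibrationModel(fits, min_bin_count=min_bin_count, clamp=clamp,
                               metadata=meta)
    log.info("trained %d groups (%d fitted, %d fallback)",
             len(fits), model.n_fitted, model.n_fallback)
    return model


def apply_to_alignments(alignments_in, alignments_out,
                        model: RecalibrationModel,
                        original_quality_tag: str | None = "OQ") -> dict:
    """Rewrite alignments with recalibrated base qualities.

    Every base of every read (including soft-clipped bases) is assigned to
    its group from the read's own sequence and mate/strand flags — no
    reference is needed at application time.  All other fields are preserved;
    the original qualities are kept in ``original_quality_tag`` unless None.
    Reads longer than the training read length keep raw scores at unseen
    cycles (warned once).
    """
    import pysam
    from .alignment_io import BASE_CODES, N_CODE, _open_alignments

    table = model.lookup_table()
    n_cycles = table.shape[1]
    warned = False
    stats = {"reads": 0, "bases": 0}

    af, _ = _open_alignments(alignments_in)
    out_path = str(alignments_out)
    mode = "wb" if out_path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(out_path, mode, header=af.header) as out:
        for read in af.fetch(until_eof=True):
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None or read.is_secondary or read.is_supplementary:
                out.write(read)
                continue
            qlen = len(seq)
            codes = np.array([BASE_CODES.get(b, N_CODE) for b in seq], dtype=np.int64)
            if read.is_reverse:
                mach = np.where(codes < 4, 3 - codes, N_CODE)[::-1]
            else:
                mach = codes
            prev = np.concatenate([[START_CODE], mach[:-1]])
            prev = np.where(prev == N_CODE, PREV_N_CODE, prev)
            cycles = np.arange(1, qlen + 1)
            q = np.asarray(quals, dtype=np.int64)
            qm = q[::-1] if read.is_reverse else q      # machine order
            mate = 2 if read.is_read2 else 1
            new = qm.astype(np.int16).copy()
            ok = (mach < 4) & (prev <= START_CODE) & (cycles <= n_cycles) & \
                 (qm <= MAX_QUALITY)
            if cycles.max() > n_cycles and not warned:
                warnings.warn("reads longer than the training read length: "
                              "bases at unseen cycles keep raw qualities")
                warned = True
            new[ok] = table[mate - 1, cycles[ok] - 1, mach[ok], prev[ok], qm[ok]]
            if read.is_reverse:
                new = new[::-1]
            stats["reads"] += 1
            stats["bases"] += qlen
            if original_quality_tag:
                read.set_tag(original_quality_tag,
                             pysam.qualities_to_qualitystring(quals))
            read.query_qualities = [int(v) for v in new]
            out.write(read)
    af.close()
    return stats
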