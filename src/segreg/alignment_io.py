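"""Sequence/alignment I/O and per-base observation extraction.

This module turns coordinate-sorted SAM/BAM alignments into the per-base
observations that drive recalibration training, builds quality-aware pileups
for minor-allele calling, calls a majority consensus, and implements the
circular-genome coordinate convention (a copy of the first ``extension``
bases appended to the reference, with read pairs that fall entirely inside
the artificial repeat moved back to the genome start).

Conventions
-----------
* Machine cycle is counted in sequencing order: for reverse-strand
  alignments the cycle runs from the right end of the stored (reference
  oriented) sequence, and observed/previous bases are complemented so that
  they are the bases the sequencer actually called.
* Coordinates are 0-based half-open internally; 1-based in all reports.
* Only proper pairs are consumed from paired-end data (single-end reads are
  consumed unconditionally); no mapping-quality cutoff is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

BASES = "ACGT"
#: integer codes: A=0, C=1, G=2, T=3, N=4
BASE_CODES = {b: i for i, b in enumerate("ACGTN")}
N_CODE = 4
#: previous-base code space: A..T = 0..3, START sentinel = 4, N = 5 (ineligible)
START = "START"
START_CODE = 4
PREV_N_CODE = 5
PREV_LABELS = ("A", "C", "G", "T", START, "N")

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0..T=3, anything else=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement base codes; N (4) maps to itself."""
    out = 3 - codes.astype(np.int16)
    out[codes >= 4] = N_CODE
    return out.astype(np.uint8)


def phred_to_error(q) :
    """Error probability for a phred score: epsilon = 10^(-q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def error_to_phred(e):
    return -10.0 * np.log10(np.asarray(e, dtype=float))


# ---------------------------------------------------------------------------
# FASTA / position-list helpers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_positions(path) -> set:
    """Read a known-variant mask: 1-based positions, one per line, optionally
    preceded by a chromosome column (``chrom<TAB>pos``)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fieldsplit = line.split("\t")
            out.add(int(fieldsplit[-1]))
    return out


# ---------------------------------------------------------------------------
# Base observations
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class BaseObservation:
    """One aligned, non-clipped base, in sequencing (machine) orientation.

    ``observed_base`` and ``previous_base`` are the bases the machine called
    (complemented relative to the stored sequence for reverse-strand reads);
    ``is_mismatch`` compares the reference-oriented base to the reference.
    """

    mate: int                       # 1 or 2
    cycle: int                      # >= 1, sequencing order
    observed_base: str              # A/C/G/T/N
    previous_base: str              # A/C/G/T/START (N if previous call was N)
    raw_quality: int
    strand: str                     # "forward" / "reverse"
    read_position: int              # position within the read (== cycle)
    reference_position: int         # 1-based
    is_mismatch: bool


class ObservationBatch:
    """Columnar container of base observations (the fast in-memory currency).

    Arrays (all length n): ``mate`` int8, ``cycle`` int32, ``base`` uint8
    (machine orientation), ``prev`` uint8 (machine orientation, START=4, N=5),
    ``qual`` int16, ``reverse`` bool, ``read_pos`` int32, ``ref_pos`` int32
    (0-based), ``mismatch`` bool.
    """

    __slots__ = ("mate", "cycle", "base", "prev", "qual", "reverse",
                 "read_pos", "ref_pos", "mismatch")

    def __init__(self, mate, cycle, base, prev, qual, reverse, read_pos,
                 ref_pos, mismatch):
        self.mate = np.asarray(mate, dtype=np.int8)
        self.cycle = np.asarray(cycle, dtype=np.int32)
        self.base = np.asarray(base, dtype=np.uint8)
        self.prev = np.asarray(prev, dtype=np.uint8)
        self.qual = np.asarray(qual, dtype=np.int16)
        self.reverse = np.asarray(reverse, dtype=bool)
        self.read_pos = np.asarray(read_pos, dtype=np.int32)
        self.ref_pos = np.asarray(ref_pos, dtype=np.int32)
        self.mismatch = np.asarray(mismatch, dtype=bool)

    def __len__(self) -> int:
        return self.mate.shape[0]

    @property
    def allele(self) -> np.ndarray:
        """Reference-oriented base codes (machine base complemented on reverse)."""
        out = self.base.copy()
        rev = self.reverse & (self.base < 4)
        out[rev] = 3 - self.base[rev]
        return out

    @property
    def eligible(self) -> np.ndarray:
        """Mask of observations usable for training (no N base / N context)."""
        return (self.base < 4) & (self.prev != PREV_N_CODE)

    def subset(self, mask) -> "ObservationBatch":
        return ObservationBatch(*(getattr(self, a)[mask] for a in self.__slots__))

    def with_qualities(self, qual) -> "ObservationBatch":
        """Copy of the batch with replaced quality scores (e.g. recalibrated)."""
        return ObservationBatch(self.mate, self.cycle, self.base, self.prev,
                                np.asarray(qual), self.reverse, self.read_pos,
                                self.ref_pos, self.mismatch)

    @classmethod
    def from_observations(cls, observations: Iterable[BaseObservation]) -> "ObservationBatch":
        rows = list(observations)
        prev_code = {**{b: i for i, b in enumerate(BASES)}, START: START_CODE, "N": PREV_N_CODE}
        return cls(
            mate=[o.mate for o in rows],
            cycle=[o.cycle for o in rows],
            base=[BASE_CODES[o.observed_base] for o in rows],
            prev=[prev_code[o.previous_base] for o in rows],
            qual=[o.raw_quality for o in rows],
            reverse=[o.strand == "reverse" for o in rows],
            read_pos=[o.read_position for o in rows],
            ref_pos=[o.reference_position - 1 for o in rows],
            mismatch=[o.is_mismatch for o in rows],
        )

    @classmethod
    def from_alignments(cls, alignments, reference) -> "ObservationBatch":
        return cls.from_observations(stream_observations(alignments, reference))

    def to_observations(self) -> Iterator[BaseObservation]:
        for i in range(len(self)):
            yield BaseObservation(
                mate=int(self.mate[i]),
                cycle=int(self.cycle[i]),
                observed_base="ACGTN"[self.base[i]],
                previous_base=PREV_LABELS[self.prev[i]],
                raw_quality=int(self.qual[i]),
                strand="reverse" if self.reverse[i] else "forward",
                read_position=int(self.read_pos[i]),
                reference_position=int(self.ref_pos[i]) + 1,
                is_mismatch=bool(self.mismatch[i]),
            )


def _open_alignments(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    path = str(alignments)
    mode = "rb" if path.endswith(".bam") else "r"
    return pysam.AlignmentFile(path, mode, check_sq=False), True


def _reference_map(reference, alignment_file) -> dict:
    """Normalise the reference argument to {contig: encoded array}."""
    if isinstance(reference, Mapping):
        return {name: encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq)
                for name, seq in reference.items()}
    # single sequence: attach it to every contig declared in the header
    enc = encode_sequence(reference) if isinstance(reference, str) else np.asarray(reference)
    names = list(alignment_file.references) or ["*"]
    return {name: enc for name in names}


def stream_observations(alignments, reference) -> Iterator[BaseObservation]:
    """Yield one :class:`BaseObservation` per aligned, non-clipped base.

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``;
    ``reference`` is a sequence string (single-contig shortcut) or a mapping
    ``{contig: sequence}``.  Insertions contribute no observation (the inserted
    bases are skipped), deletions likewise; soft-clipped bases are excluded.
    Reads flagged as PCR/optical duplicates are consumed but trigger a single
    warning, since duplicate removal is an upstream responsibility.
    """
    af, owned = _open_alignments(alignments)
    refs = _reference_map(reference, af)
    dup_warned = False
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired and not read.is_proper_pair:
                continue
            if read.is_duplicate and not dup_warned:
                warnings.warn("alignments contain reads flagged as duplicates; "
                              "duplicate removal is expected upstream")
                dup_warned = True
            if read.reference_name not in refs:
                raise KeyError(f"reference contig {read.reference_name!r} not supplied")
            ref = refs[read.reference_name]
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            qlen = len(seq)
            mate = 2 if read.is_read2 else 1
            rev = read.is_reverse
            strand = "reverse" if rev else "forward"
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                obs_ref_code = BASE_CODES.get(seq[qpos], N_CODE)
                if rev:
                    cycle = qlen - qpos
                    mach = 3 - obs_ref_code if obs_ref_code < 4 else N_CODE
                    if qpos == qlen - 1:
                        prev = START
                    else:
                        pc = BASE_CODES.get(seq[qpos + 1], N_CODE)
                        prev = "ACGTN"[3 - pc] if pc < 4 else "N"
                else:
                    cycle = qpos + 1
                    mach = obs_ref_code
                    if qpos == 0:
                        prev = START
                    else:
                        prev = seq[qpos - 1] if seq[qpos - 1] in BASE_CODES else "N"
                ref_code = ref[rpos] if rpos < len(ref) else N_CODE
                mismatch = bool(obs_ref_code < 4 and ref_code < 4 and obs_ref_code != ref_code)
                yield BaseObservation(
                    mate=mate,
                    cycle=cycle,
                    observed_base="ACGTN"[mach],
                    previous_base=prev,
                    raw_quality=int(quals[qpos]),
                    strand=strand,
                    read_position=cycle,
                    reference_position=rpos + 1,
                    is_mismatch=mismatch,
                )
    finally:
        if owned:
            af.close()


# ---------------------------------------------------------------------------
# Pileups and consensus
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PileupSite:
    """Per-position tallies: reference-oriented alleles with strand, quality
    and read-position annotations, one entry per counted base."""

    position: int                   # 1-based
    ref_base: str
    allele: np.ndarray              # uint8 codes, reference oriented
    is_reverse: np.ndarray          # bool per counted base
    qual: np.ndarray                # int16 per counted base
    read_pos: np.ndarray            # int32 per counted base

    @property
    def depth(self) -> int:
        return int(self.allele.shape[0])

    def counts(self) -> np.ndarray:
        """(4, 2) array of per-allele counts split by strand (fwd, rev)."""
        flat = np.bincount(self.allele.astype(np.int64) * 2 + self.is_reverse,
                           minlength=8)
        return flat.reshape(4, 2)

    def allele_counts(self) -> np.ndarray:
        return self.counts().sum(axis=1)


class Pileup:
    """Quality-filtered pileup over a reference, backed by position-sorted
    columnar arrays; sites with zero counted depth are omitted."""

    def __init__(self, positions, offsets, allele, is_reverse, qual, read_pos,
                 reference_codes, min_quality):
        self.positions = positions          # 0-based, unique, sorted
        self._offsets = offsets             # len(positions)+1 slice bounds
        self._allele = allele
        self._reverse = is_reverse
        self._qual = qual
        self._read_pos = read_pos
        self.reference_codes = reference_codes
        self.min_quality = min_quality

    @classmethod
    def from_batch(cls, batch: ObservationBatch, reference, min_quality: int = 20) -> "Pileup":
        if min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        ref_codes = encode_sequence(reference) if isinstance(reference, str) else np.asarray(reference)
        allele = batch.allele
        keep = (batch.qual >= min_quality) & (allele < 4)
        pos = batch.ref_pos[keep]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        positions, starts = np.unique(pos, return_index=True)
        offsets = np.append(starts, pos.shape[0])
        return cls(positions, offsets, allele[keep][order],
                   batch.reverse[keep][order], batch.qual[keep][order],
                   batch.read_pos[keep][order], ref_codes, min_quality)

    def __len__(self) -> int:
        return int(self.positions.shape[0])

    def site(self, i: int) -> PileupSite:
        a, b = self._offsets[i], self._offsets[i + 1]
        p = int(self.positions[i])
        return PileupSite(
            position=p + 1,
            ref_base="ACGTN"[self.reference_codes[p]] if p < len(self.reference_codes) else "N",
            allele=self._allele[a:b],
            is_reverse=self._reverse[a:b],
            qual=self._qual[a:b],
            read_pos=self._read_pos[a:b],
        )

    def __iter__(self) -> Iterator[PileupSite]:
        for i in range(len(self)):
            yield self.site(i)


def build_pileup(alignments, reference, min_quality: int = 20) -> Pileup:
    """Build a pileup from alignments, excluding bases below ``min_quality``
    from counts and quality lists alike."""
    batch = ObservationBatch.from_alignments(alignments, reference)
    ref = reference if not isinstance(reference, Mapping) else next(iter(reference.values()))
    return Pileup.from_batch(batch, ref, min_quality=min_quality)


@dataclass
class ConsensusResult:
    sequence: str
    #: 1-based positions with no counted coverage (reference base used)
    uncovered: list = field(default_factory=list)


def call_consensus(pileup: Pileup) -> ConsensusResult:
    """Majority-allele consensus; ties broken by fixed base order A<C<G<T,
    uncovered positions take the reference base and are flagged."""
    if len(pileup) == 0:
        raise ValueError("cannot call a consensus from an empty pileup")
    codes = pileup.reference_codes.copy()
    covered = np.zeros(len(codes), dtype=bool)
    for site in pileup:
        counts = site.allele_counts()
        # argmax returns the first (lowest code) maximum: the A<C<G<T tie-break
        codes[site.position - 1] = int(np.argmax(counts))
        covered[site.position - 1] = True
    uncovered = [int(p) + 1 for p in np.flatnonzero(~covered)]
    return ConsensusResult(sequence=decode_sequence(codes), uncovered=uncovered)


# ---------------------------------------------------------------------------
# Circular-genome coordinate handling
# ---------------------------------------------------------------------------

def relocate_circular_reads(alignments_in, alignments_out, genome_length: int,
                            extension_length: int = 1000) -> int:
    """Move read pairs mapped entirely inside the artificial repeat region
    ``[genome_length, genome_length + extension_length)`` back to the
    corresponding position at the genome start, and re-sort.

    Junction-spanning reads (or pairs with only one mate in the repeat) are
    left in extended coordinates.  Returns the number of relocated reads.
    The operation is idempotent.
    """
    af, _ = _open_alignments(alignments_in)
    reads = list(af.fetch(until_eof=True))
    header = af.header.to_dict()
    af.close()

    limit = genome_length + extension_length

    def span_in_repeat(start: int, end: int) -> bool:
        return start >= genome_length and end <= limit

    ends = {}
    for r in reads:
        if r.is_unmapped:
            continue
        if r.reference_end is not None and r.reference_end > limit:
            raise ValueError(
                f"read {r.query_name} extends past the extended reference end "
                f"({r.reference_end} > {limit})")
        ends.setdefault(r.query_name, {})[2 if r.is_read2 else 1] = (
            r.reference_start, r.reference_end)

    moved = 0
    for r in reads:
        if r.is_unmapped:
            continue
        segs = ends[r.query_name]
        if r.is_paired:
            if len(segs) < 2:            # mate not in file: leave untouched
                continue
            relocate = all(span_in_repeat(s, e) for s, e in segs.values())
        else:
            relocate = span_in_repeat(r.reference_start, r.reference_end)
        if relocate:
            r.reference_start -= genome_length
            if r.is_paired and r.next_reference_start >= genome_length:
                r.next_reference_start -= genome_length
            moved += 1

    reads.sort(key=lambda r: (r.reference_id, r.reference_start))
    out_path = str(alignments_out)
    mode = "wb" if out_path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(out_path, mode, header=header) as out:
        for r in reads:
            out.write(r)
    return moved
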