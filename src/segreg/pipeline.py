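"""End-to-end orchestration helpers shared by the CLI, the examples and the
evaluation studies: vectorised application of a trained model to simulated
read sets and one-call scoring of a sample against a reference."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment_io import (ObservationBatch, Pileup, complement_codes,
                           encode_sequence)
from .caller import CallThresholds, SiteCall, call_minor_alleles, _mle_from_hists
from .recalibrate import MAX_QUALITY, RecalibrationModel
from .simulate import ReadSet


def recalibrate_readset(reads: ReadSet, model: RecalibrationModel) -> ReadSet:
    """Return a copy of ``reads`` with recalibrated base qualities.

    Groups are derived from the reads' own sequences in machine orientation,
    exactly as :func:`segreg.recalibrate.apply_to_alignments` does for
    alignment files.
    """
    n, L = reads.seq.shape
    table = model.lookup_table()
    n_cycles = table.shape[1]
    rev = reads.reverse[:, None]
    mach = np.where(rev, complement_codes(reads.seq.ravel()).reshape(n, L)[:, ::-1],
                    reads.seq)
    prev = np.concatenate(
        [np.full((n, 1), 4, dtype=np.uint8), mach[:, :-1]], axis=1)
    qual_m = np.where(rev, reads.qual[:, ::-1], reads.qual)
    cycle = np.broadcast_to(np.arange(1, L + 1), (n, L))
    mate = np.broadcast_to(reads.mate[:, None], (n, L))
    new = qual_m.astype(np.int16).copy()
    ok = (mach < 4) & (prev <= 4) & (cycle <= n_cycles) & (qual_m <= MAX_QUALITY)
    new[ok] = table[mate[ok] - 1, cycle[ok] - 1, mach[ok].astype(np.int64),
                    prev[ok].astype(np.int64), qual_m[ok].astype(np.int64)]
    new_ref = np.where(rev, new[:, ::-1], new).astype(np.uint8)
    return ReadSet(reads.start, reads.reverse, reads.mate, reads.frag,
                   reads.seq, new_ref, reads.is_error, reads.genome_length,
                   reads.extension, reads.template_name)


def score_batch(batch: ObservationBatch, reference: str,
                thresholds: CallThresholds | None = None,
                masked_regions=(), filter_statistics: bool = True,
                recalibrated: bool = True) -> list[SiteCall]:
    """Pileup + minor-allele scoring of an observation batch in one call.

    The pileup keeps all bases; the caller applies the counting threshold,
    so raw- and recalibrated-quality passes over the same batch count
    different base sets, as they should.
    """
    pileup = Pileup.from_batch(batch, reference, min_quality=0)
    return call_minor_alleles(pileup, thresholds, masked_regions,
                              recalibrated=recalibrated,
                              filter_statistics=filter_statistics)


def llr_scan(batch: ObservationBatch, reference: str,
             min_base_quality: int = 20) -> pd.DataFrame:
    """Genome-wide LLR scoring of every site with a counted minor read.

    Histogram-based equivalent of the scoring part of
    :func:`segreg.caller.call_minor_alleles` (one bincount pass instead of
    per-site slicing; identical MLE/LLR values), suitable for scanning tens
    of millions of observations.  Returns a frame with 1-based ``position``,
    ``major``/``minor`` alleles, counted ``minor_count``/``major_count``/
    ``depth``, ``ml_maf`` and ``llr``.
    """
    ref = encode_sequence(reference) if isinstance(reference, str) else np.asarray(reference)
    G = int(len(ref))
    allele = batch.allele
    keep = (batch.qual >= min_base_quality) & (allele < 4) & \
           (batch.ref_pos >= 0) & (batch.ref_pos < G)
    pos = batch.ref_pos[keep].astype(np.int64)
    a = allele[keep].astype(np.int64)
    q = np.clip(batch.qual[keep].astype(np.int64), 0, 60)
    hist = np.bincount((pos * 4 + a) * 61 + q,
                       minlength=G * 4 * 61).reshape(G, 4, 61)
    totals = hist.sum(axis=2)
    depth = totals.sum(axis=1)
    major = np.argmax(totals, axis=1)
    rest = totals.copy()
    rest[np.arange(G), major] = -1
    minor = np.argmax(rest, axis=1)
    l = totals[np.arange(G), minor]
    k = totals[np.arange(G), major]
    sites = np.flatnonzero((depth > 0) & (l > 0) & (minor != major))
    rows = {"position": sites + 1,
            "major": [("ACGT")[m] for m in major[sites]],
            "minor": [("ACGT")[m] for m in minor[sites]],
            "minor_count": l[sites], "major_count": k[sites],
            "depth": depth[sites],
            "ml_maf": np.zeros(sites.size), "llr": np.zeros(sites.size)}
    for out_i, s in enumerate(sites):
        f_hat, llr_val = _mle_from_hists(hist[s, minor[s]], hist[s, major[s]])
        rows["ml_maf"][out_i] = f_hat
        rows["llr"][out_i] = llr_val
    return pd.DataFrame(rows)
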