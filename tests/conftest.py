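import numpy as np
import pysam
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160227)


@pytest.fixture
def small_reference(rng):
    """A 400 bp random reference sequence."""
    return "".join("ACGT"[c] for c in rng.integers(0, 4, 400))


@pytest.fixture
def sam_factory(tmp_path):
    """Write a hand-crafted SAM file from row dicts and return its path.

    Row keys: name, pos (0-based), seq, quals (list of ints); optional
    flag (default 0), cigar (default all-match), pnext, tlen.
    """
    def make(rows, ref_len, ref_name="ref", fname="reads.sam"):
        path = tmp_path / fname
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": ref_name, "LN": ref_len}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for r in rows:
                a = pysam.AlignedSegment()
                a.query_name = r["name"]
                a.flag = r.get("flag", 0)
                a.reference_id = 0
                a.reference_start = r["pos"]
                a.mapping_quality = 60
                a.query_sequence = r["seq"]
                a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
                a.query_qualities = r["quals"]
                if "pnext" in r:
                    a.next_reference_id = 0
                    a.next_reference_start = r["pnext"]
                    a.template_length = r.get("tlen", 0)
                fh.write(a)
        return str(path)

    return make
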