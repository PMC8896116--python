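import numpy as np
import pysam
import pytest

from fastnr import FragmentSet


def make_sam(path, records, contigs=None):
    """Write a coordinate-sorted SAM file.

    ``records`` are dicts with contig/start/end/mapq and optional
    ``paired`` (emit a proper pair spanning start..end instead of a single
    read). Unpaired reads carry a CIGAR covering the full span.
    """
    contigs = contigs or {"chr1": 100_000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in contigs.items()],
        }
    )
    names = list(contigs)
    segs = []
    for i, rec in enumerate(records):
        contig, start, end = rec["contig"], rec["start"], rec["end"]
        mapq = rec.get("mapq", 60)
        tid = names.index(contig)
        if rec.get("paired"):
            rlen = min(50, end - start)
            for mate in (0, 1):
                a = pysam.AlignedSegment(header)
                a.query_name = f"frag{i}"
                a.reference_id = tid
                a.mapping_quality = mapq
                a.query_sequence = "A" * rlen
                a.cigartuples = [(0, rlen)]
                if mate == 0:
                    a.reference_start = start
                    a.next_reference_start = end - rlen
                    a.template_length = end - start
                    a.flag = 0x1 | 0x2 | 0x40 | 0x20
                else:
                    a.reference_start = end - rlen
                    a.next_reference_start = start
                    a.template_length = -(end - start)
                    a.flag = 0x1 | 0x2 | 0x80 | 0x10
                a.next_reference_id = tid
                segs.append(a)
        else:
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{i}"
            a.reference_id = tid
            a.reference_start = start
            a.mapping_quality = mapq
            a.query_sequence = "A" * (end - start)
            a.cigartuples = [(0, end - start)]
            a.flag = 0
            segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in segs:
            out.write(a)
    return path


def frags(intervals, contig="chr1", total=None):
    """FragmentSet from a list of (start, end) pairs."""
    arr = np.array(intervals, dtype=np.int64).reshape(-1, 2)
    return FragmentSet(
        contig=contig, fragments=arr, total_count=total if total is not None else len(arr)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
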