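"""Independent oracles used by the test suite.

The brute-force tally below deliberately shares no code with the
package: it parses SAM text directly and walks every read base with a
plain Python loop, so it can serve as an exact oracle for the pileup
machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_tally(
    sam_path,
    reference: dict[str, str],
    genes: pd.DataFrame,
    min_mapq: int = 20,
) -> dict[tuple[str, int], np.ndarray]:
    """Per-position A/C/G/T counts on the transcribed strand.

    Assumes ungapped all-match alignments (CIGAR <n>M), which is what
    the simulator emits. Returns a dict keyed by (contig, 0-based pos).
    """

    def owner_of(contig: str, pos: int):
        hits = set()
        for _, g in genes.iterrows():
            if g["contig"] == contig and g["start"] <= pos < g["end"]:
                hits.add(g["strand"])
        if len(hits) != 1:
            return None  # intergenic or opposite-strand tie
        return hits.pop()

    counts: dict[tuple[str, int], np.ndarray] = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag, contig, pos1, mapq, cigar, seq = (
                int(f[1]), f[2], int(f[3]), int(f[4]), f[5], f[9],
            )
            if flag & (0x4 | 0x100 | 0x800):
                continue
            if mapq < min_mapq:
                continue
            assert cigar == f"{len(seq)}M", "oracle only handles ungapped reads"
            for i, base in enumerate(seq):
                if base == "N":
                    continue
                rpos = pos1 - 1 + i
                strand = owner_of(contig, rpos)
                if strand is None:
                    continue
                b = base if strand == "+" else _COMP[base]
                key = (contig, rpos)
                if key not in counts:
                    counts[key] = np.zeros(4, dtype=np.int64)
                counts[key][_IDX[b]] += 1
    return counts


def write_sam(path, contig, length, records):
    """Write a minimal SAM file. records: (qname, flag, pos0, mapq, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for qname, flag, pos0, mapq, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos0 + 1}\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
            )
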