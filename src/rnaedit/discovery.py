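"""Strand-aware base-count tallies and A→G candidate nomination.

The tally walks coordinate-sorted SAM/BAM files read by read (pysam),
counts bases at every position owned by an annotated gene, and
complements counts over minus-strand genes so every cell is expressed
on the transcribed strand. Stringency deliberately lives downstream in
the filter cascade: a site is nominated as a candidate as soon as its
transcribed-strand reference base is A and any sample shows a single G
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .containers import BASE_INDEX, BaseCountMatrix

logger = logging.getLogger(__name__)

__all__ = ["tally_base_counts", "nominate_candidates", "CandidateSet"]

# Owner codes for the per-contig position map.
_NONE, _PLUS, _MINUS, _TIE = 0, 1, 2, 3
# transcribed-strand base index for a plus-strand base observed over a '−' gene
_COMP_INDEX = {"A": BASE_INDEX["T"], "C": BASE_INDEX["G"],
               "G": BASE_INDEX["C"], "T": BASE_INDEX["A"]}


def _ownership(reference: dict[str, str], annotation: pd.DataFrame):
    """Per-contig strand-owner arrays; positions in genes on both strands
    are marked as ties and skipped (logged)."""
    owners = {}
    for contig, seq in reference.items():
        owner = np.zeros(len(seq), dtype=np.int8)
        for _, g in annotation[annotation["contig"] == contig].iterrows():
            code = _PLUS if g["strand"] == "+" else _MINUS
            sl = slice(int(g["start"]), int(g["end"]))
            cur = owner[sl]
            conflict = (cur != _NONE) & (cur != code)
            cur[cur == _NONE] = code
            cur[conflict] = _TIE
            owner[sl] = cur
        n_tie = int((owner == _TIE).sum())
        if n_tie:
            logger.info("contig %s: %d positions owned by opposite-strand genes; skipped", contig, n_tie)
        owners[contig] = owner
    return owners


def tally_base_counts(
    alignments: dict[str, str],
    reference: dict[str, str],
    annotation: pd.DataFrame,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> BaseCountMatrix:
    """Tally per-site base counts from per-sample alignment files.

    Parameters
    ----------
    alignments:
        mapping of sample id → SAM/BAM path, one file per sample.
    reference:
        mapping of contig → sequence (as from :func:`rnaedit.io.read_fasta`).
    annotation:
        gene intervals with contig/start/end/strand columns (BED-style,
        0-based half-open).
    min_mapq, min_baseq:
        pileup hygiene: only primary, mapped alignments with
        MAPQ ≥ ``min_mapq`` are counted, and bases below ``min_baseq``
        are skipped when the file carries base qualities. Base N is
        always ignored.

    Input files must be coordinate-sorted; an unsorted file raises.
    A contig absent from the reference raises, naming the contig.
    """
    owners = _ownership(reference, annotation)
    rows_per_contig = {
        contig: np.flatnonzero((own == _PLUS) | (own == _MINUS))
        for contig, own in owners.items()
    }
    row_offset, offset = {}, 0
    for contig in reference:
        row_offset[contig] = offset
        offset += len(rows_per_contig[contig])
    pos_to_row = {
        contig: dict(zip(rows, range(row_offset[contig], row_offset[contig] + len(rows))))
        for contig, rows in rows_per_contig.items()
    }
    n_rows = offset
    samples = list(alignments)
    counts = np.zeros((n_rows, len(samples), 4), dtype=np.int64)

    for j, sample in enumerate(samples):
        path = str(alignments[sample])
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            last = {}
            for read in fh.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                contig = read.reference_name
                if contig not in reference:
                    raise ValueError(f"contig {contig!r} in {path} not present in reference")
                if read.reference_start < last.get(contig, -1):
                    raise ValueError(f"{path} is not coordinate-sorted")
                last[contig] = read.reference_start
                if read.mapping_quality < min_mapq:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                owner = owners[contig]
                rowmap = pos_to_row[contig]
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos >= len(owner):
                        raise ValueError(
                            f"read {read.query_name} in {path} extends past contig {contig!r}"
                        )
                    code = owner[rpos]
                    if code == _NONE or code == _TIE:
                        continue
                    base = seq[qpos]
                    if base == "N":
                        continue
                    if quals is not None and quals[qpos] < min_baseq:
                        continue
                    idx = BASE_INDEX[base] if code == _PLUS else _COMP_INDEX[base]
                    counts[rowmap[rpos], j, idx] += 1

    site_frames = []
    for contig in reference:
        rows = rows_per_contig[contig]
        if len(rows) == 0:
            continue
        own = owners[contig][rows]
        strand = np.where(own == _PLUS, "+", "-")
        plus_base = np.frombuffer(reference[contig].encode(), dtype="S1")[rows].astype(str)
        ref_base = [
            b if s == "+" else "TGCA"["ACGT".index(b)] if b in "ACGT" else "N"
            for b, s in zip(plus_base, strand)
        ]
        site_frames.append(
            pd.DataFrame({"contig": contig, "pos": rows, "strand": strand, "ref_base": ref_base})
        )
    sites = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else pd.DataFrame(columns=["contig", "pos", "strand", "ref_base"])
    )
    if len(sites) == 0:
        counts = counts.reshape(0, len(samples), 4)
    return BaseCountMatrix(sites=sites, counts=counts, samples=samples)


@dataclass
class CandidateSet:
    """Nominated candidate sites over a base-count matrix.

    ``site_index`` indexes rows of the source matrix; ``ref``/``alt``
    give the mismatch class on the transcribed strand (always ("A","G")
    unless nomination ran in all-class diagnostic mode). Per-stage
    pass/fail flags are filled in by the filter cascade.
    """

    matrix: BaseCountMatrix
    site_index: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    stage_flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.site_index)

    @property
    def is_ag(self) -> np.ndarray:
        return (self.ref == "A") & (self.alt == "G")

    def table(self) -> pd.DataFrame:
        df = self.matrix.sites.iloc[self.site_index].reset_index(drop=True)
        df["ref"] = self.ref
        df["alt"] = self.alt
        return df


def nominate_candidates(matrix: BaseCountMatrix, all_classes: bool = False) -> CandidateSet:
    """Nominate candidate sites from a base-count matrix.

    Default mode returns every site whose transcribed-strand reference
    base is A and which shows at least one G read in at least one
    sample, as mismatch class (A, G). With ``all_classes=True`` every
    ref→alt pair with at least one supporting read anywhere becomes a
    candidate — used only for the A→G-enrichment diagnostic, never for
    site discovery itself.
    """
    if matrix.n_sites == 0:
        return CandidateSet(matrix, np.array([], dtype=int), np.array([], dtype=object), np.array([], dtype=object))
    ref_codes = matrix.ref_codes
    site_idx, refs, alts = [], [], []
    classes = (
        [(r, a) for r in range(4) for a in range(4) if r != a]
        if all_classes
        else [(BASE_INDEX["A"], BASE_INDEX["G"])]
    )
    bases = "ACGT"
    for r, a in classes:
        has_alt = (matrix.counts[:, :, a] > 0).any(axis=1)
        hit = np.flatnonzero((ref_codes == r) & has_alt)
        site_idx.append(hit)
        refs.append(np.full(len(hit), bases[r], dtype=object))
        alts.append(np.full(len(hit), bases[a], dtype=object))
    return CandidateSet(
        matrix,
        site_index=np.concatenate(site_idx),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
    )
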