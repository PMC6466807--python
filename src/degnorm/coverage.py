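"""Per-gene coverage matrices and raw counts from alignment files.

The coverage score f_ij(x) at transcript position x is the number of
reads (single-end) or DNA fragments (paired-end) of sample j whose
aligned reference bases cover that position of gene i's total transcript.
CIGAR M/=/X/D consume and cover the reference; N-gapped (spliced)
segments do not; paired mates are unioned so bases covered by both count
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from degnorm.genes import GeneModel, merge_intervals

__all__ = ["CoverageMatrix", "compute_coverage", "assemble_matrices"]

# CIGAR operations that consume the reference; of those, N (op 3) is a
# splice gap and does not cover it.
_REF_CONSUME = {0, 2, 3, 7, 8}
_REF_COVER = {0, 2, 7, 8}


@dataclass
class CoverageMatrix:
    """Coverage curves and raw counts of one gene across p samples."""

    gene_id: str
    samples: list[str]
    F: np.ndarray  # (p, L) non-negative coverage scores
    X: np.ndarray  # (p,) raw read/fragment counts
    active: bool = True

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.float64)
        self.X = np.asarray(self.X)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.samples):
            raise ValueError(f"gene {self.gene_id}: F must be (n_samples, L)")
        if (self.F < 0).any():
            raise ValueError(f"gene {self.gene_id}: negative coverage")

    @property
    def L(self) -> int:
        return self.F.shape[1]


def _covered_blocks(read) -> list[tuple[int, int]]:
    """0-based half-open reference intervals covered by one alignment,
    merging across deletions but splitting at N splice gaps."""
    blocks = []
    pos = read.reference_start
    cur_start = None
    for op, length in read.cigartuples or ():
        if op in _REF_COVER:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op in _REF_CONSUME:  # N
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I/S/H/P do not consume the reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def _keep(read, min_mapq: int, drop_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if drop_duplicates and read.is_duplicate:
        return False
    if read.mapping_quality < min_mapq:
        return False
    return True


def _strand_ok(read, gene_strand: str, stranded: str | None) -> bool:
    if stranded is None or gene_strand not in "+-":
        return True
    # for paired data orientation is defined by read1
    rev = read.is_reverse if (not read.is_paired or read.is_read1) else (not read.is_reverse)
    read_strand = "-" if rev else "+"
    same = read_strand == gene_strand
    return same if stranded == "same" else not same


def compute_coverage(
    alignments: str,
    genes: list[GeneModel],
    paired: bool = False,
    min_mapq: int = 0,
    drop_duplicates: bool = True,
    stranded: str | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Coverage curve and raw count of every gene for one alignment file.

    Requires a coordinate-sorted, indexed BAM.  Returns
    ``(coverage, counts)`` keyed by gene_id: coverage is a length-L array
    over transcript coordinates, counts the number of reads (SE) or
    fragments (PE) with at least one aligned base inside the gene's exons.
    Reads are assigned to every gene whose exons they intersect.
    """
    import pysam

    if stranded not in (None, "same", "opposite"):
        raise ValueError("stranded must be None, 'same' or 'opposite'")
    cov: dict[str, np.ndarray] = {}
    cnt: dict[str, int] = {}
    with pysam.AlignmentFile(alignments) as bam:
        if not bam.has_index():
            raise ValueError(f"alignment file {alignments} is not indexed")
        for gene in genes:
            diff = np.zeros(gene.L + 1, dtype=np.float64)
            n_units = 0
            if gene.chrom not in bam.references:
                cov[gene.gene_id] = np.zeros(gene.L)
                cnt[gene.gene_id] = 0
                continue
            reads = (
                r
                for r in bam.fetch(gene.chrom, gene.start, gene.end)
                if _keep(r, min_mapq, drop_duplicates)
                and _strand_ok(r, gene.strand, stranded)
            )
            if not paired:
                for read in reads:
                    if _add_blocks(_covered_blocks(read), gene, diff):
                        n_units += 1
            else:
                frags: dict[str, list[tuple[int, int]]] = {}
                for read in reads:
                    frags.setdefault(read.query_name, []).extend(_covered_blocks(read))
                for blocks in frags.values():
                    # union mates so shared bases count once per fragment
                    if _add_blocks(merge_intervals(blocks) if blocks else [], gene, diff):
                        n_units += 1
            cov[gene.gene_id] = np.cumsum(diff[:-1])
            cnt[gene.gene_id] = n_units
    return cov, cnt


def _add_blocks(blocks, gene: GeneModel, diff: np.ndarray) -> bool:
    """Increment the transcript-space difference array for the exonic part
    of the given genomic blocks; returns True if any base fell in an exon."""
    hit = False
    for bs, be in blocks:
        lo = np.searchsorted(gene._ends, bs, side="right")
        hi = np.searchsorted(gene._starts, be, side="left")
        for k in range(lo, hi):
            a = max(bs, gene._starts[k])
            b = min(be, gene._ends[k])
            if b <= a:
                continue
            t0 = gene._cum[k] + (a - gene._starts[k])  # 0-based transcript offset
            diff[t0] += 1
            diff[t0 + (b - a)] -= 1
            hit = True
    return hit


def assemble_matrices(
    per_sample: dict[str, tuple[dict[str, np.ndarray], dict[str, int]]],
    genes: list[GeneModel],
    min_count: int = 1,
    min_max_coverage: float = 5.0,
) -> list[CoverageMatrix]:
    """Stack per-sample coverage rows into per-gene p x L matrices.

    A gene is flagged active when every sample's raw count is at least
    ``min_count`` and the maximum per-base coverage across all samples is
    at least ``min_max_coverage``; inactive genes pass through the
    pipeline with DI = 0.
    """
    samples = list(per_sample)
    gene_sets = {s: set(per_sample[s][0]) for s in samples}
    ref = {g.gene_id for g in genes}
    for s, gs in gene_sets.items():
        if gs != ref:
            missing = sorted(ref ^ gs)
            raise ValueError(f"sample {s!r} gene set mismatch: {missing[:5]} ...")
    out = []
    for gene in genes:
        F = np.stack([per_sample[s][0][gene.gene_id] for s in samples])
        X = np.array([per_sample[s][1][gene.gene_id] for s in samples], dtype=np.int64)
        active = bool((X >= min_count).all() and F.max() >= min_max_coverage)
        out.append(CoverageMatrix(gene.gene_id, samples, F, X, active=active))
    return out
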