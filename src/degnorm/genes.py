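"""Gene models in the "total transcript" coordinate system.

A gene's total transcript is the concatenation of the merged exons of all
its isoforms, in genomic order.  Coverage curves and the NMF-OA math live
on transcript coordinates 1..L; genomic exon intervals are 0-based,
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneModel", "merge_intervals", "load_annotation", "write_bed12"]


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of possibly overlapping intervals, sorted by start."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted interval ({a}, {b})")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


@dataclass
class GeneModel:
    """Merged-exon gene structure with a genomic<->transcript bijection.

    exons are 0-based half-open genomic intervals, non-overlapping and
    sorted; transcript coordinates are 1-based inclusive over [1, L].
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    _starts: np.ndarray = field(init=False, repr=False)
    _ends: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = merge_intervals(self.exons)
        self._starts = np.array([a for a, _ in self.exons], dtype=np.int64)
        self._ends = np.array([b for _, b in self.exons], dtype=np.int64)
        lens = self._ends - self._starts
        self._cum = np.concatenate([[0], np.cumsum(lens)])

    @property
    def L(self) -> int:
        return int(self._cum[-1])

    @property
    def start(self) -> int:
        return int(self._starts[0])

    @property
    def end(self) -> int:
        return int(self._ends[-1])

    def genomic_to_transcript(self, pos) -> np.ndarray:
        """Map 0-based genomic positions to 1-based transcript positions.

        Non-exonic positions map to 0.
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(self._starts, pos, side="right") - 1
        idx = np.clip(idx, 0, len(self.exons) - 1)
        inside = (pos >= self._starts[idx]) & (pos < self._ends[idx])
        t = np.where(inside, self._cum[idx] + (pos - self._starts[idx]) + 1, 0)
        return t

    def transcript_to_genomic(self, tpos) -> np.ndarray:
        """Map 1-based transcript positions back to 0-based genomic ones."""
        tpos = np.atleast_1d(np.asarray(tpos, dtype=np.int64))
        if (tpos < 1).any() or (tpos > self.L).any():
            raise ValueError("transcript position out of range")
        idx = np.searchsorted(self._cum, tpos - 1, side="right") - 1
        return self._starts[idx] + (tpos - 1 - self._cum[idx])


def _is_gff3(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version 3"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9:
                return "=" in fields[8] and "gene_id \"" not in fields[8]
            break
    return False


def load_annotation(
    annotation_file: str,
    feature_type: str = "exon",
    exclude_contigs: tuple[str, ...] = (),
) -> list[GeneModel]:
    """Build one GeneModel per gene from a GTF or GFF3 annotation.

    Exons of all isoforms are unioned and merged into disjoint intervals.
    Genes on contigs listed in ``exclude_contigs`` are skipped; genes with
    zero exon features are dropped with a warning (emitted by gffutils for
    orphan records).
    """
    import gffutils

    gff3 = _is_gff3(annotation_file)
    db = gffutils.create_db(
        annotation_file,
        ":memory:",
        force=True,
        keep_order=False,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type(feature_type):
        if feat.seqid in exclude_contigs:
            continue
        if "gene_id" in feat.attributes:
            gene_ids = feat.attributes["gene_id"]
        elif gff3:
            gene_ids = [g.id for g in db.parents(feat, featuretype="gene")]
            if not gene_ids:
                gene_ids = feat.attributes.get("Parent", [])
        else:
            raise ValueError(
                f"exon feature at {feat.seqid}:{feat.start} carries no gene identifier"
            )
        for gid in gene_ids:
            rec = per_gene.setdefault(
                gid, {"chrom": feat.seqid, "strand": feat.strand or ".", "exons": []}
            )
            if rec["chrom"] != feat.seqid:
                warnings.warn(
                    f"gene {gid} has exons on multiple contigs; keeping {rec['chrom']}"
                )
                continue
            # gffutils is 1-based inclusive; convert to 0-based half-open
            rec["exons"].append((feat.start - 1, feat.end))
    models = []
    for gid, rec in sorted(per_gene.items()):
        if not rec["exons"]:
            warnings.warn(f"gene {gid} has zero exons; excluded")
            continue
        models.append(
            GeneModel(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                      exons=rec["exons"])
        )
    return models


def write_bed12(genes: list[GeneModel], path: str) -> None:
    """Export total-transcript models as BED12 lines (one per gene)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(b - a) for a, b in g.exons)
            starts = ",".join(str(a - g.start) for a, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start), str(g.end), g.gene_id, "0",
                        g.strand if g.strand in "+-" else ".",
                        str(g.start), str(g.end), "0",
                        str(len(g.exons)), sizes + ",", starts + ",",
                    ]
                )
                + "\n"
            )
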