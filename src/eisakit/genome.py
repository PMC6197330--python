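"""Gene models: loci with exon structure, plus GTF/BED serialization.

A :class:`GeneModel` is a gene locus (0-based, half-open coordinates) with a
list of exon intervals.  The exonic union of a gene is the proxy for mature
mRNA; the locus minus all exonic sequence is the intronic (pre-mRNA) region.
GTF files are written and read as 1-based, closed intervals with ``gene_id``
and ``transcript_id`` attributes; BED6 is native 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .intervals import Interval, merge, subtract, total_length


class AnnotationError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # locus start, 0-based inclusive
    end: int  # locus end, exclusive
    exons: tuple[Interval, ...]

    @property
    def exonic_union(self) -> list[Interval]:
        return merge(self.exons)

    @property
    def intron_intervals(self) -> list[Interval]:
        """Locus minus this gene's own exons (single-gene introns)."""
        return subtract([(self.start, self.end)], self.exons)

    @property
    def exonic_length(self) -> int:
        return total_length(self.exons)

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        if self.end <= self.start:
            raise AnnotationError(f"gene {self.gene_id}: empty locus")
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside locus "
                    f"[{self.start},{self.end})"
                )


@dataclass
class GeneModelSet:
    """An ordered collection of gene models with unique identifiers."""

    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            g.validate()
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    # -- GTF ---------------------------------------------------------------

    def to_gtf(self, path: str | os.PathLike) -> None:
        """Write gene/transcript/exon features (1-based, closed intervals)."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                for feature, (s, e) in (
                    ("gene", (g.start, g.end)),
                    ("transcript", (g.start, g.end)),
                ):
                    fh.write(
                        f"{g.chrom}\teisakit\t{feature}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\teisakit\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )

    @classmethod
    def from_gtf(cls, path: str | os.PathLike) -> "GeneModelSet":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: list[GeneModel] = []
        for gf in db.features_of_type("gene"):  # keep_order: file order
            exons = tuple(
                sorted(
                    (ex.start - 1, ex.end)
                    for ex in db.children(gf, featuretype="exon")
                )
            )
            genes.append(
                GeneModel(
                    gene_id=gf.attributes["gene_id"][0],
                    chrom=gf.seqid,
                    strand=gf.strand,
                    start=gf.start - 1,
                    end=gf.end,
                    exons=exons,
                )
            )
        return cls(genes=genes)


# -- BED6 read records -----------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write alignment records as BED6 (0-based half-open, no header)."""
    reads.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED_COLUMNS)
    return df.astype({"start": int, "end": int})


def write_sam(
    reads: pd.DataFrame, path: str | os.PathLike, chrom_lengths: dict[str, int]
) -> None:
    """Minimal single-end SAM with @HD/@SQ header; unmapped fields defaulted.

    MAPQ encodes mapping uniqueness: 255 for unique records, 0 otherwise
    (mirrors the ``score`` column used in the BED representation).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for row in reads.itertuples(index=False):
            flag = 16 if row.strand == "-" else 0
            length = int(row.end) - int(row.start)
            fh.write(
                f"{row.name}\t{flag}\t{row.chrom}\t{int(row.start) + 1}\t"
                f"{int(row.score)}\t{length}M\t*\t0\t0\t*\t*\n"
            )


def chrom_lengths(models: GeneModelSet, pad: int = 1000) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in models:
        out[g.chrom] = max(out.get(g.chrom, 0), g.end + pad)
    return out
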