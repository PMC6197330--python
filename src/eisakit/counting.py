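"""Exonic/intronic region indexing and uniquely-mapped read counting.

Total RNA-seq quantifies both mature mRNA (exonic reads) and pre-mRNA
(intronic reads).  This module builds, per gene locus, the exonic union and
the intronic remainder — the locus minus the exonic sequence of *every* gene
overlapping it — and bins uniquely mapped reads into the two region kinds:

* any exonic overlap with exactly one gene  -> exonic for that gene
  (a mature-mRNA read may straddle an exon boundary; a pre-mRNA read must
  be fully intronic);
* fully contained in exactly one gene's intronic region, with zero exonic
  overlap anywhere -> intronic for that gene;
* touching the claimed regions of more than one gene -> discarded
  (``ambiguous_gene``);
* partial intronic overlap that leaks outside the region -> discarded
  (``boundary``);
* non-unique mappers and reads over no indexed region -> discarded
  (``unassigned``).

The conservation identity ``exonic + intronic + discarded == reads in`` holds
exactly per sample.  Duplicate reads are not removed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModelSet
from .intervals import fully_contained, merge, subtract

logger = logging.getLogger(__name__)

DISCARD_REASONS = ["ambiguous_gene", "boundary", "unassigned"]


class CountFormatError(ValueError):
    """Malformed count table."""


@dataclass
class RegionIndex:
    """Per-chromosome interval maps from ranges to (gene, region kind)."""

    trees: dict[str, IntervalTree]  # payload: (gene_id, kind, strand)
    intronic_by_gene: dict[str, list[tuple[int, int]]]
    exonic_by_gene: dict[str, list[tuple[int, int]]]
    gene_ids: list[str]
    ambiguous: dict[str, IntervalTree]  # bases claimed by > 1 gene

    def genes_at(self, chrom: str):
        return self.trees.get(chrom)


def build_region_index(models: GeneModelSet) -> RegionIndex:
    """Exonic unions per gene and multi-gene-aware intronic remainders.

    The intronic region of gene g is its locus minus the exonic union of all
    genes whose locus overlaps g's span, so a read from another gene's exon
    inside g's intron is never counted as g's pre-mRNA.  Bases claimed by
    more than one gene are flagged ambiguous.
    """
    models.validate()
    by_chrom: dict[str, list] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)

    trees: dict[str, IntervalTree] = {}
    amb: dict[str, IntervalTree] = {}
    intronic_by_gene: dict[str, list[tuple[int, int]]] = {}
    exonic_by_gene: dict[str, list[tuple[int, int]]] = {}

    for chrom, genes in by_chrom.items():
        tree = IntervalTree()
        amb_tree = IntervalTree()
        loci = IntervalTree()
        for g in genes:
            loci.addi(g.start, g.end, g)
        for g in genes:
            exonic = g.exonic_union
            overlapping = [iv.data for iv in loci.overlap(g.start, g.end)]
            all_exons = [e for og in overlapping for e in og.exonic_union]
            intronic = subtract([(g.start, g.end)], all_exons)
            exonic_by_gene[g.gene_id] = exonic
            intronic_by_gene[g.gene_id] = intronic
            for s, e in exonic:
                tree.addi(s, e, (g.gene_id, "exonic", g.strand))
            for s, e in intronic:
                tree.addi(s, e, (g.gene_id, "intronic", g.strand))
        # claimed = exonic U intronic per gene; pairwise overlaps are ambiguous
        claimed = {
            g.gene_id: merge(exonic_by_gene[g.gene_id] + intronic_by_gene[g.gene_id])
            for g in genes
        }
        events: list[tuple[int, int, str]] = []
        for gid, ivs in claimed.items():
            for s, e in ivs:
                events.append((s, 1, gid))
                events.append((e, -1, gid))
        events.sort(key=lambda t: (t[0], t[1]))
        open_genes: set[str] = set()
        prev = None
        for pos, delta, gid in events:
            if prev is not None and pos > prev and len(open_genes) > 1:
                amb_tree.addi(prev, pos, frozenset(open_genes))
            if delta == 1:
                open_genes.add(gid)
            else:
                open_genes.discard(gid)
            prev = pos
        trees[chrom] = tree
        amb[chrom] = amb_tree

    return RegionIndex(
        trees=trees,
        intronic_by_gene=intronic_by_gene,
        exonic_by_gene=exonic_by_gene,
        gene_ids=models.gene_ids,
        ambiguous=amb,
    )


def _strand_ok(read_strand: str, gene_strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    if strandedness == "forward":
        return read_strand == gene_strand
    if strandedness == "reverse":
        return read_strand != gene_strand
    raise ValueError(f"unknown strandedness {strandedness!r}")


def count_reads(
    reads: pd.DataFrame,
    index: RegionIndex,
    strandedness: str = "unstranded",
) -> tuple[pd.Series, pd.Series, dict[str, int]]:
    """Classify one sample's reads into per-gene exonic/intronic counts.

    ``reads`` is a BED6-like frame (chrom, start, end, name, score, strand);
    ``score == 255`` marks uniquely mapped records, anything else is
    discarded as unassigned.  Returns ``(exonic, intronic, discarded)``.
    """
    exonic = {g: 0 for g in index.gene_ids}
    intronic = {g: 0 for g in index.gene_ids}
    discarded = {r: 0 for r in DISCARD_REASONS}
    missing_chroms: set[str] = set()

    cols = reads[["chrom", "start", "end", "score", "strand"]].to_numpy(dtype=object)
    for chrom, start, end, score, strand in cols:
        start, end = int(start), int(end)
        if int(score) != 255:
            discarded["unassigned"] += 1
            continue
        tree = index.trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            discarded["unassigned"] += 1
            continue
        hits = tree.overlap(start, end)
        genes_exonic: set[str] = set()
        genes_any: set[str] = set()
        for iv in hits:
            gid, kind, gstrand = iv.data
            if not _strand_ok(strand, gstrand, strandedness):
                continue
            genes_any.add(gid)
            if kind == "exonic":
                genes_exonic.add(gid)
        if not genes_any:
            discarded["unassigned"] += 1
        elif len(genes_any) > 1:
            discarded["ambiguous_gene"] += 1
        elif genes_exonic:
            exonic[next(iter(genes_exonic))] += 1
        else:
            gid = next(iter(genes_any))
            if fully_contained(index.intronic_by_gene[gid], start, end):
                intronic[gid] += 1
            else:
                discarded["boundary"] += 1
    if missing_chroms:
        logger.warning(
            "%d read(s) on chromosome(s) absent from index: %s",
            discarded["unassigned"], sorted(missing_chroms),
        )
    return (
        pd.Series(exonic, name="exonic"),
        pd.Series(intronic, name="intronic"),
        discarded,
    )


@dataclass
class RegionCountMatrix:
    """Genes x samples counts, one integer matrix per region kind."""

    exonic: pd.DataFrame
    intronic: pd.DataFrame
    discarded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.exonic.index) != list(self.intronic.index) or list(
            self.exonic.columns
        ) != list(self.intronic.columns):
            raise CountFormatError("exonic and intronic matrices are not aligned")
        for name, mat in (("exonic", self.exonic), ("intronic", self.intronic)):
            arr = mat.to_numpy()
            if (arr < 0).any():
                raise CountFormatError(f"negative entry in {name} matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.exonic.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.exonic.columns)


def count_samples(
    reads_by_sample: Mapping[str, pd.DataFrame],
    index: RegionIndex,
    strandedness: str = "unstranded",
) -> RegionCountMatrix:
    ex_cols, in_cols, disc_rows = {}, {}, {}
    for sample, reads in reads_by_sample.items():
        ex, inn, disc = count_reads(reads, index, strandedness)
        ex_cols[sample] = ex
        in_cols[sample] = inn
        disc_rows[sample] = disc
    samples = list(reads_by_sample)
    return RegionCountMatrix(
        exonic=pd.DataFrame(ex_cols, columns=samples).loc[index.gene_ids],
        intronic=pd.DataFrame(in_cols, columns=samples).loc[index.gene_ids],
        discarded=pd.DataFrame(disc_rows).T.reindex(columns=DISCARD_REASONS),
    )


# ---------------------------------------------------------------------------
# TSV IO


def write_counts_table(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples TSV, validating integer nonnegative entries."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            i = int(bad.to_numpy().argmax())
            raise CountFormatError(
                f"{path}: invalid count at gene {df.index[i]!r}, "
                f"sample {col!r}: {df[col].iloc[i]!r}"
            )
        df[col] = vals.astype(int)
    return df


def write_count_report(
    matrix: RegionCountMatrix, path: str | os.PathLike
) -> None:
    report = {
        "samples": matrix.sample_ids,
        "n_genes": len(matrix.gene_ids),
        "discarded": (
            matrix.discarded.to_dict(orient="index") if len(matrix.discarded) else {}
        ),
        "totals": {
            "exonic": {s: int(matrix.exonic[s].sum()) for s in matrix.sample_ids},
            "intronic": {s: int(matrix.intronic[s].sum()) for s in matrix.sample_ids},
        },
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
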