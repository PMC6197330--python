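import numpy as np
import pandas as pd
import pytest

import eisakit as ek


@pytest.fixture(scope="session")
def small_genome():
    return ek.generate_genome(50, seed=101)


@pytest.fixture(scope="session")
def rnaseq_design():
    return ek.make_rnaseq_design(3)


def brute_force_count(reads: pd.DataFrame, models, strandedness="unstranded"):
    """Independent per-read interval scan over explicit per-base region labels.

    Builds, per gene, the exonic union and the locus-minus-all-exons intronic
    set as plain base intervals, then classifies each read by direct overlap
    arithmetic.  Deliberately naive: no trees, no sweep, quadratic in genes.
    """
    from eisakit.intervals import merge, subtract, overlap_length, fully_contained

    exonic = {g: 0 for g in models.gene_ids}
    intronic = {g: 0 for g in models.gene_ids}
    disc = {"ambiguous_gene": 0, "boundary": 0, "unassigned": 0}
    per_gene = {}
    for g in models:
        all_ex = [
            e
            for og in models
            if og.chrom == g.chrom and og.start < g.end and og.end > g.start
            for e in og.exonic_union
        ]
        per_gene[g.gene_id] = (
            g.chrom,
            g.strand,
            merge(g.exons),
            subtract([(g.start, g.end)], all_ex),
        )
    for row in reads.itertuples(index=False):
        if int(row.score) != 255:
            disc["unassigned"] += 1
            continue
        hit_ex, hit_any = [], []
        for gid, (chrom, gstrand, ex, intr) in per_gene.items():
            if chrom != row.chrom:
                continue
            if strandedness == "forward" and row.strand != gstrand:
                continue
            if strandedness == "reverse" and row.strand == gstrand:
                continue
            oe = overlap_length(ex, row.start, row.end)
            oi = overlap_length(intr, row.start, row.end)
            if oe > 0:
                hit_ex.append(gid)
            if oe > 0 or oi > 0:
                hit_any.append(gid)
        if not hit_any:
            disc["unassigned"] += 1
        elif len(hit_any) > 1:
            disc["ambiguous_gene"] += 1
        elif hit_ex:
            exonic[hit_ex[0]] += 1
        else:
            gid = hit_any[0]
            if fully_contained(per_gene[gid][3], row.start, row.end):
                intronic[gid] += 1
            else:
                disc["boundary"] += 1
    return pd.Series(exonic), pd.Series(intronic), disc


def bh_textbook(p):
    """Textbook BH step-up written independently of the package path."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
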