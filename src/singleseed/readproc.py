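"""Split-UMI read processing: bespoke paired reads -> deduplicated counts.

The library's R1 is 21 nt with the UMI split around the seed barcode:

    positions 1-9   UMI part a
    positions 10-15 6-nt seed barcode
    positions 16-20 UMI part b
    position 21     ignored filler

The canonical 14-nt UMI is ``umi_b + umi_a``: moving the last five of the
first twenty bases to the front turns the read into UMI(14) + BC(6), the
layout downstream demultiplexers expect. R2 carries 55 nt of cDNA and is
poly(A)-trimmed before gene assignment. Counting collapses exact-duplicate
UMIs per (seed, gene), so one molecule contributes one count regardless of
PCR duplication.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import anndata as ad
import numpy as np
import pandas as pd
import pysam

R1_LEN = 21
UMI_A = slice(0, 9)
BARCODE = slice(9, 15)
UMI_B = slice(15, 20)
UMI_LEN = 14
BC_LEN = 6

UNASSIGNED = "__unassigned__"
UNSPECIFIC_PREFIX = "hotspot:"


def rearrange_r1(r1: str) -> tuple[str, str]:
    """Split R1 into (barcode, canonical 14-nt UMI).

    Equivalent to moving bases 16-20 in front of bases 1-15 and then
    reading UMI(14) + BC(6); the 21st base is never used.

    Raises ``ValueError`` for reads shorter than 20 nt (callers discard
    and count them).
    """
    if len(r1) < 20:
        raise ValueError(f"R1 shorter than 20 nt: {len(r1)}")
    return r1[BARCODE], r1[UMI_B] + r1[UMI_A]


def trim_polya(r2: str, min_run: int = 10, min_len: int = 30) -> str | None:
    """Remove a terminal poly(A) run of >= ``min_run``; discard short reads.

    Returns the (possibly unchanged) sequence, or ``None`` when the
    trimmed read falls below ``min_len``. Reads whose terminal A-run is
    shorter than ``min_run`` pass through untouched.
    """
    n = len(r2)
    i = n
    while i > 0 and r2[i - 1] == "A":
        i -= 1
    run = n - i
    if run < min_run:
        return r2
    if i < min_len:
        return None
    return r2[:i]


class TranscriptIndex:
    """Exact-substring lookup from read sequence to gene id.

    Seeds candidate transcripts with shared k-mers, then verifies that the
    full read occurs in the transcript; reads matching more than one gene
    are multimappers and come back ``UNASSIGNED``. Entries whose id starts
    with ``hotspot:`` mark unspecific background sequences.
    """

    def __init__(self, transcripts: dict[str, str], k: int = 25):
        self.k = k
        self.transcripts = dict(transcripts)
        self._kmers: dict[str, set[str]] = defaultdict(set)
        for name, seq in self.transcripts.items():
            for i in range(0, max(len(seq) - k + 1, 0)):
                self._kmers[seq[i : i + k]].add(name)

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 25) -> "TranscriptIndex":
        transcripts = {}
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                transcripts[rec.name] = rec.sequence.upper()
        return cls(transcripts, k=k)

    def assign(self, r2: str) -> str:
        if len(r2) < self.k:
            return UNASSIGNED
        hits = {
            name
            for name in self._kmers.get(r2[: self.k], ())
            if r2 in self.transcripts[name]
        }
        if len(hits) != 1:
            return UNASSIGNED
        return hits.pop()


def assign_gene(r2: str, index: TranscriptIndex) -> str:
    """Assign a trimmed R2 read to a unique gene, else ``UNASSIGNED``."""
    if index is None:
        raise ValueError("transcript index required for gene assignment")
    return index.assign(r2)


def count_umis(
    records: Iterable[tuple[str, str, str]],
    whitelist: dict[str, str],
    gene_order: list[str] | None = None,
) -> ad.AnnData:
    """Collapse (barcode, umi, gene) records into a seed x gene UMI matrix.

    The count for a (seed, gene) pair is the number of distinct UMI
    sequences observed for it (exact match). Records whose barcode is not
    in the whitelist are tallied separately under
    ``uns['non_whitelist_reads']`` and excluded from the matrix.
    """
    seen: dict[tuple[str, str], set[str]] = defaultdict(set)
    non_whitelist = 0
    genes_seen: dict[str, None] = {}
    for barcode, umi, gene in records:
        seed = whitelist.get(barcode)
        if seed is None:
            non_whitelist += 1
            continue
        genes_seen.setdefault(gene, None)
        seen[(seed, gene)].add(umi)

    seeds = sorted(set(whitelist.values()))
    genes = gene_order if gene_order is not None else sorted(genes_seen)
    gi = {g: j for j, g in enumerate(genes)}
    counts = np.zeros((len(seeds), len(genes)), dtype=np.int64)
    si = {s: i for i, s in enumerate(seeds)}
    for (seed, gene), umis in seen.items():
        if gene in gi:
            counts[si[seed], gi[gene]] = len(umis)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(seeds, name="seed")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs["total_umis"] = counts.sum(axis=1)
    adata.uns["non_whitelist_reads"] = non_whitelist
    return adata


def tally_unspecific(
    assignments: Iterable[tuple[str, str]], whitelist: dict[str, str]
) -> pd.Series:
    """Per-seed totals of reads labeled unspecific (hotspot hits)."""
    totals: dict[str, int] = {seed: 0 for seed in sorted(set(whitelist.values()))}
    for barcode, label in assignments:
        seed = whitelist.get(barcode)
        if seed is not None and label.startswith(UNSPECIFIC_PREFIX):
            totals[seed] += 1
    return pd.Series(totals, name="unspecific_reads")


@dataclasses.dataclass
class DemuxStats:
    total_pairs: int = 0
    short_r1: int = 0
    polya_discarded: int = 0
    unassigned: int = 0
    unspecific: int = 0
    genic: int = 0
    non_whitelist: int = 0


def _read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            yield rec1.sequence.upper(), rec2.sequence.upper()


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    whitelist: dict[str, str],
    index: TranscriptIndex,
    min_polya_run: int = 10,
    min_length: int = 30,
) -> tuple[ad.AnnData, DemuxStats]:
    """Full demultiplexing pipeline: FASTQ pair -> deduplicated counts.

    Applies R1 rearrangement, R2 poly(A) trimming, exact gene assignment,
    whitelist demultiplexing and per-(seed, gene) UMI collapse; hotspot
    hits are tallied as per-seed unspecific reads in ``obs``.
    """
    stats = DemuxStats()
    genic_records: list[tuple[str, str, str]] = []
    unspecific: list[tuple[str, str]] = []

    for r1, r2 in _read_pairs(r1_path, r2_path):
        stats.total_pairs += 1
        if len(r1) < 20:
            stats.short_r1 += 1
            continue
        barcode, umi = rearrange_r1(r1)
        trimmed = trim_polya(r2, min_run=min_polya_run, min_len=min_length)
        if trimmed is None:
            stats.polya_discarded += 1
            continue
        label = assign_gene(trimmed, index)
        if label == UNASSIGNED:
            stats.unassigned += 1
            continue
        if label.startswith(UNSPECIFIC_PREFIX):
            stats.unspecific += 1
            unspecific.append((barcode, label))
        else:
            stats.genic += 1
            genic_records.append((barcode, umi, label))

    gene_order = sorted(
        name
        for name in index.transcripts
        if not name.startswith(UNSPECIFIC_PREFIX)
    )
    adata = count_umis(genic_records, whitelist, gene_order=gene_order)
    stats.non_whitelist = int(adata.uns["non_whitelist_reads"])
    adata.obs["unspecific_reads"] = tally_unspecific(unspecific, whitelist).reindex(
        adata.obs_names, fill_value=0
    )
    return adata, stats


def read_whitelist(path: str | Path) -> dict[str, str]:
    """TSV (barcode, seed_id) -> mapping; validates 6-nt unique barcodes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "seed"])
    return make_whitelist(df["barcode"].tolist(), df["seed"].tolist())


def make_whitelist(barcodes: list[str], seeds: list[str]) -> dict[str, str]:
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("whitelist barcodes must be unique")
    for bc in barcodes:
        if len(bc) != BC_LEN:
            raise ValueError(f"barcode {bc!r} is not {BC_LEN} nt")
    return dict(zip(barcodes, seeds))


def process_assignment_table(
    table: pd.DataFrame, whitelist: dict[str, str]
) -> ad.AnnData:
    """Real-data path: (barcode, umi, gene-or-unspecific) table -> counts.

    Rows whose gene label starts with ``hotspot:`` (or equals
    ``unspecific``) feed the per-seed unspecific tally instead of the
    matrix.
    """
    is_unspec = table["gene"].str.startswith(UNSPECIFIC_PREFIX) | (
        table["gene"] == "unspecific"
    )
    genic = table.loc[~is_unspec]
    adata = count_umis(
        list(zip(genic["barcode"], genic["umi"], genic["gene"])), whitelist
    )
    unspec = table.loc[is_unspec]
    adata.obs["unspecific_reads"] = tally_unspecific(
        list(zip(unspec["barcode"], "hotspot:" + unspec["gene"])), whitelist
    ).reindex(adata.obs_names, fill_value=0)
    return adata
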