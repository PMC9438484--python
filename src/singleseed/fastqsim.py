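"""FASTQ-level simulation of the split-UMI library.

Writes paired reads in the bespoke layout (R1 = 9-nt UMI part a + 6-nt
seed barcode + 5-nt UMI part b + 1 filler base; R2 = 55 nt of cDNA,
optionally running into the poly(A) tail), together with the synthetic
transcript FASTA, the barcode whitelist and the count matrix that exact
processing must reproduce: PCR duplicates are injected per molecule and
collapse to one count, reads running deep into poly(A) are trimmed and,
when too short, discarded, and hotspot-derived reads provide the per-seed
unspecific background.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import readproc

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _cap_a_runs(seq: str, max_run: int = 3) -> str:
    """Break internal/terminal A-runs longer than ``max_run``.

    Keeps poly(A) trimming decisions attributable solely to the simulated
    tail padding (plus a bounded <=3-nt transcript remainder).
    """
    out = []
    run = 0
    for ch in seq:
        if ch == "A":
            run += 1
            if run > max_run:
                ch = "G"
                run = 0
        else:
            run = 0
        out.append(ch)
    return "".join(out)


def _trailing_a(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != "A":
            break
        n += 1
    return n


@dataclasses.dataclass
class FastqSim:
    """Outputs of :func:`simulate_fastq`."""

    r1_path: Path
    r2_path: Path
    transcript_fasta: Path
    whitelist_path: Path
    whitelist: dict[str, str]
    expected: ad.AnnData
    n_read_pairs: int


def _unique_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        seen.setdefault(_random_seq(rng, readproc.BC_LEN), None)
    return list(seen)


def simulate_fastq(
    out_dir: str | Path,
    n_seeds: int = 32,
    n_genes: int = 200,
    n_molecules: int = 30000,
    n_unspecific_reads: int = 2000,
    n_foreign_reads: int = 200,
    duplicate_mean: float = 0.5,
    transcript_length: int = 300,
    read_len: int = 55,
    n_hotspots: int = 20,
    polya_read_fraction: float = 0.3,
    rng_seed: int = 0,
    whitelist: dict[str, str] | None = None,
) -> FastqSim:
    """Write a paired FASTQ library plus the ground-truth count matrix.

    Each molecule gets a random seed (one of ``n_seeds`` whitelisted
    barcodes), a gene drawn from log-normal baseline abundances, a 14-nt
    UMI, and ``1 + Poisson(duplicate_mean)`` identical read pairs. A
    ``polya_read_fraction`` of molecules is read across the transcript
    3'-end into the poly(A) tail; trimming then shortens them and discards
    those left below 30 nt. ``n_foreign_reads`` pairs carry non-whitelist
    barcodes. The expected matrix counts distinct UMIs of surviving
    molecules per (seed, gene).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    if whitelist is None:
        barcodes = _unique_barcodes(rng, n_seeds)
        whitelist = {bc: f"seed{i:03d}" for i, bc in enumerate(barcodes)}
    else:
        readproc.make_whitelist(list(whitelist), list(whitelist.values()))
    barcodes = list(whitelist)

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    transcripts = {
        g: _cap_a_runs(_random_seq(rng, transcript_length)) for g in gene_ids
    }
    hotspot_ids = [f"{readproc.UNSPECIFIC_PREFIX}h{i:03d}" for i in range(n_hotspots)]
    hotspots = {h: _cap_a_runs(_random_seq(rng, transcript_length)) for h in hotspot_ids}

    abundance = rng.lognormal(0.0, 1.0, size=n_genes)
    abundance /= abundance.sum()

    surviving: dict[tuple[str, str], set[str]] = {}
    expected_unspec = pd.Series(0, index=sorted(set(whitelist.values())), dtype=int)

    r1_lines: list[str] = []
    r2_lines: list[str] = []
    n_pairs = 0

    def emit(read_id: str, r1: str, r2: str) -> None:
        nonlocal n_pairs
        n_pairs += 1
        q1 = "I" * len(r1)
        q2 = "I" * len(r2)
        r1_lines.append(f"@{read_id}\n{r1}\n+\n{q1}\n")
        r2_lines.append(f"@{read_id}\n{r2}\n+\n{q2}\n")

    def build_r1(barcode: str, umi: str) -> str:
        umi_b, umi_a = umi[:5], umi[5:]
        return umi_a + barcode + umi_b + _random_seq(rng, 1)

    seed_of = rng.integers(0, len(barcodes), size=n_molecules)
    gene_of = rng.choice(n_genes, size=n_molecules, p=abundance)
    for m in range(n_molecules):
        barcode = barcodes[seed_of[m]]
        gene = gene_ids[gene_of[m]]
        tr = transcripts[gene]
        umi = _random_seq(rng, readproc.UMI_LEN)

        if rng.random() < polya_read_fraction:
            # read spans the 3'-end: d genic bases + (read_len - d) of tail
            d = int(rng.integers(20, read_len - 10 + 1))  # pad >= 10
            genic = tr[len(tr) - d :]
            r2 = genic + "A" * (read_len - d)
            kept_len = d - _trailing_a(genic)
            survives = kept_len >= 30
        else:
            start = int(rng.integers(0, len(tr) - read_len + 1))
            r2 = tr[start : start + read_len]
            survives = True

        r1 = build_r1(barcode, umi)
        n_copies = 1 + int(rng.poisson(duplicate_mean))
        for c in range(n_copies):
            emit(f"mol{m:07d}:{c}", r1, r2)
        if survives:
            surviving.setdefault((whitelist[barcode], gene), set()).add(umi)

    for u in range(n_unspecific_reads):
        barcode = barcodes[int(rng.integers(0, len(barcodes)))]
        hid = hotspot_ids[int(rng.integers(0, n_hotspots))]
        seq = hotspots[hid]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        emit(f"uns{u:06d}", build_r1(barcode, _random_seq(rng, readproc.UMI_LEN)),
             seq[start : start + read_len])
        expected_unspec[whitelist[barcode]] += 1

    foreign = set(barcodes)
    for f in range(n_foreign_reads):
        while True:
            bc = _random_seq(rng, readproc.BC_LEN)
            if bc not in foreign:
                break
        gene = gene_ids[int(rng.integers(0, n_genes))]
        tr = transcripts[gene]
        start = int(rng.integers(0, len(tr) - read_len + 1))
        emit(f"for{f:06d}", build_r1(bc, _random_seq(rng, readproc.UMI_LEN)),
             tr[start : start + read_len])

    # interleave deterministically: shuffle read order once
    order = rng.permutation(n_pairs)
    r1_path = out_dir / "R1.fastq.gz"
    r2_path = out_dir / "R2.fastq.gz"
    for path, lines in ((r1_path, r1_lines), (r2_path, r2_lines)):
        with gzip.open(path, "wt") as fh:
            for i in order:
                fh.write(lines[i])

    fasta_path = out_dir / "transcripts.fasta"
    with open(fasta_path, "w") as fh:
        for name, seq in {**transcripts, **hotspots}.items():
            fh.write(f">{name}\n{seq}\n")

    wl_path = out_dir / "whitelist.tsv"
    pd.Series(whitelist).rename("seed").to_csv(wl_path, sep="\t", header=False)

    seeds = sorted(set(whitelist.values()))
    counts = np.zeros((len(seeds), n_genes), dtype=np.int64)
    si = {s: i for i, s in enumerate(seeds)}
    gi = {g: j for j, g in enumerate(gene_ids)}
    for (seed, gene), umis in surviving.items():
        counts[si[seed], gi[gene]] = len(umis)
    expected = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(seeds, name="seed")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    expected.obs["total_umis"] = counts.sum(axis=1)
    expected.obs["unspecific_reads"] = expected_unspec.reindex(seeds).to_numpy()

    return FastqSim(
        r1_path=r1_path,
        r2_path=r2_path,
        transcript_fasta=fasta_path,
        whitelist_path=wl_path,
        whitelist=whitelist,
        expected=expected,
        n_read_pairs=n_pairs,
    )
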