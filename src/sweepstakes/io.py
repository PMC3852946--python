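"""Genepop and FASTA round-trips for simulated datasets.

Microsatellite samples are written in Genepop format with 3-digit allele
coding of repeat counts, so real datasets exported from standard tools can
also be fed to the test battery.  Sequence samples are written as FASTA
haplotypes with the 0/1 site states mapped to A/T.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .forward import SampleDataset

__all__ = ["write_genepop", "read_genepop", "write_fasta", "read_fasta"]


def write_genepop(dataset: SampleDataset | np.ndarray, path, title: str = "sweepstakes simulated sample") -> None:
    geno = dataset.genotypes if isinstance(dataset, SampleDataset) else np.asarray(dataset)
    if geno.ndim != 3:
        raise ValueError("expected (n, L, 2) microsatellite genotypes")
    n, L, _ = geno.shape
    if geno.min() < 1 or geno.max() > 999:
        raise ValueError("repeat counts must be in [1, 999] for 3-digit coding")
    lines = [title]
    lines += [f"Locus{l + 1}" for l in range(L)]
    lines.append("Pop")
    for i in range(n):
        alleles = " ".join(
            f"{geno[i, l, 0]:03d}{geno[i, l, 1]:03d}" for l in range(L))
        lines.append(f"Ind{i + 1} , {alleles}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> np.ndarray:
    """Parse a single-population Genepop file into an (n, L, 2) array."""
    text = Path(path).read_text().strip().splitlines()
    try:
        pop_idx = next(i for i, ln in enumerate(text)
                       if ln.strip().lower() == "pop")
    except StopIteration:
        raise ValueError("no 'Pop' line found; not a Genepop file") from None
    locus_lines = text[1:pop_idx]
    loci: list[str] = []
    for ln in locus_lines:
        loci.extend(s.strip() for s in ln.split(",") if s.strip())
    L = len(loci)
    rows = []
    for ln in text[pop_idx + 1:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            raise ValueError("multi-population Genepop files are not supported")
        _, _, geno_part = ln.partition(",")
        fields = geno_part.split()
        if len(fields) != L:
            raise ValueError(
                f"individual has {len(fields)} genotypes, expected {L}")
        row = []
        for f in fields:
            if len(f) not in (4, 6):
                raise ValueError(f"bad genotype field {f!r}")
            w = len(f) // 2
            row.append((int(f[:w]), int(f[w:])))
        rows.append(row)
    return np.asarray(rows, dtype=np.int16)


def write_fasta(dataset: SampleDataset | np.ndarray, path,
                length: int | None = None) -> None:
    """Write 0/1 haplotypes as A/T sequences padded to the fragment length."""
    sites = dataset.genotypes if isinstance(dataset, SampleDataset) else np.asarray(dataset)
    if length is None:
        length = (dataset.sequence_length
                  if isinstance(dataset, SampleDataset) else sites.shape[1])
    if sites.shape[1] > length:
        raise ValueError("more segregating sites than sequence length")
    with open(path, "w") as fh:
        for i in range(sites.shape[0]):
            seq = "".join("T" if s else "A" for s in sites[i])
            seq += "A" * (length - sites.shape[1])
            fh.write(f">hap{i + 1}\n{seq}\n")


def read_fasta(path) -> np.ndarray:
    """Read A/T haplotypes back into a 0/1 matrix (all columns retained)."""
    seqs = []
    name = None
    buf: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith(">"):
            if name is not None:
                seqs.append("".join(buf))
            name, buf = ln[1:], []
        else:
            buf.append(ln.strip())
    if name is not None:
        seqs.append("".join(buf))
    if not seqs:
        raise ValueError("no sequences found")
    mat = np.array([[1 if c == "T" else 0 for c in s] for s in seqs],
                   dtype=np.int8)
    return mat
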