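"""Toy reference genomes.

Real breakpoint analyses run against GRCh37/hg19; everything here runs
against small random genomes whose rearrangements we control, so that
every truth label (microhomology length, insert provenance, copy number)
is well-defined by construction.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .core import GenomeRef

__all__ = ["make_toy_genome", "random_dna"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide string with expected GC fraction ``gc``."""
    if length <= 0:
        raise ValueError(f"non-positive length {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction {gc} outside [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def make_toy_genome(
    n_chroms: int,
    lengths: Sequence[int],
    gc: float = 0.41,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
    ploidy: Optional[Mapping[str, int]] = None,
) -> GenomeRef:
    """Deterministic random genome with ``n_chroms`` chromosomes.

    The same ``seed`` always yields byte-identical sequences.  Chromosome
    names default to ``chr1..chrN``.
    """
    if not 1 <= n_chroms <= 5:
        raise ValueError("n_chroms must be in 1..5")
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    lengths = [int(x) for x in lengths]
    for x in lengths:
        if x <= 0:
            raise ValueError(f"non-positive length {x}")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chroms)]
    rng = np.random.default_rng(seed)
    chroms = {name: random_dna(n, gc, rng) for name, n in zip(names, lengths)}
    return GenomeRef(chroms, ploidy)
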