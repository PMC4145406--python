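"""Variant definitions, gene-dropping, and genotype I/O.

Gene dropping assigns founder alleles by Hardy-Weinberg draws at each
variant's minor allele frequency and transmits one uniformly chosen allele
from each parent down the pedigree.  Variants are treated as unlinked, so
per-variant dosage variance has the closed form ``2 p (1 - p)`` in
founders.  Monozygotic twins share a genome and are copied, not redrawn.

Dosages are held in a :class:`pandas.DataFrame` indexed by person id with
one column per variant key ``"chrom:pos"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import PedigreeSet

__all__ = [
    "VariantDef",
    "drop_genotypes",
    "write_dosage_table",
    "read_dosage_table",
    "write_vcf",
]

_ODD_AUTOSOMES = {str(c) for c in range(1, 22, 2)}


@dataclass(frozen=True)
class VariantDef:
    """A biallelic variant on an odd autosome.

    ``maf`` is the minor allele frequency in (0, 0.5]; the alternate
    allele is taken to be the minor allele.
    """

    chromosome: str
    position: int
    maf: float
    gene: str = ""
    category: str = "background"  # coding | regulatory | background | null
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self):
        if str(self.chromosome) not in _ODD_AUTOSOMES:
            raise ValueError(f"chromosome must be an odd autosome, got {self.chromosome!r}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")
        if self.category not in ("coding", "regulatory", "background", "null"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}"


def drop_genotypes(
    pedigrees: PedigreeSet,
    variants: list[VariantDef],
    seed: int | np.random.Generator = 0,
    allow_monomorphic: bool = False,
) -> pd.DataFrame:
    """Gene-drop genotypes for every pedigree member at every variant.

    Founders are drawn at Hardy-Weinberg equilibrium; non-founders inherit
    one allele sampled uniformly from each parent; MZ twins are copied.
    Returns integer minor-allele dosages in {0, 1, 2}.

    A variant with ``maf == 0`` is rejected unless ``allow_monomorphic``
    is set, in which case its column is all zero.
    """
    for v in variants:
        if v.maf == 0.0 and not allow_monomorphic:
            raise ValueError(f"variant {v.key} has maf=0 (pass allow_monomorphic=True to permit)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.array([v.maf for v in variants])
    m = len(variants)
    order = pedigrees.topological_order()
    # paternal/maternal haplotypes as minor-allele indicators
    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    twin_rep: dict[str, str] = {}
    for ind in order:
        if ind.mz_group is not None:
            rep = min(x.person_id for x in pedigrees.mz_groups()[ind.mz_group])
            if ind.person_id != rep and rep in hap:
                hap[ind.person_id] = hap[rep]
                twin_rep[ind.person_id] = rep
                continue
        if ind.is_founder:
            h1 = (rng.random(m) < mafs).astype(np.int8)
            h2 = (rng.random(m) < mafs).astype(np.int8)
        else:
            fh = hap[ind.father_id]
            mh = hap[ind.mother_id]
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            h1 = np.where(pick_f == 0, fh[0], fh[1]).astype(np.int8)
            h2 = np.where(pick_m == 0, mh[0], mh[1]).astype(np.int8)
        hap[ind.person_id] = (h1, h2)
    ids = pedigrees.person_ids
    data = np.vstack([hap[p][0] + hap[p][1] for p in ids])
    return pd.DataFrame(
        data.astype(np.int16), index=pd.Index(ids, name="person_id"), columns=[v.key for v in variants]
    )


def write_dosage_table(dosages: pd.DataFrame, path) -> None:
    """Write dosages as a tab-separated table (rows=individuals, columns=variants)."""
    dosages.to_csv(path, sep="\t", index_label="person_id")


def read_dosage_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="person_id")


def write_vcf(dosages: pd.DataFrame, variants: list[VariantDef], path) -> None:
    """Write integer dosages as a GT-only VCF 4.2 file via pysam.

    The alternate allele encodes the minor allele, so dosage 2 becomes
    genotype ``1/1``.  Fractional dosages are not representable and raise.
    """
    import pysam

    missing = [v.key for v in variants if v.key not in dosages.columns]
    if missing:
        raise KeyError(f"dosage table lacks variant columns: {missing[:5]}")
    arr = dosages[[v.key for v in variants]].to_numpy()
    if not np.isin(arr, [0, 1, 2]).all():
        raise ValueError("VCF output requires integer dosages in {0, 1, 2}")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted({str(v.chromosome) for v in variants}, key=int):
        header.contigs.add(chrom)
    for pid in dosages.index:
        header.add_sample(str(pid))
    by_pos = sorted(range(len(variants)), key=lambda i: (int(variants[i].chromosome), variants[i].position))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in by_pos:
            v = variants[i]
            rec = out.new_record(
                contig=str(v.chromosome),
                start=v.position - 1,
                stop=v.position,
                alleles=(v.ref_allele, v.alt_allele),
                id=v.key,
            )
            for j, pid in enumerate(dosages.index):
                d = int(arr[j, i])
                rec.samples[str(pid)]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
            out.write(rec)
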