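"""Exports: VCF genotypes (genetic coordinates), accession and pedigree CSVs.

VCF positions are genetic, not physical: POS = cM x 10^5, rounded - the
simulator has no physical map. The header says so.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .founders import LandraceAccession
from .gbs import GenotypeMatrix
from .genome import GenomeMap, Individual

__all__ = ["write_vcf", "accession_table", "pedigree_table"]

_POS_SCALE = 100_000  # cM -> integer VCF POS


def write_vcf(
    individuals: Sequence[Individual],
    gmap: GenomeMap,
    path: str | Path,
    loci: np.ndarray | None = None,
    dosages: GenotypeMatrix | None = None,
    sample_names: Sequence[str] | None = None,
) -> None:
    """Write phased biallelic genotypes (GT, optionally DS from a
    :class:`GenotypeMatrix`) as an uncompressed VCF."""
    if loci is None:
        loci = (
            dosages.marker_index if dosages is not None else np.arange(gmap.n_loci)
        )
    names = list(sample_names or (f"IND{i}" for i in range(len(individuals))))
    chrom_of = gmap.locus_chromosome()
    pos_cm = gmap.global_positions()
    has_ds = dosages is not None
    lines = [
        "##fileformat=VCFv4.2",
        "##source=prebreedsim",
        "##INFO=<ID=.,Number=0,Type=Flag,Description=\"none\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
    ]
    if has_ds:
        lines.append(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior-mean dosage">'
        )
    lines.append(
        "##coordinates=genetic; POS = centimorgan x 1e5 (no physical map exists)"
    )
    for c in range(gmap.n_chromosomes):
        length = int(gmap.chrom_lengths_cm[c] * _POS_SCALE) + 1
        lines.append(f"##contig=<ID=chr{c + 1},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names)
    )
    fmt = "GT:DS" if has_ds else "GT"
    for j, locus in enumerate(loci):
        locus = int(locus)
        fields = [
            f"chr{chrom_of[locus] + 1}",
            str(int(round(pos_cm[locus] * _POS_SCALE))),
            f"L{locus}",
            "A",
            "T",
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i, ind in enumerate(individuals):
            gt = f"{ind.haplotypes[0, locus]}|{ind.haplotypes[1, locus]}"
            if has_ds:
                gt += f":{dosages.dosages[i, j]:.3f}"
            fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def accession_table(accessions: Sequence[LandraceAccession]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession_id": [a.accession_id for a in accessions],
            "n_members": [len(a.members) for a in accessions],
            "realized_F": [a.realized_F for a in accessions],
        }
    )


def pedigree_table(individuals: Sequence[Individual]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [ind.id for ind in individuals],
            "mother": [ind.mother_id for ind in individuals],
            "father": [ind.father_id for ind in individuals],
            "type": [ind.role for ind in individuals],
        }
    )
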