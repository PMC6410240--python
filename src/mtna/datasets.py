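"""Packaged count tables and reference constants used by the analyses.

Two small published tables from a Munich (Germany) population survey of the
MtnA 3' UTR indel ship with the package so that the population-genetic
report runs offline:

* genotype counts per seasonal collection (Del/Del, Del/Non, Non/Non);
* deletion-allele counts by sex, reconstructed from the published per-sex
  frequencies and chromosome counts.

Haploid survey constants for the African samples are exposed as
``(n_deletion_alleles, n_chromosomes)`` tuples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_tsv

#: Siavonga (Zambia) haploid-embryo survey: deletion alleles / genomes.
ZAMBIA_SIAVONGA = (5, 192)

#: Kafue National Park (Zambia) survey: deletion alleles / genomes.
ZAMBIA_KAFUE = (0, 17)

#: Earlier Munich survey of 11 isofemale lines (22 chromosomes).
MUNICH_2005 = (20, 22)

#: MtnA locus on chromosome arm 3R (1-based inclusive, metadata only).
MTNA_REGION_3R = (9_783_407, 9_784_370)


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mtna.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_tsv(path)


def munich_genotype_counts() -> pd.DataFrame:
    """Genotype counts per Munich seasonal collection.

    Columns: ``collection, n_deldel, n_delnon, n_nonnon``. Summing the four
    collections gives the pooled (510, 96, 8) table.
    """
    return _load("munich_genotype_counts.tsv")


def munich_allele_counts() -> pd.DataFrame:
    """Deletion-allele counts by collection and sex (chromosome scale).

    Columns: ``collection, sex, n_chromosomes, n_del``.
    """
    return _load("munich_allele_counts.tsv")


__all__ = [
    "ZAMBIA_SIAVONGA",
    "ZAMBIA_KAFUE",
    "MUNICH_2005",
    "MTNA_REGION_3R",
    "munich_genotype_counts",
    "munich_allele_counts",
]
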