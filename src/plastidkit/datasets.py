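"""Loaders for the packaged study tables.

Three tables from a loblolly-pine (*Pinus taeda*) breeding-population
chloroplast study ship with the package as plain TSV:

* ``table1_primers.tsv`` — the 6 PCR primer pairs covering an 18-SNP panel.
* ``table2_mutations.tsv`` — 75 pooled-sequencing mutation sites (71 SNPs,
  4 indels) against the reference plastome, with pooled mutation rates and
  gene/intergenic annotations.  A second copy in the published three-block
  page layout is kept for dialect-fidelity testing.
* ``table3_genotypes.tsv`` — Sanger genotypes of 33 breeding individuals at
  a 15-locus SNP panel.

Known transcription caveat, kept verbatim rather than reconciled: panel loci
``rpoC1_23167``, ``IGS_23593``, ``IGS_50999``, ``ycf1_98314`` and
``ycf1_101148`` in tables 1/3 have no corresponding mutation-table row.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core_io import (
    GenotypeMatrix,
    PrimerPair,
    VariantRecord,
    read_genotype_matrix,
    read_primer_table,
    read_variant_table,
)

__all__ = [
    "fixture_path",
    "load_primer_table",
    "load_mutation_table",
    "load_genotype_table",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    path = resources.files("plastidkit").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)


def load_primer_table() -> list[PrimerPair]:
    return read_primer_table(fixture_path("table1_primers.tsv"))


def load_mutation_table(dialect: str = "flat") -> list[VariantRecord]:
    name = "table2_mutations_blocks.tsv" if dialect == "blocks" else "table2_mutations.tsv"
    return read_variant_table(fixture_path(name), dialect=dialect)


def load_genotype_table() -> GenotypeMatrix:
    return read_genotype_matrix(fixture_path("table3_genotypes.tsv"))
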