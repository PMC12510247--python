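"""Readers, writers and domain types for every format the pipeline touches.

Coordinates are 1-based and inclusive throughout the package, matching the
arithmetic of PCR primer tables (amplicon length = reverse − forward + 1) and
the mutation-site tables this toolkit consumes.

Supported formats: FASTA (via Biopython), GFF3 (via gffutils) or a 5-column
TSV for gene annotations, newick (via dendropy, see :mod:`plastidkit.phylo`),
and three documented TSV dialects for the primer table, the mutation-site
table and the genotype matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneFeature",
    "PrimerPair",
    "VariantRecord",
    "GenotypeMatrix",
    "read_fasta",
    "write_fasta",
    "read_features",
    "read_variant_table",
    "write_variant_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_primer_table",
]

NUCLEOTIDES = frozenset("ACGTN")

#: glyphs accepted as the "matches the reference" symbol in genotype tables;
#: published tables mix ASCII hyphens with en/em dashes.
_DASHES = {"-", "–", "—", "−"}


class FormatError(ValueError):
    """Malformed input file; message carries file position where known."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally circular (plastome)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, 1) if c in bad)
            raise ValueError(
                f"sequence {self.id!r}: illegal character {self.sequence[pos - 1]!r} "
                f"at position {pos} (alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on the reference, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"  # CDS, tRNA, rRNA, other

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"feature {self.name!r}: bad span {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name!r}: strand must be + or -")

    def __contains__(self, coordinate: int) -> bool:
        return self.start <= coordinate <= self.end


@dataclass(frozen=True)
class PrimerPair:
    """One PCR primer pair with the values declared in the source table."""

    pair_id: str
    forward_start: int
    reverse_start: int
    forward_seq: str
    reverse_seq: str
    declared_amplicon_length: int
    declared_gc_f: float
    declared_gc_r: float
    target_snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.forward_seq or not self.reverse_seq:
            raise ValueError(f"primer pair {self.pair_id!r}: empty sequence")
        if not self.forward_start < self.reverse_start:
            raise ValueError(
                f"primer pair {self.pair_id!r}: forward start must precede reverse start"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One mutation site: SNP (single-base alts) or indel (+SEQ/-SEQ alt).

    ``rates`` are pooled-read alternate-allele fractions, parallel to
    ``alt_alleles``.  The intergenic annotation convention is
    ``"geneA~geneB"`` (ordered flanking genes); genic variants carry the
    bare gene name.
    """

    coordinate: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    rates: tuple[float, ...]
    kind: str  # "SNP" or "indel"
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError(f"variant at {self.coordinate}: no alternate alleles")
        if len(self.alt_alleles) != len(self.rates):
            raise ValueError(
                f"variant at {self.coordinate}: {len(self.alt_alleles)} alts "
                f"but {len(self.rates)} rates"
            )
        for r in self.rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"variant at {self.coordinate}: rate {r} outside [0,1]")
        snp_like = all(len(a) == 1 and a in "ACGT" for a in self.alt_alleles)
        if self.kind == "SNP" and not snp_like:
            raise ValueError(f"variant at {self.coordinate}: SNP with non-single-base alt")
        if self.kind == "indel" and snp_like:
            raise ValueError(f"variant at {self.coordinate}: indel with single-base alts")
        if self.kind not in {"SNP", "indel"}:
            raise ValueError(f"variant at {self.coordinate}: kind must be SNP or indel")

    @property
    def max_rate(self) -> float:
        return max(self.rates)

    @property
    def is_intergenic(self) -> bool:
        return "~" in self.annotation


@dataclass
class GenotypeMatrix:
    """Individuals × panel loci call matrix.

    Call symbols: ``'-'`` = matches reference, a base = alternate allele,
    ``'N'`` = ambiguous Sanger call.  Locus ids are ``"gene_position"``.
    """

    locus_ids: list[str]
    reference_calls: list[str]
    individuals: list[str]
    calls: list[list[str]]
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_loci = len(self.locus_ids)
        if len(self.reference_calls) != n_loci:
            raise ValueError("reference_calls length must match locus count")
        if len(self.calls) != len(self.individuals):
            raise ValueError("one call row per individual required")
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != n_loci:
                raise ValueError(f"ragged row for individual {ind!r}")
            for j, sym in enumerate(row):
                if sym not in {"-", "A", "C", "G", "T", "N"}:
                    raise ValueError(
                        f"individual {ind!r}, locus {self.locus_ids[j]!r}: "
                        f"unknown symbol {sym!r}"
                    )
        if not self.positions:
            self.positions = [_locus_position(l) for l in self.locus_ids]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def profile(self, individual: str) -> tuple[str, ...]:
        return tuple(self.calls[self.individuals.index(individual)])

    def subset_loci(self, locus_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(locus_indices)
        return GenotypeMatrix(
            locus_ids=[self.locus_ids[j] for j in idx],
            reference_calls=[self.reference_calls[j] for j in idx],
            individuals=list(self.individuals),
            calls=[[row[j] for j in idx] for row in self.calls],
            positions=[self.positions[j] for j in idx],
        )


def _locus_position(locus_id: str) -> int:
    tail = locus_id.rsplit("_", 1)[-1]
    try:
        return int(tail)
    except ValueError:
        return -1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Sequences are upper-cased; RNA ('U') and IUPAC ambiguity codes other
    than 'N' are rejected with the offending position named.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            records.append(SequenceRecord(id=rec.id, sequence=seq, circular=circular))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotations: GFF3 or 5-column TSV (name, start, end, strand, kind)
# ---------------------------------------------------------------------------

_GFF_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "gene": "other"}


def read_features(path: str | Path) -> list[GeneFeature]:
    """Read gene features from GFF3 (``.gff``/``.gff3``) or 5-column TSV.

    Returns features sorted by start coordinate; names must be unique.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        feats = _read_gff3(path)
    else:
        feats = _read_feature_tsv(path)
    feats.sort(key=lambda f: (f.start, f.end))
    names = [f.name for f in feats]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate feature names {sorted(dupes)}")
    return feats


def _read_gff3(path: Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats: list[GeneFeature] = []
    for f in db.all_features():
        if f.featuretype not in _GFF_TYPES:
            continue
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.id])[0]
        feats.append(
            GeneFeature(
                name=name,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                kind=_GFF_TYPES[f.featuretype],
            )
        )
    return feats


def _read_feature_tsv(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"name", "gene"}:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected ≥4 tab-separated columns")
            kind = parts[4] if len(parts) > 4 else "other"
            try:
                feats.append(
                    GeneFeature(
                        name=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        strand=parts[3],
                        kind=kind,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return feats


# ---------------------------------------------------------------------------
# Mutation-site table (two dialects: flat, and the published 3-block layout)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["Coordinate", "Ref", "SNP_Indels", "Rate", "Gene"]


def _normalise_gene_label(label: str) -> str:
    # published tables carry markdown emphasis, intraword spaces and a
    # typographic tilde; normalize to bare "gene" / "geneA~geneB"
    label = label.replace("*", "").replace("∼", "~").replace("–", "-")
    parts = [p.strip().replace(" ", "") for p in label.split("~")]
    return "~".join(parts)


def _parse_variant_row(fields: Sequence[str], where: str) -> VariantRecord:
    coord_s, ref, alts_s, rates_s, gene = (f.strip() for f in fields)
    try:
        coordinate = int(coord_s)
    except ValueError as exc:
        raise FormatError(f"{where}: bad coordinate {coord_s!r}") from exc
    alts = tuple(a.strip().replace("−", "-") for a in alts_s.split("/"))
    rate_fields = rates_s.split("/")
    if len(rate_fields) != len(alts):
        raise FormatError(
            f"{where}: {len(alts)} alternate alleles but {len(rate_fields)} rates"
        )
    try:
        rates = tuple(float(r) for r in rate_fields)
    except ValueError as exc:
        raise FormatError(f"{where}: unparseable rate {rates_s!r}") from exc
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise FormatError(f"{where}: rate {r} outside [0,1]")
    kind = "SNP" if all(len(a) == 1 and a in "ACGT" for a in alts) else "indel"
    try:
        return VariantRecord(
            coordinate=coordinate,
            ref_allele=ref,
            alt_alleles=alts,
            rates=rates,
            kind=kind,
            annotation=_normalise_gene_label(gene),
        )
    except ValueError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def read_variant_table(path: str | Path, dialect: str = "flat") -> list[VariantRecord]:
    """Read a mutation-site table.

    ``dialect="flat"``: one record per row, 5 columns.
    ``dialect="blocks"``: the published 15-column layout with three
    side-by-side 5-column blocks; flattened column-major so records come
    out in coordinate order.
    """
    path = Path(path)
    if dialect not in {"flat", "blocks"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[str]] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty table")
    body = lines[1:] if lines[0].split("\t")[0].strip().lower() == "coordinate" else lines
    if not body:
        raise FormatError(f"{path}: table has a header but no rows")
    n_blocks = 3 if dialect == "blocks" else 1
    blocks: list[list[list[str]]] = [[] for _ in range(n_blocks)]
    for lineno, line in enumerate(body, 2):
        fields = line.split("\t")
        if len(fields) != 5 * n_blocks:
            raise FormatError(
                f"{path}:{lineno}: expected {5 * n_blocks} columns, got {len(fields)}"
            )
        for b in range(n_blocks):
            blocks[b].append(fields[5 * b : 5 * b + 5])
    for block in blocks:
        rows.extend(block)
    records = [
        _parse_variant_row(row, f"{path} row {i + 1}") for i, row in enumerate(rows)
    ]
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in sorted(records, key=lambda r: r.coordinate):
            alts = "/".join(v.alt_alleles)
            rates = "/".join(_format_rate(r) for r in v.rates)
            fh.write(f"{v.coordinate}\t{v.ref_allele}\t{alts}\t{rates}\t{v.annotation}\n")


def _format_rate(rate: float) -> str:
    if rate == int(rate):
        return str(int(rate))
    return f"{rate:.2f}".rstrip("0")


# ---------------------------------------------------------------------------
# Genotype matrix (Gene/Pos/Ref header rows, then one row per individual)
# ---------------------------------------------------------------------------

def _normalise_call(symbol: str, where: str) -> str:
    symbol = symbol.strip()
    if symbol in _DASHES:
        return "-"
    if symbol in {"A", "C", "G", "T", "N"}:
        return symbol
    raise FormatError(f"{where}: unknown genotype symbol {symbol!r}")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a genotype table: header rows Gene/Pos/Ref, then individuals."""
    path = Path(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if len(lines) < 4:
        raise FormatError(f"{path}: need Gene/Pos/Ref headers plus ≥1 individual row")
    header: dict[str, list[str]] = {}
    for expected, line in zip(("gene", "pos", "ref"), lines[:3]):
        fields = line.split("\t")
        if fields[0].strip().lower() != expected:
            raise FormatError(f"{path}: expected {expected!r} header row, got {fields[0]!r}")
        header[expected] = [f.strip() for f in fields[1:]]
    genes, pos_s, refs = header["gene"], header["pos"], header["ref"]
    if not len(genes) == len(pos_s) == len(refs):
        raise FormatError(f"{path}: Gene/Pos/Ref header rows differ in length")
    try:
        positions = [int(p) for p in pos_s]
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position in Pos row") from exc
    locus_ids = [f"{_normalise_gene_label(g)}_{p}" for g, p in zip(genes, positions)]
    individuals: list[str] = []
    calls: list[list[str]] = []
    for lineno, line in enumerate(lines[3:], 4):
        fields = line.split("\t")
        ind = fields[0].strip()
        row = fields[1:]
        if len(row) != len(locus_ids):
            raise FormatError(
                f"{path}:{lineno}: individual {ind!r} has {len(row)} calls, "
                f"expected {len(locus_ids)}"
            )
        individuals.append(ind)
        calls.append(
            [_normalise_call(s, f"{path}:{lineno} column {j + 2}") for j, s in enumerate(row)]
        )
    if len(set(individuals)) != len(individuals):
        raise FormatError(f"{path}: duplicate individual ids")
    return GenotypeMatrix(
        locus_ids=locus_ids,
        reference_calls=[_normalise_call(r, f"{path}: Ref row") for r in refs],
        individuals=individuals,
        calls=calls,
        positions=positions,
    )


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    genes = [l.rsplit("_", 1)[0] for l in gm.locus_ids]
    with open(path, "w") as fh:
        fh.write("Gene\t" + "\t".join(genes) + "\n")
        fh.write("Pos\t" + "\t".join(str(p) for p in gm.positions) + "\n")
        fh.write("Ref\t" + "\t".join(gm.reference_calls) + "\n")
        for ind, row in zip(gm.individuals, gm.calls):
            fh.write(ind + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Primer table
# ---------------------------------------------------------------------------

def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read the primer-panel TSV (one row per pair, declared stats kept)."""
    path = Path(path)
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty primer table")
    cols = lines[0].split("\t")
    idx = {c: i for i, c in enumerate(cols)}
    required = {
        "Pair", "F_Location", "F_Sequence", "F_GC",
        "R_Location", "R_Sequence", "R_GC", "Amplicon_bp",
    }
    missing = required - set(idx)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for lineno, line in enumerate(lines[1:], 2):
        f = line.split("\t")
        try:
            targets = tuple(
                t.strip() for t in f[idx["Target_SNPs"]].split(",") if t.strip()
            ) if "Target_SNPs" in idx else ()
            pairs.append(
                PrimerPair(
                    pair_id=f[idx["Pair"]].strip(),
                    forward_start=int(f[idx["F_Location"]]),
                    reverse_start=int(f[idx["R_Location"]]),
                    forward_seq=f[idx["F_Sequence"]].strip().upper(),
                    reverse_seq=f[idx["R_Sequence"]].strip().upper(),
                    declared_amplicon_length=int(f[idx["Amplicon_bp"]]),
                    declared_gc_f=float(f[idx["F_GC"]]),
                    declared_gc_r=float(f[idx["R_GC"]]),
                    target_snp_ids=targets,
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pairs
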