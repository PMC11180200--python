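"""Readers and writers for the pipeline's external representations.

Formats handled here:

* plain and gapped FASTA (delegated to Biopython's ``SeqIO``);
* the gene feature table, a small documented TSV dialect: ``#key<TAB>value``
  pragma lines (``genome_length`` required, ``species`` optional) followed by
  a header row ``name  start  end  strand  class`` with 1-based inclusive
  coordinates;
* Newick trees with branch lengths and optional internal-node support
  labels (delegated to DendroPy).

Gene names are normalised to a canonical 39-name vocabulary covering the 37
vertebrate mitochondrial genes plus the two non-coding landmarks (the origin
of light-strand replication ``OL`` and the control region ``CR``).
Normalisation is idempotent; unmappable names are kept verbatim with a
warning so that unusual annotations survive a round trip.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "FormatError",
    "CoordinateError",
    "SequenceRecord",
    "Strand",
    "GeneClass",
    "GeneFeature",
    "GeneTable",
    "CANONICAL_GENES",
    "normalize_gene_name",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_newick",
    "write_newick",
]


class FormatError(ValueError):
    """A file violates the expected format."""


class CoordinateError(ValueError):
    """Feature coordinates are inconsistent with the genome."""


# IUPAC nucleotides plus alignment gap.
_ALLOWED_RESIDUES = frozenset("ACGTUNRYSWKMBDHV-")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV-", "TGCAANYRSWMKVHDB-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an (possibly degenerate, possibly gapped) DNA string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence; gaps are legal only in alignment contexts."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Strand(str, Enum):
    H = "H"  # heavy strand (the reference orientation)
    L = "L"  # light strand

    @property
    def flipped(self) -> "Strand":
        return Strand.L if self is Strand.H else Strand.H


class GeneClass(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    NC = "NC"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, 1-based inclusive coordinates on the H strand."""

    name: str
    start: int
    end: int
    strand: Strand
    gene_class: GeneClass

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start {self.start} < 1")
        if self.start > self.end:
            raise CoordinateError(
                f"{self.name}: start {self.start} > end {self.end} "
                "(origin-spanning features are not supported)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self, genome: str) -> str:
        """H-strand subsequence covered by this feature."""
        if self.end > len(genome):
            raise CoordinateError(
                f"{self.name}: end {self.end} exceeds sequence length {len(genome)}"
            )
        return genome[self.start - 1 : self.end]

    def coding_sequence(self, genome: str) -> str:
        """Feature sequence in coding-strand orientation."""
        region = self.slice(genome)
        return reverse_complement(region) if self.strand is Strand.L else region


@dataclass(frozen=True)
class GeneTable:
    """Ordered annotation of one mitogenome.

    Features are kept sorted by start coordinate; duplicate names are legal
    (rearranged genomes carry extra gene copies).
    """

    species_id: str
    genome_length: int
    features: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end, f.name)))
        object.__setattr__(self, "features", feats)
        if feats:
            worst = max(f.end for f in feats)
            if worst > self.genome_length:
                raise CoordinateError(
                    f"{self.species_id}: feature end {worst} exceeds genome length "
                    f"{self.genome_length}"
                )

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def select(
        self,
        gene_class: GeneClass | None = None,
        names: Iterable[str] | None = None,
    ) -> tuple[GeneFeature, ...]:
        wanted = None if names is None else {n for n in names}
        return tuple(
            f
            for f in self.features
            if (gene_class is None or f.gene_class is gene_class)
            and (wanted is None or f.name in wanted)
        )

    def copy_count(self, name: str) -> int:
        return sum(1 for f in self.features if f.name == name)


# --------------------------------------------------------------------------
# Gene-name normalisation
# --------------------------------------------------------------------------

#: Canonical vocabulary, genomic order of the typical teleost mitogenome.
CANONICAL_GENES: tuple[str, ...] = (
    "trnF", "rrnS", "trnV", "rrnL", "trnL2", "nad1", "trnI", "trnQ", "trnM",
    "nad2", "trnW", "trnA", "trnN", "OL", "trnC", "trnY", "cox1", "trnS2",
    "trnD", "cox2", "trnK", "atp8", "atp6", "cox3", "trnG", "nad3", "trnR",
    "nad4l", "nad4", "trnH", "trnS1", "trnL1", "nad5", "nad6", "trnE",
    "cytb", "trnT", "trnP", "CR",
)

_ROMAN = {"I": "1", "II": "2", "III": "3"}

_AA3_TO_1 = {
    "PHE": "F", "VAL": "V", "LEU": "L", "ILE": "I", "GLN": "Q", "MET": "M",
    "TRP": "W", "ALA": "A", "ASN": "N", "CYS": "C", "TYR": "Y", "SER": "S",
    "ASP": "D", "LYS": "K", "GLY": "G", "ARG": "R", "HIS": "H", "GLU": "E",
    "THR": "T", "PRO": "P",
}

# Leucine / serine isotypes keyed by anticodon family.
_ISOTYPE = {
    ("L", "UUR"): "trnL2", ("L", "TTR"): "trnL2", ("L", "CUN"): "trnL1",
    ("L", "CTN"): "trnL1", ("L", "1"): "trnL1", ("L", "2"): "trnL2",
    ("S", "UCN"): "trnS2", ("S", "TCN"): "trnS2", ("S", "AGY"): "trnS1",
    ("S", "AGN"): "trnS1", ("S", "1"): "trnS1", ("S", "2"): "trnS2",
}

_PLAIN_ALIASES = {
    # protein-coding genes
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND5": "nad5", "ND6": "nad6", "ND4L": "nad4l", "NAD4L": "nad4l",
    "NADH1": "nad1", "NADH2": "nad2", "NADH3": "nad3", "NADH4": "nad4",
    "NADH5": "nad5", "NADH6": "nad6", "NADH4L": "nad4l",
    "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
    "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
    "COI": "cox1", "COII": "cox2", "COIII": "cox3",
    "COXI": "cox1", "COXII": "cox2", "COXIII": "cox3",
    "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
    "CYTB": "cytb", "COB": "cytb", "CYB": "cytb", "CYTOCHROMEB": "cytb",
    # rRNAs
    "12S": "rrnS", "12SRRNA": "rrnS", "RRNS": "rrnS", "SRRNA": "rrnS",
    "SSU": "rrnS", "16S": "rrnL", "16SRRNA": "rrnL", "RRNL": "rrnL",
    "LRRNA": "rrnL", "LSU": "rrnL",
    # non-coding landmarks
    "CR": "CR", "DLOOP": "CR", "CONTROLREGION": "CR", "CONTROLREGIONCR": "CR",
    "OL": "OL", "ORIL": "OL",
}

_TRNA_RE = re.compile(r"^TRNA?[-._ ]?(?P<rest>.+)$")


def _normalize_trna(rest: str) -> str | None:
    """Map a tRNA designation (``Phe``, ``F``, ``Leu(UUR)``, ``L1``...) to canonical."""
    rest = rest.strip().upper()
    m = re.match(r"^(?P<aa>[A-Z]{1,3})(?P<iso>\d)?(\((?P<anti>[A-Z]{3})\))?$", rest)
    if not m:
        return None
    aa = m.group("aa")
    if len(aa) == 3:
        aa = _AA3_TO_1.get(aa)
        if aa is None:
            return None
    elif aa not in _AA3_TO_1.values():
        return None
    iso = m.group("iso") or ""
    anti = m.group("anti") or ""
    if aa in ("L", "S"):
        key = (aa, iso or anti)
        if key not in _ISOTYPE:
            return None
        return _ISOTYPE[key]
    return f"trn{aa}"


def normalize_gene_name(name: str) -> tuple[str, bool]:
    """Map a gene name to the canonical vocabulary.

    Returns ``(canonical_name, known)``; unknown names come back verbatim
    with ``known=False``. The mapping is idempotent on canonical names.
    """
    raw = name.strip()
    if raw in CANONICAL_GENES:
        return raw, True
    key = re.sub(r"[\s*_\-]", "", raw).upper()
    if key in _PLAIN_ALIASES:
        return _PLAIN_ALIASES[key], True
    # canonical names given in the wrong case, e.g. "NAD4L", "TRNL2"
    lowered = raw.lower()
    for canon in CANONICAL_GENES:
        if lowered == canon.lower():
            return canon, True
    m = _TRNA_RE.match(key)
    if m:
        canon = _normalize_trna(m.group("rest"))
        if canon is not None:
            return canon, True
    # bare amino-acid designations such as "Phe" / "Leu1" / "Ser(AGY)"
    canon = _normalize_trna(key)
    if canon is not None:
        return canon, True
    return raw, False


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gapped) FASTA file, preserving record order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path, newline=None) as handle:  # newline=None folds CRLF
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# Gene feature table (TSV)
# --------------------------------------------------------------------------

_STRAND_ALIASES = {"H": Strand.H, "+": Strand.H, "HEAVY": Strand.H,
                   "L": Strand.L, "-": Strand.L, "LIGHT": Strand.L}
_CLASS_ALIASES = {"PCG": GeneClass.PCG, "CDS": GeneClass.PCG,
                  "TRNA": GeneClass.TRNA, "RRNA": GeneClass.RRNA,
                  "NC": GeneClass.NC, "NONCODING": GeneClass.NC}

_TABLE_COLUMNS = ("name", "start", "end", "strand", "class")


def read_gene_table(path: str | Path, species_id: str | None = None) -> GeneTable:
    """Parse a gene feature table.

    The file carries ``#genome_length`` (required) and ``#species`` (optional)
    pragma lines, then a ``name/start/end/strand/class`` header and one row per
    feature. Tab- and comma-delimited files are both accepted. Gene names are
    normalised; unmappable names are kept verbatim with a warning.
    """
    pragmas: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path, newline=None) as handle:
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                parts = re.split(r"[\t=]", body, maxsplit=1)
                if len(parts) == 2:
                    pragmas[parts[0].strip().lower()] = parts[1].strip()
                continue
            delim = "\t" if "\t" in line else ","
            rows.append([cell.strip() for cell in line.split(delim)])
    if not rows:
        raise FormatError(f"{path}: no feature rows found")
    header = tuple(h.lower() for h in rows[0])
    if header != _TABLE_COLUMNS:
        raise FormatError(
            f"{path}: expected header {_TABLE_COLUMNS}, got {header}"
        )
    if "genome_length" not in pragmas:
        raise FormatError(f"{path}: missing '#genome_length' pragma line")
    try:
        genome_length = int(pragmas["genome_length"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad genome_length {pragmas['genome_length']!r}") from exc

    features: list[GeneFeature] = []
    for row in rows[1:]:
        if len(row) != 5:
            raise FormatError(f"{path}: expected 5 columns, got {len(row)}: {row}")
        name_raw, start_s, end_s, strand_s, class_s = row
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinate in row {row}") from exc
        if start > end:
            raise CoordinateError(f"{path}: {name_raw}: start {start} > end {end}")
        strand_key = strand_s.strip().upper()
        if strand_key not in _STRAND_ALIASES:
            raise FormatError(f"{path}: unknown strand symbol {strand_s!r} for {name_raw}")
        class_key = class_s.strip().upper().replace("-", "")
        if class_key not in _CLASS_ALIASES:
            raise FormatError(f"{path}: unknown gene class {class_s!r} for {name_raw}")
        name, known = normalize_gene_name(name_raw)
        if not known:
            warnings.warn(
                f"{path}: gene name {name_raw!r} not in the canonical vocabulary; "
                "keeping it verbatim",
                stacklevel=2,
            )
        features.append(
            GeneFeature(
                name=name,
                start=start,
                end=end,
                strand=_STRAND_ALIASES[strand_key],
                gene_class=_CLASS_ALIASES[class_key],
            )
        )
    sid = species_id or pragmas.get("species", Path(path).stem)
    return GeneTable(species_id=sid, genome_length=genome_length, features=tuple(features))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"#species\t{table.species_id}\n")
        handle.write(f"#genome_length\t{table.genome_length}\n")
        handle.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in table.features:
            handle.write(
                f"{f.name}\t{f.start}\t{f.end}\t{f.strand.value}\t{f.gene_class.value}\n"
            )


# --------------------------------------------------------------------------
# Newick
# --------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; internal node labels are kept as support labels."""
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"{path}: malformed Newick tree: {exc}") from exc


def write_newick(tree, path: str | Path) -> None:
    """Serialise a DendroPy tree (or any object with ``to_dendropy``)."""
    if hasattr(tree, "to_dendropy"):
        tree = tree.to_dendropy()
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    with open(path, "w") as handle:
        handle.write(out)
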