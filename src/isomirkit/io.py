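"""Core domain types and standard-format readers/writers.

Internal coordinates are 0-based half-open throughout; file formats keep
their native conventions (GFF3 is 1-based inclusive).  All nucleotide
sequences are normalized to the upper-case DNA alphabet on input (U -> T),
so RNA- and DNA-style inputs unify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

TISSUES = ("BF", "F", "GF", "GL", "O")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Internally inconsistent annotation (e.g. mature not in precursor)."""


# ---------------------------------------------------------------------------
# sequence file I/O


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


_VALID_BASES = frozenset("ACGTN")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are upper-cased with U converted to T.  Raises
    :class:`FormatError` (naming the offending line) on malformed headers,
    empty records, or characters outside ``{A,C,G,T,U,N}``.
    """
    records: list[tuple[str, str]] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = _normalize_seq("".join(chunks))
        if not seq:
            raise FormatError(f"{path}: empty sequence for record "
                              f"{header!r} (line {header_line})")
        records.append((header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before any header at line {lineno}")
                norm = _normalize_seq(line)
                bad = set(norm) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}: invalid character(s) {sorted(bad)} at line {lineno}")
                chunks.append(norm)
    flush()
    return records


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read 4-line FASTQ records into ``[(id, sequence, quality), ...]``.

    Truncated records or sequence/quality length mismatches raise
    :class:`FormatError`.  Sequences are normalized like :func:`read_fasta`.
    """
    out: list[tuple[str, str, str]] = []
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                out.append((title.split()[0], _normalize_seq(seq), qual))
    except ValueError as exc:  # Biopython signals malformed FASTQ this way
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SmallRNALibrary:
    """One sequenced small-RNA replicate after (or during) filtering.

    ``reads`` maps unique read sequence -> raw count for the reads retained
    after the final (genome-match) filter; ``stage_tallies`` maps stage name
    -> (redundant, non-redundant) counts along the cascade.
    """

    library_id: str
    tissue: str
    replicate: int
    reads: dict[str, int] = field(default_factory=dict)
    stage_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)
    genome_matched_total: int = 0

    def validate(self) -> None:
        for seq, count in self.reads.items():
            if count < 0:
                raise ConsistencyError(f"{self.library_id}: negative count for {seq}")
            if not set(seq) <= set("ACGT"):
                raise ConsistencyError(f"{self.library_id}: non-ACGT read {seq!r}")
            if not 18 <= len(seq) <= 24:
                raise ConsistencyError(
                    f"{self.library_id}: read length {len(seq)} outside 18-24")
        tallies = [red for red, _ in self.stage_tallies.values()]
        if any(b > a for a, b in zip(tallies, tallies[1:])):
            raise ConsistencyError(
                f"{self.library_id}: stage tallies increase along the cascade")
        if self.reads and self.genome_matched_total != sum(self.reads.values()):
            raise ConsistencyError(
                f"{self.library_id}: genome_matched_total != sum of retained reads")


@dataclass
class LocusModel:
    """One miRNA precursor locus with its reference mature/star sequences.

    ``mature_start``/``star_start`` are 0-based offsets of the references
    within ``precursor_seq``.  Genomic coordinates (``chrom``, ``start``,
    ``end``, ``strand``) are optional: fixture loci carry only identifiers
    and sequences.
    """

    locus_id: str
    precursor_seq: Optional[str] = None
    mature_ref: Optional[str] = None
    mature_start: Optional[int] = None
    star_ref: Optional[str] = None
    star_start: Optional[int] = None
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None

    # typical plant pre-miRNA lengths; outside this range we warn, not fail
    PRECURSOR_RANGE = (41, 227)

    def __post_init__(self) -> None:
        if self.precursor_seq is None:
            return
        n = len(self.precursor_seq)
        lo, hi = self.PRECURSOR_RANGE
        if not lo <= n <= hi:
            warnings.warn(
                f"locus {self.locus_id}: precursor length {n} outside "
                f"the typical {lo}-{hi} nt range", stacklevel=2)
        for arm, ref, start in (("mature", self.mature_ref, self.mature_start),
                                ("star", self.star_ref, self.star_start)):
            if ref is None:
                continue
            if start is None:
                raise ConsistencyError(
                    f"locus {self.locus_id}: {arm} sequence given without position")
            if self.precursor_seq[start:start + len(ref)] != ref:
                raise ConsistencyError(
                    f"locus {self.locus_id}: {arm} reference is not the "
                    f"precursor substring at offset {start}")
        if self.mature_ref is not None and self.star_ref is not None:
            m = (self.mature_start, self.mature_start + len(self.mature_ref))
            s = (self.star_start, self.star_start + len(self.star_ref))
            if max(m[0], s[0]) < min(m[1], s[1]):
                raise ConsistencyError(
                    f"locus {self.locus_id}: mature and star intervals overlap")

    @property
    def mature_interval(self) -> Optional[tuple[int, int]]:
        if self.mature_ref is None:
            return None
        return (self.mature_start, self.mature_start + len(self.mature_ref))

    @property
    def star_interval(self) -> Optional[tuple[int, int]]:
        if self.star_ref is None:
            return None
        return (self.star_start, self.star_start + len(self.star_ref))


@dataclass
class FilterStatsRow:
    """Per-library read accounting along the filtering cascade."""

    library_id: str
    raw: int
    adapter_matched: int
    length_filtered: int
    low_complexity_redundant: int
    low_complexity_nonredundant: int
    contaminant_redundant: int
    contaminant_nonredundant: int
    genome_matched_redundant: int
    genome_matched_nonredundant: int

    def __post_init__(self) -> None:
        cascade = (self.raw, self.adapter_matched, self.length_filtered,
                   self.low_complexity_redundant, self.contaminant_redundant,
                   self.genome_matched_redundant)
        if any(b > a for a, b in zip(cascade, cascade[1:])):
            raise ConsistencyError(
                f"{self.library_id}: non-monotone cascade tallies {cascade}")


class ExpressionMatrix:
    """An isomiR x library table of normalized counts (RPM).

    Rows live at (locus, sequence) resolution; a read assigned to several
    loci appears once per locus in the per-locus view and exactly once in
    the de-duplicated sequence view used for whole-miRNome statistics.
    """

    def __init__(self, table: pd.DataFrame, libraries: Optional[list[str]] = None):
        required = {"locus", "sequence"}
        if not required <= set(table.columns):
            raise ValueError("ExpressionMatrix needs 'locus' and 'sequence' columns")
        if "accession" not in table.columns:
            table = table.assign(accession=pd.NA)
        if libraries is None:
            libraries = [c for c in table.columns
                         if c not in ("locus", "sequence", "accession")]
        values = table[libraries].astype(float)
        if (values.values < 0).any():
            raise ValueError("negative normalized counts")
        self.table = pd.concat(
            [table[["locus", "sequence", "accession"]].reset_index(drop=True),
             values.reset_index(drop=True)], axis=1)
        self.libraries = list(libraries)

    # -- views ---------------------------------------------------------

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.table["locus"]))

    def per_locus(self, locus: str) -> pd.DataFrame:
        """Rows of one locus, indexed by sequence."""
        sub = self.table[self.table["locus"] == locus]
        if sub.empty:
            raise KeyError(f"unknown locus {locus!r}")
        return sub.set_index("sequence")[self.libraries]

    def dedup(self) -> pd.DataFrame:
        """Sequence-level view: multi-locus reads counted once."""
        return (self.table.drop_duplicates("sequence")
                .set_index("sequence")[self.libraries])

    def loci_of(self, sequence: str) -> set[str]:
        return set(self.table.loc[self.table["sequence"] == sequence, "locus"])

    def sequence_of(self, accession: str) -> str:
        seqs = self.table.loc[self.table["accession"] == accession, "sequence"].unique()
        if len(seqs) == 0:
            raise KeyError(f"unknown accession {accession!r}")
        if len(seqs) > 1:
            raise KeyError(f"accession {accession!r} maps to {len(seqs)} sequences; "
                           "look up by sequence instead")
        return seqs[0]

    def resolve(self, key: str) -> str:
        """Map an accession or a sequence to the row sequence."""
        if set(key) <= set("ACGTN"):
            return key
        return self.sequence_of(key)

    def value(self, key: str, library: str) -> float:
        seq = self.resolve(key)
        row = self.table[self.table["sequence"] == seq].iloc[0]
        return float(row[library])

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.9g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# locus annotation (GFF3 + FASTA)


def load_locus_annotation(gff_path: str | Path,
                          precursor_fasta: str | Path,
                          refs_fasta: str | Path) -> list[LocusModel]:
    """Assemble :class:`LocusModel` objects from a GFF3 annotation.

    Expects ``miRNA_primary_transcript`` features (ID = locus id) with child
    ``miRNA`` features whose IDs end in ``.mature`` / ``.star``.
    ``precursor_fasta`` holds one record per locus id; ``refs_fasta`` holds
    the mature/star sequences under the child-feature IDs.  GFF coordinates
    (1-based inclusive) are converted to 0-based half-open, and mature/star
    positions are re-expressed relative to the precursor in 5'->3'
    precursor orientation.
    """
    import gffutils

    precursors = dict(read_fasta(precursor_fasta))
    refs = dict(read_fasta(refs_fasta))
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)

    loci: list[LocusModel] = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        locus_id = feat.id
        p_start, p_end = feat.start - 1, feat.end  # to 0-based half-open
        precursor = precursors.get(locus_id)
        if precursor is None:
            raise ConsistencyError(f"locus {locus_id}: no precursor FASTA record")
        if len(precursor) != p_end - p_start:
            raise ConsistencyError(
                f"locus {locus_id}: precursor length {len(precursor)} does not "
                f"match the annotated interval")
        kwargs: dict = dict(locus_id=locus_id, precursor_seq=precursor,
                            chrom=feat.seqid, start=p_start, end=p_end,
                            strand=feat.strand)
        for child in db.children(feat, featuretype="miRNA"):
            arm = child.id.rsplit(".", 1)[-1]
            if arm not in ("mature", "star"):
                continue
            c_start, c_end = child.start - 1, child.end
            if feat.strand == "-":
                offset = p_end - c_end
            else:
                offset = c_start - p_start
            ref = refs.get(child.id)
            if ref is None:
                raise ConsistencyError(f"locus {locus_id}: no reference sequence "
                                       f"for {child.id}")
            if precursor[offset:offset + len(ref)] != ref:
                raise ConsistencyError(
                    f"locus {locus_id}: {arm} sequence does not match the "
                    f"precursor slice at offset {offset}")
            kwargs[f"{arm}_ref"] = ref
            kwargs[f"{arm}_start"] = offset
        loci.append(LocusModel(**kwargs))
    return loci


def write_locus_annotation(gff_path: str | Path,
                           precursor_fasta: str | Path,
                           refs_fasta: str | Path,
                           loci: Iterable[LocusModel]) -> None:
    """Inverse of :func:`load_locus_annotation` (native GFF3 coordinates)."""
    loci = list(loci)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.locus_id}"
            fh.write("\t".join([loc.chrom, "isomirkit", "miRNA_primary_transcript",
                                str(loc.start + 1), str(loc.end), ".", loc.strand,
                                ".", attrs]) + "\n")
            for arm, ref, off in ((".mature", loc.mature_ref, loc.mature_start),
                                  (".star", loc.star_ref, loc.star_start)):
                if ref is None:
                    continue
                if loc.strand == "-":
                    g_end = loc.end - off
                    g_start = g_end - len(ref)
                else:
                    g_start = loc.start + off
                    g_end = g_start + len(ref)
                fh.write("\t".join([loc.chrom, "isomirkit", "miRNA",
                                    str(g_start + 1), str(g_end), ".", loc.strand,
                                    ".", f"ID={loc.locus_id}{arm};"
                                         f"Parent={loc.locus_id}"]) + "\n")
    write_fasta(precursor_fasta, [(l.locus_id, l.precursor_seq) for l in loci])
    refs = []
    for loc in loci:
        refs.append((f"{loc.locus_id}.mature", loc.mature_ref))
        if loc.star_ref is not None:
            refs.append((f"{loc.locus_id}.star", loc.star_ref))
    write_fasta(refs_fasta, refs)


def tissue_of(library_id: str) -> str:
    """``'BF1' -> 'BF'`` — strip the trailing replicate number."""
    return library_id.rstrip("0123456789")


def replicate_of(library_id: str) -> int:
    digits = library_id[len(tissue_of(library_id)):]
    if not digits:
        raise ValueError(f"library id {library_id!r} has no replicate number")
    return int(digits)
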