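"""The small-RNA read filtering cascade and perfect-match genome mapping.

Stages, in order: 3' adapter trimming -> length selection (18-24 nt) ->
low-complexity removal -> rRNA/tRNA contaminant removal -> full-length
zero-mismatch genome matching.  Each stage records both redundant (read)
and non-redundant (distinct sequence) tallies, mirroring the accounting a
sequencing report would print.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import (FilterStatsRow, LocusModel, SmallRNALibrary, reverse_complement,
                 tissue_of, replicate_of)

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class FilterConfig:
    adapter3: str = DEFAULT_ADAPTER3
    min_len: int = 18
    max_len: int = 24
    min_distinct_bases: int = 3
    min_adapter_overlap: int = 6
    contaminant_set: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")


@dataclass(frozen=True)
class GenomeHit:
    """A full-length perfect match of a read to the genome."""

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str


def trim_adapter(read: str, config: FilterConfig) -> Optional[str]:
    """Return the insert before the leftmost adapter occurrence, or None.

    An adapter is detected as an exact match of an adapter *prefix* of
    length >= ``min_adapter_overlap`` (shorter only when the read end
    truncates it).  Reads with no detectable adapter are rejected: with
    fixed-length machine reads the insert boundary is then unknown.
    """
    adapter = config.adapter3
    k = config.min_adapter_overlap
    n = len(read)
    for i in range(n - k + 1):
        span = min(len(adapter), n - i)
        if read[i:i + span] == adapter[:span]:
            return read[:i]
    return None


def filter_length(sequence: str, config: FilterConfig) -> bool:
    """Keep iff ``min_len <= len <= max_len`` (both inclusive)."""
    return config.min_len <= len(sequence) <= config.max_len


def filter_complexity(sequence: str, config: FilterConfig) -> bool:
    """Drop homopolymers and simple repeats: keep iff the sequence uses at
    least ``min_distinct_bases`` distinct nucleotides."""
    return len(set(sequence)) >= config.min_distinct_bases


def filter_contaminants(sequence: str, config: FilterConfig) -> bool:
    """Keep iff the read is not a substring of any contaminant reference,
    on either strand (reads are fragments of full-length rRNA/tRNA)."""
    if not config.contaminant_set:
        return True
    rc = reverse_complement(sequence)
    for ref in config.contaminant_set:
        if sequence in ref or rc in ref:
            return False
    return True


class GenomeIndex:
    """Exact-search index over one or more chromosomes (both strands).

    A k-mer seed table keyed on read prefixes; candidate positions are
    verified by full-length comparison, so every reported hit is a
    zero-mismatch full-length occurrence.
    """

    def __init__(self, sequences: Mapping[str, str] | str, k: int = 12):
        if isinstance(sequences, str):
            sequences = {"chr1": sequences}
        self.sequences = dict(sequences)
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i:i + k], []).append((chrom, i))

    def _find_forward(self, query: str) -> list[tuple[str, int]]:
        if len(query) < self.k:  # fall back to a direct scan
            out = []
            for chrom, seq in self.sequences.items():
                p = seq.find(query)
                while p != -1:
                    out.append((chrom, p))
                    p = seq.find(query, p + 1)
            return out
        hits = []
        for chrom, pos in self._seeds.get(query[:self.k], ()):
            if self.sequences[chrom][pos:pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits

    def find(self, read: str) -> list[GenomeHit]:
        """All full-length perfect-match placements on both strands.

        Reads containing N are discarded before search (a perfect match is
        undefined for ambiguous bases).
        """
        if "N" in read or not read:
            return []
        hits = [GenomeHit(c, p, p + len(read), "+")
                for c, p in self._find_forward(read)]
        rc = reverse_complement(read)
        hits += [GenomeHit(c, p, p + len(read), "-")
                 for c, p in self._find_forward(rc)]
        return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def match_genome(sequence: str, genome_index: GenomeIndex) -> list[GenomeHit]:
    return genome_index.find(sequence)


def assign_loci(hits: Iterable[GenomeHit], loci: Iterable[LocusModel]) -> set[str]:
    """Locus ids whose genomic interval fully contains a same-strand hit.

    A read related to several loci is assigned to all of them; hits outside
    every locus leave the read unassigned (empty set).
    """
    assigned = set()
    for hit in hits:
        for locus in loci:
            if locus.chrom is None:
                continue
            if (locus.chrom == hit.chrom and locus.strand == hit.strand
                    and locus.start <= hit.start and hit.end <= locus.end):
                assigned.add(locus.locus_id)
    return assigned


@dataclass
class CascadeResult:
    library: SmallRNALibrary
    stats: FilterStatsRow
    locus_assignments: dict[str, set[str]] = field(default_factory=dict)


def run_cascade(fastq_records: Iterable[tuple[str, str, str]],
                genome_index: Optional[GenomeIndex],
                loci: Sequence[LocusModel],
                config: FilterConfig,
                library_id: str = "lib1") -> CascadeResult:
    """Apply the full cascade to one library and account for every stage.

    Accepts the in-memory record list produced by :func:`isomirkit.io.read_fastq`.
    When ``genome_index`` is None the genome-match stage keeps everything
    (useful for pre-mapped inputs).
    """
    records = list(fastq_records)
    raw_counts = Counter(seq for _, seq, _ in records)
    n_raw = sum(raw_counts.values())
    if n_raw == 0:
        warnings.warn(f"{library_id}: empty FASTQ", stacklevel=2)

    def tally(counts: Counter) -> tuple[int, int]:
        return sum(counts.values()), len(counts)

    # adapter: trim each distinct raw sequence once
    trimmed: Counter = Counter()
    for seq, count in raw_counts.items():
        insert = trim_adapter(seq, config)
        if insert is not None and insert:
            trimmed[insert] += count

    length_ok = Counter({s: c for s, c in trimmed.items()
                         if filter_length(s, config)})
    complex_ok = Counter({s: c for s, c in length_ok.items()
                          if filter_complexity(s, config)})
    if not config.contaminant_set:
        warnings.warn(f"{library_id}: empty contaminant set, none removed",
                      stacklevel=2)
    contam_ok = Counter({s: c for s, c in complex_ok.items()
                         if filter_contaminants(s, config)})

    assignments: dict[str, set[str]] = {}
    if genome_index is None:
        genome_ok = contam_ok
    else:
        genome_ok = Counter()
        for seq, count in contam_ok.items():
            hits = genome_index.find(seq)
            if hits:
                genome_ok[seq] = count
                assignments[seq] = assign_loci(hits, loci)

    stats = FilterStatsRow(
        library_id=library_id,
        raw=n_raw,
        adapter_matched=sum(trimmed.values()),
        length_filtered=sum(length_ok.values()),
        low_complexity_redundant=tally(complex_ok)[0],
        low_complexity_nonredundant=tally(complex_ok)[1],
        contaminant_redundant=tally(contam_ok)[0],
        contaminant_nonredundant=tally(contam_ok)[1],
        genome_matched_redundant=tally(genome_ok)[0],
        genome_matched_nonredundant=tally(genome_ok)[1],
    )
    library = SmallRNALibrary(
        library_id=library_id,
        tissue=tissue_of(library_id),
        replicate=replicate_of(library_id) if library_id[-1].isdigit() else 1,
        reads=dict(genome_ok),
        stage_tallies={
            "raw": (n_raw, len(raw_counts)),
            "adapter": (sum(trimmed.values()), len(trimmed)),
            "length": (sum(length_ok.values()), len(length_ok)),
            "low_complexity": tally(complex_ok),
            "contaminant": tally(contam_ok),
            "genome": tally(genome_ok),
        },
        genome_matched_total=sum(genome_ok.values()),
    )
    library.validate()
    return CascadeResult(library=library, stats=stats,
                         locus_assignments=assignments)
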