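"""IsomiR cataloging: RPM normalization, arm/offset annotation, dominance.

An isomiR is annotated by exact placement of its sequence within the
precursor, against whichever arm reference (mature or star) it overlaps
most.  Offsets are expressed in precursor 5'->3' orientation for both
arms: ``offset5 = start - reference start`` (negative = 5' extension) and
``offset3 = end - reference end`` (positive = 3' extension).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .io import (ExpressionMatrix, LocusModel, SmallRNALibrary, tissue_of)

#: beyond this end-offset magnitude a placement is considered spurious
MAX_OFFSET = 8


def normalize_counts(raw_count: float, genome_matched_total: int,
                     library_id: str = "?") -> float:
    """Reads per million genome-matched reads."""
    if genome_matched_total <= 0:
        raise ValueError(
            f"library {library_id}: normalization undefined for "
            f"genome_matched_total={genome_matched_total}")
    return raw_count / genome_matched_total * 1e6


class IsomiRAnnotation(NamedTuple):
    arm: str                 # 'mature' | 'star' | 'unaligned'
    offset5: Optional[int]
    offset3: Optional[int]
    ambiguous: bool = False


def annotate_isomir(sequence: str, locus: LocusModel) -> IsomiRAnnotation:
    """Place a sequence within the precursor and classify its arm.

    All exact placements are enumerated; each is scored by its overlap
    with the mature and star reference intervals and the best (placement,
    arm) pair wins, ties going to the placement nearest its reference
    start.  Sequences with no placement, no reference overlap, or end
    offsets beyond ``MAX_OFFSET`` are ``unaligned``.  Multiple viable
    placements are flagged ambiguous.
    """
    unaligned = IsomiRAnnotation("unaligned", None, None)
    if locus.precursor_seq is None:
        return unaligned
    placements = []
    start = locus.precursor_seq.find(sequence)
    while start != -1:
        placements.append(start)
        start = locus.precursor_seq.find(sequence, start + 1)
    if not placements:
        return unaligned

    refs = []
    if locus.mature_ref is not None:
        refs.append(("mature", *locus.mature_interval))
    if locus.star_ref is not None:
        refs.append(("star", *locus.star_interval))
    if not refs:
        return unaligned

    best = None
    for pos in placements:
        end = pos + len(sequence)
        for arm, ref_start, ref_end in refs:
            overlap = min(end, ref_end) - max(pos, ref_start)
            if overlap <= 0:
                continue
            candidate = (overlap, -abs(pos - ref_start), arm, pos,
                         pos - ref_start, end - ref_end)
            if best is None or candidate[:2] > best[:2]:
                best = candidate
    if best is None:
        return unaligned
    _, _, arm, _, off5, off3 = best
    if abs(off5) > MAX_OFFSET or abs(off3) > MAX_OFFSET:
        return unaligned
    return IsomiRAnnotation(arm, off5, off3, ambiguous=len(placements) > 1)


@dataclass
class IsomiRRecord:
    """One variant sequence at one locus with per-library abundance."""

    sequence: str
    locus_id: str
    arm: str
    offset5: Optional[int]
    offset3: Optional[int]
    rpm: dict[str, float] = field(default_factory=dict)
    accession: Optional[str] = None


def build_catalog(source: ExpressionMatrix | Sequence[SmallRNALibrary],
                  loci: Optional[Sequence[LocusModel]] = None,
                  assignments: Optional[dict[str, dict[str, set[str]]]] = None,
                  ) -> tuple[ExpressionMatrix, list[IsomiRRecord]]:
    """Turn locus-assigned counts into an annotated, normalized catalog.

    ``source`` is either an already-normalized :class:`ExpressionMatrix`
    (e.g. the packaged fixture) or a list of filtered libraries, in which
    case ``assignments`` maps library id -> sequence -> locus-id set (as
    produced by the filtering cascade) and counts are RPM-normalized by
    each library's genome-matched total.  A sequence assigned to a locus
    it cannot be placed in is kept with ``arm='unaligned'`` and a warning.
    """
    locus_models = {l.locus_id: l for l in (loci or [])}

    if isinstance(source, ExpressionMatrix):
        matrix = source
    else:
        libraries = list(source)
        lib_ids = [lib.library_id for lib in libraries]
        rows: dict[tuple[str, str], dict[str, float]] = {}
        for lib in libraries:
            assign = (assignments or {}).get(lib.library_id, {})
            for seq, count in lib.reads.items():
                rpm = normalize_counts(count, lib.genome_matched_total,
                                       lib.library_id)
                for locus_id in assign.get(seq, set()):
                    rows.setdefault((locus_id, seq),
                                    dict.fromkeys(lib_ids, 0.0))[lib.library_id] = rpm
        table = pd.DataFrame(
            [{"locus": locus_id, "sequence": seq, **vals}
             for (locus_id, seq), vals in sorted(rows.items())])
        matrix = ExpressionMatrix(table, libraries=lib_ids)

    records = []
    for _, row in matrix.table.iterrows():
        locus_id = row["locus"]
        model = locus_models.get(locus_id)
        if model is not None and model.precursor_seq is not None:
            ann = annotate_isomir(row["sequence"], model)
            if ann.arm == "unaligned":
                warnings.warn(f"sequence {row['sequence']} cannot be placed "
                              f"in locus {locus_id}", stacklevel=2)
        else:
            ann = IsomiRAnnotation("unaligned", None, None)
        records.append(IsomiRRecord(
            sequence=row["sequence"], locus_id=locus_id, arm=ann.arm,
            offset5=ann.offset5, offset3=ann.offset3,
            rpm={lib: float(row[lib]) for lib in matrix.libraries},
            accession=None if pd.isna(row["accession"]) else row["accession"]))
    return matrix, records


# ---------------------------------------------------------------------------
# dominance


@dataclass
class DominanceReport:
    """Ranked variants per (locus, library) and per (locus, tissue).

    ``per_library[(locus, lib)]`` and ``per_tissue[(locus, tissue)]`` are
    RPM-sorted ``[(sequence, rpm), ...]``; all-zero groups are empty.
    ``invariant[locus]`` is True when the tissue-level dominant read is the
    same in every tissue; ``ties`` collects groups whose top two entries
    are exactly tied (broken lexicographically by sequence).
    """

    per_library: dict[tuple[str, str], list[tuple[str, float]]]
    per_tissue: dict[tuple[str, str], list[tuple[str, float]]]
    invariant: dict[str, bool]
    tissues: list[str]
    ties: set[tuple[str, str]] = field(default_factory=set)

    def dominant(self, locus: str, group: str) -> Optional[str]:
        ranked = self.per_library.get((locus, group)) \
            or self.per_tissue.get((locus, group))
        return ranked[0][0] if ranked else None

    def second(self, locus: str, group: str) -> Optional[str]:
        ranked = self.per_library.get((locus, group)) \
            or self.per_tissue.get((locus, group))
        return ranked[1][0] if ranked and len(ranked) > 1 else None


def _rank(series: pd.Series) -> list[tuple[str, float]]:
    nonzero = series[series > 0]
    ordered = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(seq, float(v)) for seq, v in ordered]


def dominance_table(matrix: ExpressionMatrix,
                    average_replicates: bool = True) -> DominanceReport:
    """Rank isomiRs by RPM within each locus, per library and per tissue.

    Tissue-level ranking uses the arithmetic mean of the replicates' RPM
    when ``average_replicates`` is True; otherwise a tissue's dominant is
    only defined when all its replicates agree (per-replicate convention).
    """
    tissues = list(dict.fromkeys(tissue_of(lib) for lib in matrix.libraries))
    by_tissue = {t: [lib for lib in matrix.libraries if tissue_of(lib) == t]
                 for t in tissues}
    per_library: dict[tuple[str, str], list[tuple[str, float]]] = {}
    per_tissue: dict[tuple[str, str], list[tuple[str, float]]] = {}
    invariant: dict[str, bool] = {}
    ties: set[tuple[str, str]] = set()

    for locus in matrix.loci:
        sub = matrix.per_locus(locus)
        for lib in matrix.libraries:
            ranked = _rank(sub[lib])
            per_library[(locus, lib)] = ranked
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                ties.add((locus, lib))
        tissue_dominants = []
        for t in tissues:
            ranked = _rank(sub[by_tissue[t]].mean(axis=1))
            per_tissue[(locus, t)] = ranked
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                ties.add((locus, t))
            if average_replicates:
                tissue_dominants.append(ranked[0][0] if ranked else None)
            else:
                reps = {per_library[(locus, lib)][0][0]
                        if per_library[(locus, lib)] else None
                        for lib in by_tissue[t]}
                tissue_dominants.append(reps.pop() if len(reps) == 1 else None)
        invariant[locus] = (len(set(tissue_dominants)) == 1
                            and tissue_dominants[0] is not None)
    return DominanceReport(per_library=per_library, per_tissue=per_tissue,
                           invariant=invariant, tissues=tissues, ties=ties)


def sample_invariant_dominants(report: DominanceReport) -> set[str]:
    """Distinct dominant reads of loci whose dominant is tissue-invariant."""
    out = set()
    for locus, flag in report.invariant.items():
        if flag:
            out.add(report.per_tissue[(locus, report.tissues[0])][0][0])
    return out


# ---------------------------------------------------------------------------
# 5' composition


def five_prime_composition(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per (locus, library): fraction of locus RPM whose read starts with T.

    Plant AGO1 loading favours a 5' uridine, so a high fraction indicates
    5'-end conservation among a locus's variants.  Zero-abundance cells are
    reported as missing.  Also reports whether the locus's overall most
    abundant variant starts with T.
    """
    rows = []
    for locus in matrix.loci:
        sub = matrix.per_locus(locus)
        starts_t = sub.index.str.startswith("T")
        total = sub.sum(axis=0)
        dominant = sub.sum(axis=1).idxmax()
        for lib in matrix.libraries:
            frac = (sub.loc[starts_t, lib].sum() / total[lib]
                    if total[lib] > 0 else float("nan"))
            rows.append(dict(locus=locus, library=lib, fraction_t=frac,
                             dominant_starts_t=dominant.startswith("T")))
    return pd.DataFrame(rows)
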