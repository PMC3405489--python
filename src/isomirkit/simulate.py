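"""Forward simulation of small-RNA-seq libraries with isomiR structure.

The generator emulates the structure of a multi-tissue plant small-RNA
experiment: a random genome carrying hairpin precursor loci, each producing
a population of templated length variants (isomiRs) from imprecise Dicer
cleavage at the 5' and 3' ends of both duplex arms, sequenced as
fixed-length machine reads with a 3' adapter, plus rRNA/tRNA-like
contaminant reads and low-complexity reads at configurable fractions.
Every library ships with a ground-truth table (arm, end offsets, expected
RPM) so the downstream pipeline can be tested for exact parameter recovery.

Replicate noise is a per-(locus, library) negative-binomial size factor
(gamma-Poisson total, then a multinomial split over isomiR variants); with
``dispersion == 0`` counts are deterministic (largest-remainder rounding of
the expected values), which makes replicates exactly identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import DEFAULT_ADAPTER3
from .io import LocusModel, SmallRNALibrary, reverse_complement

_BASES = np.array(list("ACGT"))

# geometry of the constructed hairpin
_PAD = 3      # precursor slack on each side of the duplex arms
_LOOP = 15    # spacer between mature and star arms


@dataclass
class CutSiteModel:
    """Probabilities of Dicer cut-site offsets at each duplex end.

    Offsets are in precursor 5'->3' orientation: negative ``offset5``
    extends the 5' end, positive ``offset3`` extends the 3' end.
    ``arm_mature_fraction`` is the probability that a molecule comes from
    the mature arm rather than the star arm.
    """

    offset5_probs: Mapping[int, float] = field(
        default_factory=lambda: {-1: 0.15, 0: 0.70, 1: 0.15})
    offset3_probs: Mapping[int, float] = field(
        default_factory=lambda: {-1: 0.20, 0: 0.60, 1: 0.20})
    arm_mature_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name, probs in (("offset5_probs", self.offset5_probs),
                            ("offset3_probs", self.offset3_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(not -3 <= o <= 3 for o in probs):
                raise ValueError(f"{name} offsets must lie in [-3, 3]")
        if not 0 < self.arm_mature_fraction <= 1:
            raise ValueError("arm_mature_fraction must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study design and noise parameters for one simulated experiment.

    Defaults mirror the emulated study: five tissues, three replicates
    each.  ``depth`` is the expected read count per library (a scale
    parameter: expected RPM values are depth-invariant).
    """

    tissues: Sequence[str] = ("BF", "F", "GF", "GL", "O")
    replicates_per_tissue: int = 3
    depth: int = 100_000
    dispersion: float = 0.05
    tissue_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    contaminant_fraction: float = 0.15
    low_complexity_fraction: float = 0.01
    cut_model: CutSiteModel = field(default_factory=CutSiteModel)
    locus_weights: Optional[Mapping[str, float]] = None
    adapter3: str = DEFAULT_ADAPTER3
    read_length: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("contaminant_fraction", "low_complexity_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def library_ids(self) -> list[str]:
        return [f"{t}{r}" for t in self.tissues
                for r in range(1, self.replicates_per_tissue + 1)]

    def library_rng(self, tissue: str, replicate: int) -> np.random.Generator:
        """One reproducible, stream-independent generator per library."""
        tidx = list(self.tissues).index(tissue)
        return np.random.default_rng([self.seed, tidx, replicate])


# ---------------------------------------------------------------------------
# genome and locus construction


def make_genome(length: int, seed: int | np.random.Generator) -> str:
    """An i.i.d. uniform A/C/G/T sequence; reproducible for a fixed seed."""
    if length <= 0:
        raise ValueError("genome length must be > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    return "".join(_BASES[rng.integers(0, 4, size=length)])


class PlacementError(ValueError):
    """A precursor cannot be planted at the requested position."""


def plant_precursor(genome: str, position: int, mature_seq: str,
                    seed: int | np.random.Generator,
                    existing: Iterable[LocusModel] = (),
                    locus_id: str = "locus1",
                    chrom: str = "chr1") -> tuple[str, LocusModel]:
    """Overwrite the genome with a hairpin locus and return its model.

    The hairpin is ``pad + mature + loop + star + pad``.  The star arm is
    the reverse complement of the mature-pairing region placed so that the
    duplex carries the canonical 2-nt 3' overhangs: ``star[:-2]`` reverse-
    complements ``mature[:-2]``, and the star's own 2-nt 3' overhang is
    drawn at random.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    m = len(mature_seq)
    if not 18 <= m <= 24:
        raise ValueError(f"mature length {m} outside 18-24")
    star = reverse_complement(mature_seq[:-2]) + "".join(rng.choice(_BASES, size=2))
    pad5 = "".join(rng.choice(_BASES, size=_PAD))
    pad3 = "".join(rng.choice(_BASES, size=_PAD))
    loop = "".join(rng.choice(_BASES, size=_LOOP))
    precursor = pad5 + mature_seq + loop + star + pad3
    end = position + len(precursor)
    if position < 0 or end > len(genome):
        raise PlacementError(
            f"locus {locus_id}: precursor [{position}, {end}) outside the genome")
    for other in existing:
        if other.chrom == chrom and max(other.start, position) < min(other.end, end):
            raise PlacementError(
                f"locus {locus_id} overlaps planted locus {other.locus_id}")
    locus = LocusModel(locus_id=locus_id, precursor_seq=precursor,
                       mature_ref=mature_seq, mature_start=_PAD,
                       star_ref=star, star_start=_PAD + m + _LOOP,
                       chrom=chrom, start=position, end=end, strand="+")
    modified = genome[:position] + precursor + genome[end:]
    return modified, locus


def make_loci(genome_length: int, n_loci: int,
              seed: int | np.random.Generator,
              mature_lengths: Sequence[int] = (21, 22),
              adapter3: str = DEFAULT_ADAPTER3,
              min_adapter_overlap: int = 6) -> tuple[str, list[LocusModel]]:
    """A random genome with ``n_loci`` evenly spaced hairpin loci.

    Precursors are redrawn until they contain no seed-length adapter prefix,
    so simulated inserts can never trigger a spurious adapter trim.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    genome = make_genome(genome_length, rng)
    max_prec = 2 * max(mature_lengths) + _LOOP + 2 * _PAD
    stride = genome_length // n_loci
    if stride < max_prec + 10:
        raise PlacementError("genome too short for the requested locus count")
    forbidden = adapter3[:min_adapter_overlap]
    loci: list[LocusModel] = []
    for i in range(n_loci):
        pos = i * stride + 5
        for _ in range(200):
            m = int(rng.choice(list(mature_lengths)))
            mature = "".join(rng.choice(_BASES, size=m))
            genome2, locus = plant_precursor(
                genome, pos, mature, rng, existing=loci,
                locus_id=f"sim_{i + 1}", chrom="chr1")
            if forbidden not in locus.precursor_seq:
                genome = genome2
                loci.append(locus)
                break
        else:  # pragma: no cover
            raise PlacementError("could not draw an adapter-free precursor")
    return genome, loci


def make_contaminants(seed: int | np.random.Generator, n: int = 5,
                      length_range: tuple[int, int] = (120, 300),
                      adapter3: str = DEFAULT_ADAPTER3,
                      min_adapter_overlap: int = 6) -> list[str]:
    """Synthetic rRNA/tRNA-like reference sequences (adapter-seed free)."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    forbidden = adapter3[:min_adapter_overlap]
    out = []
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ref = "".join(rng.choice(_BASES, size=length))
        if forbidden not in ref:
            out.append(ref)
    return out


# ---------------------------------------------------------------------------
# count sampling


def isomir_cells(locus: LocusModel, cut_model: CutSiteModel
                 ) -> list[tuple[str, str, int, int, float]]:
    """The (sequence, arm, offset5, offset3, probability) support of a locus.

    Offsets extending beyond the precursor are clipped with a warning.
    """
    cells = []
    arms = [("mature", cut_model.arm_mature_fraction,
             locus.mature_start, locus.mature_start + len(locus.mature_ref))]
    if cut_model.arm_mature_fraction < 1.0:
        if locus.star_ref is None:
            raise ValueError(f"locus {locus.locus_id}: star arm requested "
                             "but no star reference")
        arms.append(("star", 1.0 - cut_model.arm_mature_fraction,
                     locus.star_start, locus.star_start + len(locus.star_ref)))
    n = len(locus.precursor_seq)
    for arm, arm_p, ref_start, ref_end in arms:
        for o5, p5 in cut_model.offset5_probs.items():
            for o3, p3 in cut_model.offset3_probs.items():
                s, e = ref_start + o5, ref_end + o3
                if s < 0 or e > n:
                    warnings.warn(
                        f"locus {locus.locus_id}: offsets ({o5},{o3}) extend "
                        "beyond the precursor; clipped", stacklevel=2)
                    s, e = max(s, 0), min(e, n)
                cells.append((locus.precursor_seq[s:e], arm, o5, o3,
                              arm_p * p5 * p3))
    return cells


def _deterministic_round(expected: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of nonnegative expectations to sum ``total``."""
    base = np.floor(expected).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(expected - base), kind="stable")
        base[order[:short]] += 1
    return base


def sample_isomir_counts(locus: LocusModel, cut_model: CutSiteModel,
                         expected_total: float, dispersion: float,
                         rng: np.random.Generator) -> dict[str, int]:
    """Draw per-isomiR read counts for one locus in one library.

    With ``dispersion == 0`` the counts are the deterministically rounded
    expectations; otherwise the locus total is gamma-Poisson (negative
    binomial, mean ``expected_total``, variance ``mean + dispersion*mean^2``)
    and the variants are a multinomial split of that total.
    """
    if expected_total <= 0:
        raise ValueError("expected_total must be > 0")
    cells = isomir_cells(locus, cut_model)
    probs = np.array([c[4] for c in cells])
    probs = probs / probs.sum()
    if dispersion == 0:
        counts = _deterministic_round(probs * expected_total,
                                      int(round(expected_total)))
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion) * expected_total
        total = rng.poisson(lam)
        counts = rng.multinomial(total, probs)
    out: dict[str, int] = {}
    for (seq, *_), count in zip(cells, counts):
        if count:
            out[seq] = out.get(seq, 0) + int(count)
    return out


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class SimulatedLibrary:
    library_id: str
    records: list[tuple[str, str, str]]        # FASTQ (id, raw seq, quality)
    truth: SmallRNALibrary                      # expected cascade output
    truth_table: pd.DataFrame                   # per-isomiR ground truth


def _locus_shares(loci: Sequence[LocusModel], config: SimulationConfig,
                  tissue: str) -> dict[str, float]:
    weights = {}
    for locus in loci:
        w = 1.0 if config.locus_weights is None \
            else float(config.locus_weights.get(locus.locus_id, 1.0))
        fc = float(config.tissue_effects.get(locus.locus_id, {}).get(tissue, 1.0))
        weights[locus.locus_id] = w * fc
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def simulate_library(loci: Sequence[LocusModel], config: SimulationConfig,
                     tissue: str, replicate: int,
                     contaminants: Sequence[str] = (),
                     emit_records: bool = True) -> SimulatedLibrary:
    """One replicate library: raw FASTQ records plus ground truth.

    Raw reads are the insert followed by the 3' adapter, truncated (or
    A-padded) to the fixed machine read length, so adapter trimming is
    always exercised.  The truth table lists every isomiR's arm, end
    offsets, sampled count and expected RPM
    (cell probability x locus expression share x 10^6).

    ``emit_records=False`` skips read assembly (empty ``records``) for
    count-level studies; the sampled counts are identical either way.
    """
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    rng = config.library_rng(tissue, replicate)
    library_id = f"{tissue}{replicate}"
    shares = _locus_shares(loci, config, tissue)
    clean_depth = config.depth * (1.0 - config.contaminant_fraction
                                  - config.low_complexity_fraction)

    reads: dict[str, int] = {}
    truth_rows = []
    for locus in loci:
        share = shares[locus.locus_id]
        counts = sample_isomir_counts(locus, config.cut_model,
                                      clean_depth * share,
                                      config.dispersion, rng)
        for seq, arm, o5, o3, prob in isomir_cells(locus, config.cut_model):
            count = counts.get(seq, 0)
            truth_rows.append(dict(locus=locus.locus_id, sequence=seq, arm=arm,
                                   offset5=o5, offset3=o3, count=count,
                                   expected_rpm=prob * share * 1e6))
        for seq, count in counts.items():
            reads[seq] = reads.get(seq, 0) + count

    n_contam = int(round(config.depth * config.contaminant_fraction)) \
        if emit_records else 0
    n_low = int(round(config.depth * config.low_complexity_fraction)) \
        if emit_records else 0
    contam_reads: list[str] = []
    low_reads: list[str] = []
    if n_contam and not contaminants:
        raise ValueError("contaminant_fraction > 0 but no contaminant set given")
    for _ in range(n_contam):
        ref = contaminants[rng.integers(0, len(contaminants))]
        length = int(rng.integers(18, 25))
        start = int(rng.integers(0, len(ref) - length + 1))
        contam_reads.append(ref[start:start + length])
    for _ in range(n_low):
        length = int(rng.integers(18, 25))
        if rng.random() < 0.5:
            low_reads.append(str(rng.choice(_BASES)) * length)
        else:
            pair = "".join(rng.choice(_BASES, size=2, replace=False))
            low_reads.append((pair * length)[:length])

    def raw_read(insert: str) -> str:
        raw = (insert + config.adapter3)[:config.read_length]
        return raw + "A" * (config.read_length - len(raw))

    records = []
    serial = 0
    if emit_records:
        for seq, count in sorted(reads.items()):
            for _ in range(count):
                records.append((f"{library_id}_{serial}", raw_read(seq),
                                "I" * config.read_length))
                serial += 1
        for insert in contam_reads + low_reads:
            records.append((f"{library_id}_{serial}", raw_read(insert),
                            "I" * config.read_length))
            serial += 1

    n_locus = sum(reads.values())
    raw_total = n_locus + n_contam + n_low
    nr_locus = len(reads)
    nr_after_low = nr_locus + len(set(contam_reads))
    truth = SmallRNALibrary(
        library_id=library_id, tissue=tissue, replicate=replicate,
        reads=dict(reads),
        stage_tallies={
            "raw": (raw_total, len(set(reads) | set(contam_reads) | set(low_reads))),
            "adapter": (raw_total, len(set(reads) | set(contam_reads)
                                       | set(low_reads))),
            "length": (raw_total, len(set(reads) | set(contam_reads)
                                      | set(low_reads))),
            "low_complexity": (raw_total - n_low, nr_after_low),
            "contaminant": (n_locus, nr_locus),
            "genome": (n_locus, nr_locus),
        },
        genome_matched_total=n_locus,
    )
    table = pd.DataFrame(truth_rows)
    return SimulatedLibrary(library_id=library_id, records=records,
                            truth=truth, truth_table=table)


def simulate_experiment(loci: Sequence[LocusModel], config: SimulationConfig,
                        contaminants: Sequence[str] = (),
                        emit_records: bool = True
                        ) -> dict[str, SimulatedLibrary]:
    """All tissues x replicates, keyed by library id."""
    out = {}
    for tissue in config.tissues:
        for rep in range(1, config.replicates_per_tissue + 1):
            sim = simulate_library(loci, config, tissue, rep, contaminants,
                                   emit_records=emit_records)
            out[sim.library_id] = sim
    return out


def truth_matrix(sims: Mapping[str, SimulatedLibrary]):
    """RPM matrix built directly from the simulated ground truth.

    Bypasses read filtering and mapping: counts come straight from each
    library's truth table, normalized by its genome-matched total.  Useful
    for count-level studies of the noise model itself.
    """
    from .io import ExpressionMatrix  # local import to avoid a cycle

    frames = []
    for lib_id, sim in sims.items():
        tt = sim.truth_table
        rpm = tt["count"] / sim.truth.genome_matched_total * 1e6
        frames.append(pd.DataFrame({"locus": tt["locus"],
                                    "sequence": tt["sequence"],
                                    lib_id: rpm}))
    merged = frames[0][["locus", "sequence"]]
    for frame in frames:
        lib = frame.columns[-1]
        merged = merged.merge(
            frame.groupby(["locus", "sequence"], as_index=False)[lib].sum(),
            on=["locus", "sequence"], how="left")
    return ExpressionMatrix(merged.fillna(0.0))
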