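"""End-to-end orchestration: simulate -> filter -> catalog -> stats.

Every output TSV carries a provenance header (package version, seed,
config hash) so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .catalog import build_catalog, dominance_table, five_prime_composition, \
    sample_invariant_dominants
from .datasets import load_table1_fixture, load_table2_fixture
from .filtering import FilterConfig, GenomeIndex, run_cascade
from .io import ExpressionMatrix, FilterStatsRow
from .simulate import SimulationConfig, make_contaminants, make_loci, \
    simulate_experiment
from .stats import DEFAULT_EXCLUSIONS, arm_ratio, cluster_samples, concordance, \
    pairwise_ttests


@dataclass
class RunConfig:
    """One pipeline run: either simulate inputs or consume the fixture."""

    mode: str = "simulate"                    # 'simulate' | 'fixture'
    out_dir: str = "isomirkit_out"
    seed: int = 0
    genome_length: int = 60_000
    n_loci: int = 12
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    exclusions: Sequence[str] = DEFAULT_EXCLUSIONS
    alpha: float = 0.05
    cluster_mode: str = "all_reads"

    def config_hash(self) -> str:
        # the output location is not part of the scientific configuration
        payload = {k: v for k, v in _as_jsonable(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _provenance(config: RunConfig) -> list[str]:
    return [f"isomirkit {__version__}",
            f"seed={config.seed}",
            f"config_hash={config.config_hash()}"]


def _write_tsv(path: Path, df: pd.DataFrame, header: list[str],
               index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.9g")


@dataclass
class AnalysisReports:
    matrix: ExpressionMatrix
    concordance: "object"
    differential: "object"
    dendrogram: "object"
    dominance: "object"
    stats_rows: list[FilterStatsRow] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> AnalysisReports:
    """Run the configured pipeline and write reports under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)

    if config.mode == "fixture":
        matrix = load_table2_fixture()
        stats_rows = load_table1_fixture()
    elif config.mode == "simulate":
        sim = config.simulation
        genome, loci = make_loci(config.genome_length, config.n_loci,
                                 config.seed, adapter3=sim.adapter3)
        contaminants = make_contaminants(config.seed + 1,
                                         adapter3=sim.adapter3)
        fconfig = dataclasses.replace(config.filter, adapter3=sim.adapter3,
                                      contaminant_set=tuple(contaminants))
        index = GenomeIndex(genome)
        libraries, assignments, stats_rows = [], {}, []
        for lib_id, simlib in simulate_experiment(loci, sim, contaminants).items():
            result = run_cascade(simlib.records, index, loci, fconfig,
                                 library_id=lib_id)
            libraries.append(result.library)
            assignments[lib_id] = result.locus_assignments
            stats_rows.append(result.stats)
        matrix, _ = build_catalog(libraries, loci, assignments)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    conc = concordance(matrix, config.exclusions)
    diff = pairwise_ttests(matrix, alpha=config.alpha)
    dend = cluster_samples(matrix, mode=config.cluster_mode)
    dom = dominance_table(matrix)

    matrix.to_tsv(out / "catalog.tsv", header_lines=header)
    _write_tsv(out / "filter_stats.tsv",
               pd.DataFrame([dataclasses.asdict(r) for r in stats_rows]), header)
    _write_tsv(out / "concordance.tsv",
               pd.DataFrame([conc.rounded()]), header)
    _write_tsv(out / "ttests.tsv", diff.pvalues, header, index=True)
    _write_tsv(out / "five_prime.tsv", five_prime_composition(matrix), header)
    with open(out / "clusters.nwk", "w") as fh:
        fh.write(dend.to_newick() + "\n")
    return AnalysisReports(matrix=matrix, concordance=conc, differential=diff,
                           dendrogram=dend, dominance=dom, stats_rows=stats_rows)


def summarize_table1(rows: Sequence[FilterStatsRow]
                     ) -> tuple[int, int, int]:
    """(total raw, mean raw, mean genome-matched) over the 15 libraries."""
    if len(rows) != 15:
        raise ValueError(f"expected 15 rows, got {len(rows)}")
    total = sum(r.raw for r in rows)
    mean_raw = round(total / len(rows))
    mean_gm = round(sum(r.genome_matched_redundant for r in rows) / len(rows))
    return total, int(mean_raw), int(mean_gm)


# locus 3_16 dominant mature/star accessions used for the arm-ratio check
_LOCUS_316 = ("3_16", "HE860348", "HE860347")
# most abundant isomiR of locus 4_21 (a conserved miR398-family read)
_ACC_4_21 = "HE860366"


def reproduce_reference() -> pd.DataFrame:
    """Recompute the fixture-derived summary statistics and check them.

    Returns a table of (quantity, computed, expected, passed) rows covering
    the per-library accounting totals, replicate concordance, dominance,
    differential and arm-ratio results of the packaged dataset.
    """
    rows = load_table1_fixture()
    matrix = load_table2_fixture()
    total, mean_raw, mean_gm = summarize_table1(rows)
    conc = concordance(matrix)
    rounded = conc.rounded()
    diff = pairwise_ttests(matrix)
    dom = dominance_table(matrix)
    ratio = arm_ratio(matrix, *_LOCUS_316)
    gfgl = ratio.group_mean([l for l in matrix.libraries
                             if l.startswith(("GF", "GL"))])
    n366 = int(diff.n_significant[matrix.resolve(_ACC_4_21)])
    o_dominants = {dom.per_library[("3_16", lib)][0][0] for lib in ("O1", "O2", "O3")}
    star_seq = matrix.resolve("HE860347")
    n_invariant = len(sample_invariant_dominants(dom))

    checks = [
        ("total_raw_reads", total, 40_764_330),
        ("mean_raw_reads", mean_raw, 2_717_622),
        ("mean_genome_matched_reads", mean_gm, 664_777),
        ("pearson_within_BF", rounded["BF"], 0.98),
        ("pearson_within_F", rounded["F"], 0.95),
        ("pearson_within_GF", rounded["GF"], 0.98),
        ("pearson_within_GL", rounded["GL"], 0.95),
        ("pearson_within_O", rounded["O"], 0.97),
        ("pearson_cross_tissue", rounded["cross_tissue"], 0.66),
        ("arm_ratio_3_16_O", round(ratio.tissue_mean["O"], 1), 0.4),
        ("arm_ratio_3_16_GF_GL", round(gfgl, 1), 5.7),
        ("significant_comparisons_4_21", n366, 8),
        ("dominant_3_16_O_is_star", o_dominants == {star_seq}, True),
        ("n_sample_invariant_dominant_reads", n_invariant, 16),
    ]
    return pd.DataFrame(
        [dict(quantity=q, computed=c, expected=e, passed=(c == e))
         for q, c, e in checks])
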