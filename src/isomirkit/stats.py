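"""Replicate concordance, differential tests, clustering and arm ratios.

Conventions frozen for reproducibility: correlations are computed on the
de-duplicated sequence view of untransformed RPM with abnormal sequences
excluded first, and reported to 2 decimals; pairwise differential tests
are two-sided pooled-variance Student t-tests with no multiplicity
correction; sample clustering is agglomerative with the Canberra metric
and complete linkage; arm ratios are means of per-replicate ratios,
reported to 1 decimal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import canberra as _canberra, pdist

from .catalog import dominance_table, sample_invariant_dominants
from .io import ExpressionMatrix, tissue_of

ENCODE_BAND = (0.92, 0.98)
DEFAULT_EXCLUSIONS = ("HE860285",)


def pearson(u: Sequence[float], v: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if u.std() == 0 or v.std() == 0:
        return float("nan")
    if np.array_equal(u, v):  # identical replicates correlate exactly
        return 1.0
    return float(np.corrcoef(u, v)[0, 1])


@dataclass
class ConcordanceReport:
    pairwise: pd.DataFrame                  # 15 x 15 symmetric r matrix
    within_tissue: dict[str, float]         # tissue -> mean of its 3 pairs
    cross_tissue: float                     # mean over between-tissue pairs
    excluded_sequences: list[str]
    encode_band: tuple[float, float] = ENCODE_BAND
    in_band: dict[str, bool] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {t: round(v, ndigits) for t, v in self.within_tissue.items()}
        out["cross_tissue"] = round(self.cross_tissue, ndigits)
        return out


def concordance(matrix: ExpressionMatrix,
                exclusions: Iterable[str] = DEFAULT_EXCLUSIONS
                ) -> ConcordanceReport:
    """Pearson concordance across all library pairs on the de-duplicated view.

    ``exclusions`` (accessions or sequences — e.g. a read whose abundance
    is so high it forces every correlation toward one) are dropped before
    any correlation is computed.  Within-tissue averages use each tissue's
    three replicate pairs; the cross-tissue average pools every
    between-tissue pair.
    """
    dedup = matrix.dedup()
    excluded = []
    for key in exclusions:
        try:
            seq = matrix.resolve(key)
            excluded.append(seq)
        except KeyError:
            warnings.warn(f"exclusion {key!r} not found in matrix", stacklevel=2)
    dedup = dedup.drop(index=[s for s in excluded if s in dedup.index])

    libs = list(dedup.columns)
    corr = dedup.corr(method="pearson")
    tissues = list(dict.fromkeys(tissue_of(l) for l in libs))
    within, cross = {}, []
    for t in tissues:
        pairs = list(itertools.combinations(
            [l for l in libs if tissue_of(l) == t], 2))
        within[t] = float(np.mean([corr.loc[a, b] for a, b in pairs]))
    for a, b in itertools.combinations(libs, 2):
        if tissue_of(a) != tissue_of(b):
            cross.append(corr.loc[a, b])
    lo, hi = ENCODE_BAND
    in_band = {t: lo <= round(v, 2) <= hi for t, v in within.items()}
    return ConcordanceReport(pairwise=corr, within_tissue=within,
                             cross_tissue=float(np.mean(cross))
                             if cross else float("nan"),
                             excluded_sequences=excluded, in_band=in_band)


# ---------------------------------------------------------------------------
# differential analysis


@dataclass
class DifferentialReport:
    """Per-isomiR pairwise tissue comparisons.

    ``pvalues``: DataFrame indexed by sequence with one column per tissue
    pair ('BF_vs_F', ...); ``significant``: same shape, boolean;
    ``n_significant``: per-sequence count of significant comparisons.
    """

    pvalues: pd.DataFrame
    significant: pd.DataFrame
    n_significant: pd.Series
    alpha: float
    degenerate: set[tuple[str, str]] = field(default_factory=set)


def student_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance two-sample t-test p-value.

    Degenerate inputs: equal constants -> 1.0, different constants -> 0.0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def pairwise_ttests(matrix: ExpressionMatrix, alpha: float = 0.05
                    ) -> DifferentialReport:
    """All tissue-pair Student t-tests for every de-duplicated isomiR."""
    dedup = matrix.dedup()
    tissues = list(dict.fromkeys(tissue_of(l) for l in dedup.columns))
    groups = {t: [l for l in dedup.columns if tissue_of(l) == t]
              for t in tissues}
    pairs = list(itertools.combinations(tissues, 2))
    cols = [f"{a}_vs_{b}" for a, b in pairs]
    pvals = pd.DataFrame(index=dedup.index, columns=cols, dtype=float)
    degenerate = set()
    for seq, row in dedup.iterrows():
        for (a, b), col in zip(pairs, cols):
            va, vb = row[groups[a]].values, row[groups[b]].values
            p = student_t_pvalue(va, vb)
            if (np.std(va, ddof=1) == 0 and np.std(vb, ddof=1) == 0
                    and va.mean() != vb.mean()):
                degenerate.add((seq, col))
            pvals.loc[seq, col] = p
    sig = pvals < alpha
    return DifferentialReport(pvalues=pvals, significant=sig,
                              n_significant=sig.sum(axis=1), alpha=alpha,
                              degenerate=degenerate)


# ---------------------------------------------------------------------------
# clustering


def canberra(u: Sequence[float], v: Sequence[float]) -> float:
    """Canberra distance; coordinates where both entries are 0 contribute 0."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return float(_canberra(u, v))


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node."""
        tree = to_tree(self.linkage_matrix)
        out: list[frozenset[str]] = []

        def walk(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.labels[node.id]])
            members = walk(node.left) | walk(node.right)
            out.append(members)
            return members

        walk(tree)
        return out

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(render(c, node.dist)
                             for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def cluster_samples(matrix: ExpressionMatrix, mode: str = "all_reads",
                    average_replicates: bool = True) -> Dendrogram:
    """Hierarchical clustering of samples (Canberra metric, complete linkage).

    ``all_reads`` uses the de-duplicated sequence view (multi-locus reads
    counted once); ``dominant_only`` restricts to the sample-invariant
    dominant reads.  With ``average_replicates`` columns are per-tissue
    replicate means; otherwise each replicate library is a leaf.
    """
    if mode not in ("all_reads", "dominant_only"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    dedup = matrix.dedup()
    if mode == "dominant_only":
        keep = sample_invariant_dominants(dominance_table(matrix))
        dedup = dedup.loc[sorted(keep & set(dedup.index))]
    if average_replicates:
        tissues = list(dict.fromkeys(tissue_of(l) for l in dedup.columns))
        data = pd.DataFrame(
            {t: dedup[[l for l in dedup.columns if tissue_of(l) == t]].mean(axis=1)
             for t in tissues})
    else:
        data = dedup
    if data.shape[1] < 2:
        raise ValueError("need at least 2 columns to cluster")
    dists = pdist(data.T.values, metric="canberra")
    return Dendrogram(linkage_matrix=linkage(dists, method="complete"),
                      labels=list(data.columns))


# ---------------------------------------------------------------------------
# arm ratios


#: ratio classes for miRNA/miRNA* abundance: strong mature-strand
#: preference down to inverted (star-dominated) processing
RATIO_BINS = (("high", 100.0, float("inf")),
              ("intermediate", 10.0, 100.0),
              ("low", 1.0, 10.0),
              ("inverted", 0.0, 1.0))


def classify_ratio(ratio: float) -> str:
    for name, lo, hi in RATIO_BINS:
        if lo <= ratio < hi or (name == "high" and ratio >= lo):
            return name
    raise ValueError(f"ratio {ratio} not classifiable")


@dataclass
class ArmRatioRow:
    locus: str
    mature_key: str
    star_key: str
    per_replicate: dict[str, Optional[float]]   # library -> ratio (None if 0/0)
    tissue_mean: dict[str, Optional[float]]
    tissue_class: dict[str, Optional[str]]

    def group_mean(self, libraries: Iterable[str]) -> Optional[float]:
        """Mean ratio over an arbitrary replicate set (e.g. pooled tissues)."""
        vals = [self.per_replicate[l] for l in libraries
                if self.per_replicate.get(l) is not None]
        return float(np.mean(vals)) if vals else None


def arm_ratio(matrix: ExpressionMatrix, locus: str,
              mature_key: str, star_key: str) -> ArmRatioRow:
    """miRNA/miRNA* abundance ratio for one locus.

    ``mature_key``/``star_key`` are accessions or sequences of the
    dominant mature- and star-arm reads.  Per-replicate ratios divide the
    mature RPM by the star RPM; replicates with zero star RPM are excluded
    (None).  Tissue means are arithmetic means of the per-replicate
    ratios, classified into the high/intermediate/low/inverted bins.
    """
    sub = matrix.per_locus(locus)
    mature_seq = matrix.resolve(mature_key)
    star_seq = matrix.resolve(star_key)
    for seq, key in ((mature_seq, mature_key), (star_seq, star_key)):
        if seq not in sub.index:
            raise KeyError(f"{key!r} not present at locus {locus}")
    per_rep: dict[str, Optional[float]] = {}
    for lib in matrix.libraries:
        m, s = float(sub.loc[mature_seq, lib]), float(sub.loc[star_seq, lib])
        per_rep[lib] = (m / s) if s > 0 else None
    tissues = list(dict.fromkeys(tissue_of(l) for l in matrix.libraries))
    t_mean: dict[str, Optional[float]] = {}
    t_class: dict[str, Optional[str]] = {}
    for t in tissues:
        vals = [per_rep[l] for l in matrix.libraries
                if tissue_of(l) == t and per_rep[l] is not None]
        if vals:
            mean = float(np.mean(vals))
            t_mean[t], t_class[t] = mean, classify_ratio(mean)
        else:
            t_mean[t] = t_class[t] = None
    return ArmRatioRow(locus=locus, mature_key=mature_key, star_key=star_key,
                       per_replicate=per_rep, tissue_mean=t_mean,
                       tissue_class=t_class)
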