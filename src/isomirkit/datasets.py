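"""Packaged reference datasets.

Two fixtures ship with the package, transcribed from the published peach
small-RNA survey they summarize:

* ``table1.tsv`` — per-library read counts along the filtering cascade for
  the 15 libraries (5 tissues x 3 replicates).
* ``table2.tsv`` — normalized counts (reads per million genome-matched
  reads) for the isomiRs of 26 precursor loci across the 15 libraries,
  keyed by EMBL accession and read sequence.

A SHA-256 manifest guards against silent corruption of the packaged files.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .io import ConsistencyError, ExpressionMatrix, FilterStatsRow

_DATA = resources.files(__package__) / "data"


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


def _read_checked(name: str) -> bytes:
    payload = (_DATA / name).read_bytes()
    manifest = json.loads((_DATA / "manifest.json").read_text())
    digest = hashlib.sha256(payload).hexdigest()
    if digest != manifest[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != manifest {manifest[name]}")
    return payload


def load_table1_fixture() -> list[FilterStatsRow]:
    """The 15 per-library filtering-cascade tallies."""
    import io as _io

    df = pd.read_csv(_io.BytesIO(_read_checked("table1.tsv")), sep="\t")
    rows = [FilterStatsRow(**rec) for rec in df.to_dict("records")]
    if len(rows) != 15:
        raise ConsistencyError(f"table1 fixture has {len(rows)} rows, expected 15")
    return rows


def load_table2_fixture() -> ExpressionMatrix:
    """The isomiR x library RPM matrix (26 loci, 15 libraries).

    Reads listed under several loci keep one row per (locus, sequence) pair;
    the de-duplicated sequence view collapses them to a single row.
    """
    import io as _io

    df = pd.read_csv(_io.BytesIO(_read_checked("table2.tsv")), sep="\t")
    matrix = ExpressionMatrix(df)
    if len(matrix.libraries) != 15:
        raise ConsistencyError(
            f"table2 fixture has {len(matrix.libraries)} library columns, expected 15")
    return matrix
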