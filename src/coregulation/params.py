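"""Per-gene translational-parameter tables.

A gene's translation is summarised by a small set of per-gene quantities:

====== =======================================================================
symbol meaning
====== =======================================================================
L      coding-sequence length in codons
x      average number of transcripts per cell
g      ribosome density, ribosomes per 100 codons of a transcript
w      absolute number of ribosomes attached to a single transcript
m      transcript mean lifetime (seconds)
I      mean translation initiation time (seconds)
E      mean translation elongation time of a transcript (seconds)
e      mean elongation time of one codon (seconds)
b      proteins produced from one transcript during its lifetime
B      total proteins produced from all transcripts of a gene (derived, b*x)
A      protein molecules per cell, from independent abundance studies
R      proteins produced per second by a gene's transcripts (derived)
====== =======================================================================

Under a transcriptional steady state (matured mRNAs appear in the cytoplasm
at the same rate as they are degraded), the production rate of gene *i* is
``R_i = x_i * b_i / m_i``.  Because ``b`` and ``m`` are available only for a
fraction of genes while ``b = m / I``, the rate is computed here as
``R_i = x_i / I_i``, which is algebraically identical but needs only the
widely available ``x`` and ``I``.

Absent values are first-class: a missing cell stays missing (NaN internally,
empty on disk), is never imputed, and every downstream analysis restricts
itself to genes where the needed symbol is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of a parameter table on disk.
SYMBOLS: tuple[str, ...] = ("L", "x", "g", "w", "m", "I", "E", "e", "b", "B", "A", "R")

#: Symbols that must be strictly positive where present.
_STRICTLY_POSITIVE = frozenset({"m", "I"})


class ParamsTable:
    """Immutable-by-convention table of per-gene translational parameters.

    Parameters
    ----------
    frame
        DataFrame indexed by gene identifier with a subset of :data:`SYMBOLS`
        as float columns; NaN marks an absent value.
    validate
        Check identifier uniqueness, non-negativity and the positivity of
        ``m`` and ``I``. Disable only for internal round-trips.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame.index.name = "gene_id"
        for sym in SYMBOLS:
            if sym not in frame.columns:
                frame[sym] = np.nan
        frame = frame[list(SYMBOLS)].astype(float)
        if validate:
            _validate_frame(frame)
        self._frame = frame

    # -- basic container behaviour -----------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (do not mutate)."""
        return self._frame

    @property
    def genes(self) -> pd.Index:
        return self._frame.index

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._frame.index

    def copy(self) -> "ParamsTable":
        return ParamsTable(self._frame, validate=False)

    def values_for(self, symbol: str, genes: Iterable[str]) -> np.ndarray:
        """Values of ``symbol`` for ``genes`` in order (NaN where absent)."""
        _check_symbol(symbol)
        return self._frame[symbol].reindex(list(genes)).to_numpy()

    def genes_with(self, symbol: str) -> frozenset[str]:
        """Identifiers whose value of ``symbol`` is present."""
        _check_symbol(symbol)
        col = self._frame[symbol]
        return frozenset(col.index[col.notna()])

    # -- derivations --------------------------------------------------------
    def with_production_rate(self) -> "ParamsTable":
        """Return a new table with ``R = x / I`` filled in.

        Genes missing ``x`` or ``I`` keep ``R`` absent. A present ``I`` of
        exactly zero is a hard error: the rate is undefined.
        """
        return derive_production_rate(self)

    def with_total_production(self) -> "ParamsTable":
        """Return a new table with ``B = b * x`` filled in."""
        return derive_total_production(self)

    def with_abundance(self, abundance) -> "ParamsTable":
        """Return a new table with ``A`` merged from an external source."""
        return merge_abundance(self, abundance)


def _check_symbol(symbol: str) -> None:
    if symbol not in SYMBOLS:
        raise KeyError(
            f"unknown translational parameter {symbol!r}; expected one of {SYMBOLS}"
        )


def _validate_frame(frame: pd.DataFrame) -> None:
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id {dup[0]!r} in parameter table")
    for sym in SYMBOLS:
        col = frame[sym]
        neg = col < 0
        if neg.any():
            gene = col.index[neg][0]
            raise ValueError(f"negative value of {sym} for gene {gene!r}")
    for sym in _STRICTLY_POSITIVE:
        zero = frame[sym] == 0
        if zero.any():
            gene = frame.index[zero][0]
            raise ValueError(f"{sym} must be strictly positive; zero for gene {gene!r}")
    bad_L = frame["L"].notna() & (frame["L"] < 1)
    if bad_L.any():
        gene = frame.index[bad_L][0]
        raise ValueError(f"L must be >= 1; violated for gene {gene!r}")


def read_params_table(
    path: str | Path,
    id_column: str = "gene_id",
    column_map: Mapping[str, str] | None = None,
) -> ParamsTable:
    """Read a tab- or comma-separated parameter table.

    Parameters
    ----------
    path
        File with a header row and one gene per row. The delimiter is
        sniffed, so both TSV and CSV work.
    id_column
        Name of the identifier column.
    column_map
        Optional ``symbol -> column name`` mapping resolving nonstandard
        headers to the canonical symbols.

    Raises
    ------
    ValueError
        On a duplicated identifier (named), a negative parameter value
        (with its row number), or an unknown symbol in ``column_map``.
    """
    path = Path(path)
    # cells come in as strings and are converted with to_numeric, which
    # round-trips shortest-repr floats exactly (the default parser does not)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if id_column not in raw.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    if column_map:
        for sym in column_map:
            _check_symbol(sym)
        rename = {col: sym for sym, col in column_map.items()}
        missing = [col for col in rename if col not in raw.columns]
        if missing:
            raise ValueError(f"mapped column(s) {missing} not found in {path}")
        raw = raw.rename(columns=rename)

    ids = raw[id_column].astype(str)
    dup_mask = ids.duplicated()
    if dup_mask.any():
        raise ValueError(f"duplicate gene_id {ids[dup_mask].iloc[0]!r} in {path}")

    def _cell(value) -> float:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        text = str(value).strip()
        if not text:
            return np.nan
        try:
            return float(text)  # exact round-trip of shortest-repr floats
        except ValueError:
            return np.nan

    data = {}
    for sym in SYMBOLS:
        if sym not in raw.columns:
            continue
        col = raw[sym].map(_cell)
        neg = col < 0
        if neg.any():
            # +2: one for the header line, one for 0-based indexing
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise ValueError(f"negative value in column {sym!r} at row {row} of {path}")
        data[sym] = col.to_numpy()

    frame = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
    table = ParamsTable(frame)
    present = {s: int(frame[s].notna().sum()) for s in data}
    logger.info("read %d genes from %s; present counts %s", len(table), path, present)
    return table


def write_params_table(table: ParamsTable, path: str | Path) -> None:
    """Write a table as TSV in canonical column order; absent cells empty."""
    out = table.frame.copy()
    out.to_csv(Path(path), sep="\t", na_rep="")


def merge_abundance(table: ParamsTable, abundance) -> ParamsTable:
    """Merge protein abundance ``A`` (molecules per cell) into a table.

    ``abundance`` is a path to a two-column file (gene, A) or a DataFrame
    with those two columns. Matching is exact, case-sensitive; abundance
    entries without a matching gene are logged and dropped, never an error,
    because abundance surveys cover only part of any genome.
    """
    if isinstance(abundance, (str, Path)):
        ab = pd.read_csv(abundance, sep=None, engine="python", dtype={0: str})
    else:
        ab = abundance.copy()
    if ab.shape[1] < 2:
        raise ValueError("abundance input needs two columns: gene, A")
    ab = ab.iloc[:, :2]
    ab.columns = ["gene_id", "A"]
    ab["gene_id"] = ab["gene_id"].astype(str)
    if ab["gene_id"].duplicated().any():
        dup = ab["gene_id"][ab["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in abundance table")
    values = pd.to_numeric(ab["A"], errors="coerce")
    if (values < 0).any():
        raise ValueError("negative abundance value")

    frame = table.frame.copy()
    matched = ab["gene_id"].isin(frame.index)
    if (~matched).any():
        logger.info(
            "abundance: %d of %d ids not in parameter table (ignored)",
            int((~matched).sum()),
            len(ab),
        )
    sub = ab[matched]
    frame.loc[sub["gene_id"].to_numpy(), "A"] = values[matched].to_numpy()
    return ParamsTable(frame, validate=False)


def derive_production_rate(table: ParamsTable) -> ParamsTable:
    """Fill in the protein production rate ``R = x / I`` (per second).

    Idempotent; the input table is not mutated. Genes lacking ``x`` or ``I``
    keep ``R`` absent.
    """
    frame = table.frame.copy()
    x, I = frame["x"], frame["I"]
    zero_I = I == 0
    if zero_I.any():
        gene = frame.index[zero_I][0]
        raise ValueError(f"I = 0 for gene {gene!r}: production rate undefined")
    both = x.notna() & I.notna()
    R = pd.Series(np.nan, index=frame.index)
    R[both] = x[both] / I[both]
    frame["R"] = R
    return ParamsTable(frame, validate=False)


def derive_total_production(table: ParamsTable) -> ParamsTable:
    """Fill in ``B = b * x``, the total proteins produced from a gene.

    ``B`` ignores protein degradation, so it is a cumulative production
    count, not an abundance estimate.
    """
    frame = table.frame.copy()
    b, x = frame["b"], frame["x"]
    both = b.notna() & x.notna()
    B = pd.Series(np.nan, index=frame.index)
    B[both] = b[both] * x[both]
    frame["B"] = B
    return ParamsTable(frame, validate=False)


@dataclass(frozen=True)
class ConsistencyReport:
    """Advisory comparison of the two equivalent production-rate formulas.

    For genes carrying all of ``x, b, m, I``, compares ``x*b/m`` (steady
    state) against ``x/I`` (the ``b = m/I`` substitution). The two agree
    identically when ``b`` was itself derived as ``m/I``; deviations point
    at internally inconsistent source tables.
    """

    frame: pd.DataFrame  # columns: r_steady_state, r_initiation, rel_deviation, flagged
    rel_tol: float

    @property
    def flagged(self) -> list[str]:
        return list(self.frame.index[self.frame["flagged"]])

    def __len__(self) -> int:
        return len(self.frame)


def check_rate_consistency(table: ParamsTable, rel_tol: float = 1e-9) -> ConsistencyReport:
    """Report relative deviation between the two production-rate formulas.

    Report-only: the table is never modified. Genes missing any of
    ``x, b, m, I`` are excluded (the report is empty if none qualify).
    """
    frame = table.frame
    have = frame[["x", "b", "m", "I"]].notna().all(axis=1)
    sub = frame[have]
    r1 = sub["x"] * sub["b"] / sub["m"]
    r2 = sub["x"] / sub["I"]
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(r1 - r2) / np.abs(r2)
    report = pd.DataFrame(
        {
            "r_steady_state": r1,
            "r_initiation": r2,
            "rel_deviation": dev,
            "flagged": dev > rel_tol,
        }
    )
    return ConsistencyReport(frame=report, rel_tol=rel_tol)
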