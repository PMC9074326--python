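"""Reading and writing the tool's plain-text table formats.

Expression matrices are TSV with genes as rows (first column = gene id,
header row = sample ids).  Networks — gold standards and predictions alike —
are DREAM-style 3-column TSV: ``regulator TAB target TAB value`` with 0/1
values for gold standards and real scores for predictions.  Lines starting
with ``#`` are comments.  Parsers reject malformed input with the offending
location rather than coercing it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import WeightedNetwork
from .simulate import GoldStandardNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "gold_from_edges",
    "scores_from_edges",
    "write_network",
    "write_gold_standard",
]


def read_expression(path) -> pd.DataFrame:
    """Parse a genes x samples TSV expression matrix.

    Raises
    ------
    ValueError
        On duplicate gene identifiers (named) or non-numeric cells
        (named with row/column coordinates).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.isnull().any() or df.isnull().any().any():
        raise ValueError(f"{path}: ragged or empty cells in expression table")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene identifier(s) {dup}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[i]!r}, sample {col!r} (row {i + 2})"
                ) from None
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (round-trips through
    :func:`read_expression` to full float precision)."""
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_edge_list(path) -> pd.DataFrame:
    """Parse a 3-column edge TSV into (regulator, target, value) rows.

    Duplicate ordered pairs are an error (named); self-edges are dropped
    with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            reg, tgt, raw = parts
            try:
                val = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric edge value {raw!r}"
                ) from None
            rows.append((reg, tgt, val, lineno))

    seen = {}
    keep = []
    for reg, tgt, val, lineno in rows:
        if reg == tgt:
            warnings.warn(f"{path}:{lineno}: self-edge {reg}->{tgt} dropped", stacklevel=2)
            continue
        if (reg, tgt) in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate pair ({reg}, {tgt}) "
                f"first seen on line {seen[(reg, tgt)]}"
            )
        seen[(reg, tgt)] = lineno
        keep.append((reg, tgt, val))
    return pd.DataFrame(keep, columns=["regulator", "target", "value"])


def gold_from_edges(df: pd.DataFrame, genes=None) -> GoldStandardNetwork:
    """Build a gold standard from parsed edges (value 1 = true edge).

    `genes` extends the gene universe beyond those named in the file.
    """
    bad = df.loc[~df["value"].isin([0.0, 1.0])]
    if not bad.empty:
        raise ValueError(
            f"gold-standard values must be 0/1; offending pairs: "
            f"{list(zip(bad['regulator'], bad['target']))[:10]}"
        )
    pos = df.loc[df["value"] == 1.0]
    edges = frozenset(zip(pos["regulator"], pos["target"]))
    all_genes = set(df["regulator"]) | set(df["target"]) | set(genes or [])
    return GoldStandardNetwork(
        genes=tuple(sorted(all_genes)),
        regulators=frozenset(df["regulator"]) | {r for r, _ in edges},
        edges=edges,
        weights={e: 1.0 for e in edges},
    )


def scores_from_edges(df: pd.DataFrame) -> dict:
    """Parsed edges as a ``{(regulator, target): score}`` mapping."""
    return {
        (r, t): float(v)
        for r, t, v in zip(df["regulator"], df["target"], df["value"])
    }


def write_network(
    net: WeightedNetwork,
    path,
    extended: bool = False,
    min_strength: float | None = None,
) -> None:
    """Write a ranked edge list (strength desc, then lexicographic).

    `extended` adds the raw regression coefficient and MI columns;
    `min_strength` is an optional post-hoc output filter (edges with
    strength strictly below it are dropped).
    """
    with open(path, "w") as fh:
        for e in net.edges:  # WeightedNetwork keeps the canonical order
            if min_strength is not None and e.strength < min_strength:
                continue
            row = [e.regulator, e.target, f"{e.strength:.6f}"]
            if extended:
                row += [f"{e.beta:.6g}", f"{e.mi:.6g}"]
            fh.write("\t".join(row) + "\n")


def write_gold_standard(net: GoldStandardNetwork, path) -> None:
    """Write a gold standard as DREAM-style 3-column TSV (value 1)."""
    with open(path, "w") as fh:
        for reg, tgt in sorted(net.edges):
            fh.write(f"{reg}\t{tgt}\t1\n")
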