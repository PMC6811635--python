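"""Readers and writers: CSV tables, Newick dendrograms, JSON reports.

CSV dialect is comma-separated UTF-8 with ``.`` as decimal separator; the
first row/column carry labels. Validation is total — every malformed input
raises a typed error with the offending location, never a silent coercion.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import skbio

from . import __version__
from .datamodel import (
    AbundanceMatrix,
    Dendrogram,
    DendrogramNode,
    DissimilarityMatrix,
    SamplingUnit,
    SpeciesRecord,
    TrapSample,
)
from .errors import FormatError

_METADATA_COLUMNS = [
    "unit_id", "cave_code", "zone", "depth_m", "x", "y", "z",
    "n_traps", "passage_length_m",
]


def _read_csv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df


def read_abundance_csv(path: str | Path) -> AbundanceMatrix:
    """Read a species x unit count table.

    Expects a header row of unit ids and a first column of species ids.
    Cells must be non-negative numbers.
    """
    df = _read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for what, labels in (("species", list(df.index)), ("unit", list(df.columns))):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        if dup:
            raise FormatError(f"{path}: duplicated {what} id(s): {dup}")
    for col in df.columns:
        for row, cell in df[col].items():
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell at species {row!r}, unit {col!r}: {cell!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"{path}: negative or non-finite cell at species {row!r}, unit {col!r}: {cell!r}"
                )
    # Raw count tables read as not-normalized; callers flip the flag after
    # effort correction.
    return AbundanceMatrix(df.astype(float), is_normalized=False)


def write_abundance_csv(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, index_label="species_id")


def read_metadata_csv(path: str | Path) -> list[SamplingUnit]:
    """Read the sampling-unit metadata table.

    Columns: unit_id, cave_code, zone, depth_m, x, y, z, n_traps,
    passage_length_m, and optionally stratum (derived from depth when absent;
    an explicit label wins, which is how slope caves are placed into deeper
    massif strata).
    """
    df = _read_csv(path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    units = []
    for i, row in df.iterrows():
        try:
            stratum = row.get("stratum")
            if stratum is None or (isinstance(stratum, float) and np.isnan(stratum)) or stratum == "":
                stratum = None
            units.append(
                SamplingUnit(
                    unit_id=str(row["unit_id"]),
                    cave_code=str(row["cave_code"]),
                    zone=str(row["zone"]),
                    depth_m=float(row["depth_m"]),
                    coord_xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
                    n_traps=int(row["n_traps"]),
                    passage_length_m=float(row["passage_length_m"]),
                    stratum=None if stratum is None else str(stratum),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i} ({row.get('unit_id')!r}): {exc}") from exc
    ids = [u.unit_id for u in units]
    dup = sorted({x for x in ids if ids.count(x) > 1})
    if dup:
        raise FormatError(f"{path}: duplicated unit id(s): {dup}")
    return units


def write_metadata_csv(units: Sequence[SamplingUnit], path: str | Path) -> None:
    rows = [
        {
            "unit_id": u.unit_id, "cave_code": u.cave_code, "zone": u.zone,
            "depth_m": u.depth_m, "x": u.coord_xyz[0], "y": u.coord_xyz[1],
            "z": u.coord_xyz[2], "n_traps": u.n_traps,
            "passage_length_m": u.passage_length_m, "stratum": u.stratum,
        }
        for u in units
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_csv(path: str | Path) -> list[SpeciesRecord]:
    """Read the species table (columns: species_id, name, eco_class)."""
    df = _read_csv(path)
    missing = [c for c in ("species_id", "name", "eco_class") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = [
        SpeciesRecord(str(r["species_id"]), str(r["name"]), str(r["eco_class"]))
        for _, r in df.iterrows()
    ]
    ids = [s.species_id for s in records]
    dup = sorted({x for x in ids if ids.count(x) > 1})
    if dup:
        raise FormatError(f"{path}: duplicated species id(s): {dup}")
    return records


def write_species_csv(species: Sequence[SpeciesRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"species_id": s.species_id, "name": s.name, "eco_class": s.eco_class} for s in species]
    ).to_csv(path, index=False)


def read_trap_csv(path: str | Path) -> list[TrapSample]:
    """Read long-format trap records (unit_id, season, species_id, count)."""
    df = _read_csv(path)
    missing = [c for c in ("unit_id", "season", "species_id", "count") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        TrapSample(str(r["unit_id"]), str(r["season"]), str(r["species_id"]), int(r["count"]))
        for _, r in df.iterrows()
    ]


def write_trap_csv(samples: Sequence[TrapSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"unit_id": s.unit_id, "season": s.season, "species_id": s.species_id, "count": s.count}
            for s in samples
        ]
    ).to_csv(path, index=False)


def write_dissimilarity_csv(d: DissimilarityMatrix, path: str | Path) -> None:
    d.to_dataframe().to_csv(path, index_label="unit_id")


def read_dissimilarity_csv(path: str | Path, metric_name: str = "") -> DissimilarityMatrix:
    df = _read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return DissimilarityMatrix(list(df.index), df.to_numpy(dtype=float), metric_name)


# --- Newick -----------------------------------------------------------------

def _newick_of(node: DendrogramNode, parent_height: float) -> str:
    length = parent_height - node.height
    if node.is_leaf:
        return f"{node.label}:{length:.10g}"
    inner = ",".join(_newick_of(child, node.height) for child in node.children)
    return f"({inner}):{length:.10g}"


def newick_string(tree: Dendrogram) -> str:
    """Serialize a dendrogram to Newick; branch length = parent height - child height."""
    inner = ",".join(_newick_of(child, tree.root.height) for child in tree.root.children)
    return f"({inner});"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n", encoding="utf-8")


def read_newick(path_or_str: str | Path) -> Dendrogram:
    """Parse a Newick ultrametric tree back into a :class:`Dendrogram`.

    Parsing is delegated to scikit-bio's TreeNode reader; heights are
    reconstructed from root-to-node path lengths (the root sits at the
    maximal leaf depth, leaves at height 0).
    """
    text = str(path_or_str)
    if not text.strip().endswith(";"):
        text = Path(path_or_str).read_text(encoding="utf-8")
    sk_tree = skbio.TreeNode.read(_io.StringIO(text))
    depths: dict[int, float] = {}

    def depth_of(node: Any, acc: float) -> None:
        depths[id(node)] = acc
        for child in node.children:
            depth_of(child, acc + (child.length or 0.0))

    depth_of(sk_tree, 0.0)
    max_depth = max(depths[id(tip)] for tip in sk_tree.tips()) if sk_tree.count(tips=True) else 0.0

    def convert(node: Any) -> DendrogramNode:
        height = max_depth - depths[id(node)]
        if node.is_tip():
            return DendrogramNode(height=0.0, label=str(node.name))
        return DendrogramNode(height=height, children=[convert(c) for c in node.children])

    return Dendrogram(convert(sk_tree))


# --- Structured report ------------------------------------------------------

def make_report(sections: dict[str, Any] | None = None, seed: int | None = None) -> dict[str, Any]:
    """A machine-readable result bundle with a provenance header.

    Every statistic entered downstream carries its own replicate count, seed
    and p-value convention; the header records the package version and the
    master seed of the run.
    """
    return {
        "provenance": {
            "package": "speleodiv",
            "version": __version__,
            "seed": seed,
            "p_value_convention": "add-one: p = (count + 1) / (n_perm + 1)",
        },
        "sections": sections or {},
    }


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


__all__ = [
    "read_abundance_csv", "write_abundance_csv", "read_metadata_csv",
    "write_metadata_csv", "read_species_csv", "write_species_csv",
    "read_trap_csv", "write_trap_csv", "read_dissimilarity_csv",
    "write_dissimilarity_csv", "newick_string", "write_newick", "read_newick",
    "make_report", "write_report", "read_report",
]
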