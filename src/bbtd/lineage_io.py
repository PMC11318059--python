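"""Input/output for lineage-tree expression data and network artifacts.

Reads per-embryo tables of quantified fluorescence (one labeled gene per
file, cells named in Sulston nomenclature, samples every 1.5 min),
assembles cell-lineage trees by name-prefix parent resolution, and
round-trips the integrated binary subtree dataset and inferred networks
to plain-text formats (TSV + JSON sidecar, edge-list TSV, GraphML).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

DATASET_SCHEMA_VERSION = 1

#: The five founder cells whose descendant subtrees are analyzed
#: independently.
SUBTREE_LABELS = ("AB", "C", "D", "E", "MS")

#: Lowercase letters that may extend a Sulston cell name (anterior,
#: posterior, left, right, dorsal, ventral).
_SULSTON_SUFFIX = frozenset("aplrdv")

#: Founder-cell aliases: names that are not plain prefix-extensions of
#: their parent.  Maps a cell name to the name used as its effective
#: lineage prefix.  Shipped as config so uncommon dialects can extend it.
DEFAULT_ALIASES: dict[str, str] = {
    "EMS": "P1",
    "E": "EMS",
    "MS": "EMS",
    "P1": "P0",
    "P2": "P1",
    "P3": "P2",
    "P4": "P3",
    "C": "P2",
    "D": "P3",
    "AB": "P0",
    "Z2": "P4",
    "Z3": "P4",
}


class LineageIOError(ValueError):
    """Raised for malformed or schema-incompatible input files."""


@dataclass
class RawEmbryoFile:
    """Quantified fluorescence of one labeled gene in one embryo.

    ``records`` holds (cell name, time index, intensity) rows; time
    indices are 1-based sample counts at the raw 1.5-min interval and are
    contiguous within each cell.
    """

    gene_name: str
    records: pd.DataFrame  # columns: cell, time, intensity

    def cells(self) -> dict[str, np.ndarray]:
        """Per-cell intensity series, in time order."""
        out: dict[str, np.ndarray] = {}
        for cell, grp in self.records.groupby("cell", sort=False):
            out[str(cell)] = grp.sort_values("time")["intensity"].to_numpy(float)
        return out

    def validate(self) -> None:
        dup = self.records.duplicated(subset=["cell", "time"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise LineageIOError(
                f"duplicate (cell, time) record: ({row['cell']}, {row['time']})"
            )
        if (self.records["intensity"] < 0).any():
            raise LineageIOError("negative fluorescence intensity")
        for cell, grp in self.records.groupby("cell", sort=False):
            t = np.sort(grp["time"].to_numpy())
            if len(t) > 1 and not np.all(np.diff(t) == 1):
                warnings.warn(
                    f"non-contiguous time indices in cell {cell}", stacklevel=2
                )


@dataclass
class CellRecord:
    name: str
    parent: str | None
    series: np.ndarray


@dataclass
class LineageTree:
    """A forest of cells within one founder-cell subtree.

    Parent links are resolved by longest-proper-prefix matching of
    Sulston names; each cell carries its ordered intensity series.
    """

    subtree_label: str
    cells: dict[str, CellRecord] = field(default_factory=dict)

    @property
    def roots(self) -> list[str]:
        return [c.name for c in self.cells.values() if c.parent is None]

    def children(self, name: str) -> list[str]:
        return sorted(c.name for c in self.cells.values() if c.parent == name)

    def validate(self) -> None:
        for cell in self.cells.values():
            if cell.parent is not None:
                if cell.parent not in self.cells:
                    raise LineageIOError(f"dangling parent link: {cell.name}")
                seen = {cell.name}
                cur = cell.parent
                while cur is not None:
                    if cur in seen:
                        raise LineageIOError(f"cycle through {cell.name}")
                    seen.add(cur)
                    cur = self.cells[cur].parent


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_embryo_file(
    path: str | Path,
    gene_name: str | None = None,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> RawEmbryoFile:
    """Read one per-embryo fluorescence table.

    The on-disk schema is configurable because embryo-table dialects
    vary: ``columns`` maps the logical names ``cell``, ``time`` and
    ``intensity`` to the file's column headers; the delimiter is sniffed
    when not given.  The gene name defaults to the second ``_``-separated
    token of the file stem (the convention of ``CD<date>_<gene>_<rep>``
    file names).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = delimiter or _sniff_delimiter(path)
    colmap = {"cell": "cell", "time": "time", "intensity": "intensity"}
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LineageIOError(f"cannot parse {path}: {exc}") from exc
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise LineageIOError(f"{path}: missing columns {missing}")
    df = df[[colmap["cell"], colmap["time"], colmap["intensity"]]].copy()
    df.columns = ["cell", "time", "intensity"]
    bad = df["time"].isna() | df["intensity"].isna() | df["cell"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise LineageIOError(f"{path}: malformed row at line {line}")
    df["cell"] = df["cell"].astype(str)
    df["time"] = df["time"].astype(int)
    df["intensity"] = df["intensity"].astype(float)
    if gene_name is None:
        parts = path.stem.split("_")
        gene_name = parts[1] if len(parts) >= 2 else path.stem
    raw = RawEmbryoFile(gene_name=gene_name, records=df)
    raw.validate()
    return raw


def in_subtree(name: str, subtree_label: str) -> bool:
    """Whether a Sulston cell name lies in the given founder subtree."""
    if not name.startswith(subtree_label):
        return False
    tail = name[len(subtree_label):]
    return all(ch in _SULSTON_SUFFIX for ch in tail)


def resolve_parent(
    name: str,
    present: Sequence[str],
    aliases: Mapping[str, str] | None = None,
) -> str | None:
    """Longest proper prefix of ``name`` among ``present`` cell names.

    Aliased names (founder cells whose parent is not a name prefix) are
    stepped through the alias table first.
    """
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    present_set = set(present) - {name}
    cur = name
    # follow aliases for the name itself (e.g. "E" -> "EMS" -> "P1")
    while True:
        for k in range(len(cur) - 1, 0, -1):
            if cur[:k] in present_set:
                return cur[:k]
        if cur in aliases:
            cur = aliases[cur]
            if cur in present_set:
                return cur
        else:
            return None


def build_tree(
    raw: RawEmbryoFile,
    subtree_label: str,
    aliases: Mapping[str, str] | None = None,
) -> LineageTree:
    """Assemble the lineage forest of one founder subtree from a raw file.

    Cells outside the labeled subtree are dropped.  Every non-root cell
    is linked to the unique longest-proper-prefix parent present in the
    file; a cell with no resolvable parent is kept as a root (with a
    warning unless it is the founder itself).
    """
    if subtree_label not in SUBTREE_LABELS:
        raise ValueError(f"unknown subtree label {subtree_label!r}")
    series = raw.cells()
    names = [n for n in series if in_subtree(n, subtree_label)]
    tree = LineageTree(subtree_label=subtree_label)
    for name in names:
        parent = resolve_parent(name, names, aliases)
        # founder or a direct founder daughter (e.g. "Ea") is a natural
        # subtree start; any other orphan gets flagged
        designated_root = len(name) <= len(subtree_label) + 1
        if parent is None and not designated_root:
            warnings.warn(
                f"cell {name} has no resolvable parent; treated as root",
                stacklevel=2,
            )
        tree.cells[name] = CellRecord(name=name, parent=parent, series=series[name])
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Dataset round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset, out_dir: str | Path) -> None:
    """Write a binary subtree dataset as TSV tables plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    states = np.asarray(dataset.states, dtype=float).copy()
    states[dataset.missing] = np.nan
    pd.DataFrame(states, index=dataset.gene_names).to_csv(
        out / "states.tsv", sep="\t", header=False, na_rep="NA"
    )
    pd.DataFrame(
        {
            "point": np.arange(dataset.n_points),
            "cell": dataset.cell_of_point,
            "prev": dataset.prev,
        }
    ).to_csv(out / "points.tsv", sep="\t", index=False)
    meta = {
        "schema_version": DATASET_SCHEMA_VERSION,
        "gene_names": list(dataset.gene_names),
        "subtree_label": dataset.subtree_label,
        "delta_t": dataset.delta_t,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(in_dir: str | Path):
    """Read back a dataset written by :func:`write_dataset`."""
    from bbtd.integration import SubtreeDataset

    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    if meta.get("schema_version") != DATASET_SCHEMA_VERSION:
        raise LineageIOError(
            f"dataset schema version {meta.get('schema_version')!r}; "
            f"this reader supports version {DATASET_SCHEMA_VERSION}"
        )
    raw = pd.read_csv(
        src / "states.tsv", sep="\t", header=None, index_col=0, na_values="NA"
    )
    points = pd.read_csv(src / "points.tsv", sep="\t")
    vals = raw.to_numpy(float)
    missing = np.isnan(vals)
    states = np.where(missing, 0, vals).astype(np.int8)
    return SubtreeDataset(
        states=states,
        missing=missing,
        gene_names=[str(g) for g in meta["gene_names"]],
        cell_of_point=points["cell"].astype(str).to_numpy(),
        prev=points["prev"].to_numpy(int),
        delta_t=float(meta["delta_t"]),
        subtree_label=meta.get("subtree_label"),
    )


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def export_network(
    A: np.ndarray,
    Delta: np.ndarray,
    gene_names: Sequence[str],
    tsv_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Export a signed, delayed network as an edge-list TSV and GraphML.

    One row per nonzero entry of ``A``: regulator, target, sign (+1
    activation / -1 repression) and the delay in interpolation units.
    """
    A = np.asarray(A)
    Delta = np.asarray(Delta)
    rows = []
    for i, j in zip(*np.nonzero(A)):
        rows.append(
            {
                "regulator": gene_names[j],
                "target": gene_names[i],
                "sign": int(A[i, j]),
                "delay_units": int(Delta[i, j]),
            }
        )
    pd.DataFrame(rows, columns=["regulator", "target", "sign", "delay_units"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if graphml_path is not None:
        g = nx.DiGraph()
        g.add_nodes_from(gene_names)
        for r in rows:
            g.add_edge(
                r["regulator"], r["target"], sign=r["sign"], delay=r["delay_units"]
            )
        nx.write_graphml(g, graphml_path)


def read_network(
    tsv_path: str | Path, gene_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Read an edge-list TSV back into (A, Delta) matrices."""
    df = pd.read_csv(tsv_path, sep="\t")
    n = len(gene_names)
    index = {g: k for k, g in enumerate(gene_names)}
    A = np.zeros((n, n), dtype=np.int8)
    Delta = np.zeros((n, n), dtype=np.int8)
    for _, row in df.iterrows():
        i, j = index[row["target"]], index[row["regulator"]]
        A[i, j] = int(row["sign"])
        Delta[i, j] = int(row["delay_units"])
    return A, Delta
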