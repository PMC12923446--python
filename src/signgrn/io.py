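"""TSV readers/writers for expression data, labels, edges and gold standards.

All artifact files start with ``#``-prefixed comment headers recording the
package version, the seed and a hash of the run configuration, and
round-trip losslessly through the paired reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import GoldStandard, RankedNetwork
from .labeling import ExpressionDataset

__all__ = [
    "read_expression",
    "write_expression",
    "write_labels",
    "read_labels",
    "write_edges",
    "read_edges",
    "read_gold",
    "write_gold",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed=None, config: dict | None = None) -> str:
    parts = [f"# signgrn v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config is not None:
        parts.append(f"# config={config_hash(config)}")
    return "\n".join(parts) + "\n"


def _write_tsv(path, df: pd.DataFrame, seed=None, config=None,
               index=False, float_format="%.17g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def write_expression(path, data: ExpressionDataset, metadata_path=None,
                     seed=None, config=None) -> None:
    """Write the expression matrix, and optionally the cell metadata table."""
    df = pd.DataFrame(data.values, columns=data.gene_names)
    df.insert(0, "cell_id", data.cell_ids)
    _write_tsv(path, df, seed=seed, config=config)
    if metadata_path is not None:
        pt = ["" if np.isnan(p) else repr(float(p)) for p in data.pseudotime]
        meta = pd.DataFrame({
            "cell_id": data.cell_ids,
            "pseudotime": pt,
            "condition": np.where(np.isnan(data.pseudotime),
                                  "steady", "pseudotime"),
        })
        _write_tsv(metadata_path, meta, seed=seed, config=config)


def read_expression(path, metadata_path=None,
                    with_stimulus: bool = False) -> ExpressionDataset:
    """Read an expression TSV (header = gene names, first column cell id).

    Without a metadata table every cell must carry its pseudotime through
    the metadata file; ``metadata_path`` is therefore required unless the
    expression table itself has a ``pseudotime`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected cell_id plus at least 2 gene columns")
    if df.columns[0] != "cell_id":
        raise ValueError(f"{path}: first column must be 'cell_id'")
    cell_ids = df["cell_id"].tolist()
    inline_pt = "pseudotime" in df.columns
    gene_cols = [c for c in df.columns[1:] if c != "pseudotime"]
    for c in gene_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[~pd.to_numeric(df[c], errors="coerce").notna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {c!r} near line {line}")
    values = df[gene_cols].to_numpy(dtype=float)

    if inline_pt:
        pt = pd.to_numeric(df["pseudotime"], errors="coerce").to_numpy()
    elif metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", comment="#",
                           dtype={"cell_id": str},
                           float_precision="round_trip")
        if "cell_id" not in meta.columns or "pseudotime" not in meta.columns:
            raise ValueError(f"{metadata_path}: needs cell_id and pseudotime columns")
        lookup = dict(zip(meta["cell_id"],
                          pd.to_numeric(meta["pseudotime"], errors="coerce")))
        unknown = set(meta["cell_id"]) - set(cell_ids)
        if unknown:
            raise ValueError(
                f"{metadata_path}: metadata references unknown cell id(s): "
                f"{sorted(unknown)[:5]}"
            )
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValueError(
                f"{metadata_path}: no metadata row for cell id(s): {missing[:5]}"
            )
        pt = np.array([lookup[c] for c in cell_ids], dtype=float)
    else:
        raise ValueError("metadata_path is required when the expression table "
                         "has no pseudotime column")
    data = ExpressionDataset(values, gene_cols, cell_ids, pt)
    return data.with_stimulus() if with_stimulus else data


def write_labels(path, label_table: pd.DataFrame, seed=None, config=None) -> None:
    """Write a long-format label table (cell_id, gene, label, weight)."""
    expected = ["cell_id", "gene", "label", "weight"]
    if list(label_table.columns) != expected:
        raise ValueError(f"label table must have columns {expected}")
    _write_tsv(path, label_table, seed=seed, config=config)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"cell_id": str, "gene": str, "label": str},
                     float_precision="round_trip")
    return df


def write_edges(path, network: RankedNetwork, seed=None, config=None) -> None:
    """Write a ranked edge list (regulator, target, confidence, rank)."""
    df = pd.DataFrame(network.edges, columns=["regulator", "target", "confidence"])
    df["rank"] = np.arange(1, len(df) + 1)
    _write_tsv(path, df, seed=seed, config=config)


def read_edges(path) -> RankedNetwork:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"regulator": str, "target": str},
                     float_precision="round_trip")
    needed = {"regulator", "target", "confidence"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}")
    edges = [(r.regulator, r.target, float(r.confidence))
             for r in df.itertuples()]
    return RankedNetwork.from_edges(edges)


def write_gold(path, gold: GoldStandard, seed=None, config=None) -> None:
    df = pd.DataFrame(sorted(gold.edges), columns=["regulator", "target"])
    _write_tsv(path, df, seed=seed, config=config)


def read_gold(path, genes: list[str] | None = None) -> GoldStandard:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gold standard needs two columns")
    cols = list(df.columns[:2])
    edges = {(r, t) for r, t in zip(df[cols[0]], df[cols[1]])}
    if genes is None:
        genes = sorted({g for e in edges for g in e})
    return GoldStandard(genes=list(genes), edges=edges)
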