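"""File formats: gene x sample TSV, sample metadata TSV, GMT gene sets, gene lists.

Conventions:

* matrices: tab-separated, header row of sample ids, first column ``gene``;
* metadata: tab-separated with columns ``sample, tissue, condition, source,
  subject`` (optional ``distance``);
* gene sets: GMT — one set per line, ``name <tab> description <tab> member...``;
* control/housekeeping lists: plain text, one gene id per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def write_matrix(m: ExpressionMatrix, counts_path, meta_path=None) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t")
    if meta_path is not None:
        m.samples.to_csv(meta_path, sep="\t", index=False)


def read_matrix(counts_path, meta_path, scale: str = "counts") -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"subject": str, "sample": str})
    meta["subject"] = meta["subject"].astype(str)
    return ExpressionMatrix(values=values, samples=meta, scale=scale)


def read_gene_list(path) -> list[str]:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: member list}``.

    Duplicate members within a set are dropped (first occurrence kept); empty
    sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name, _desc, *members = parts
        members = [g for g in members if g]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        seen: dict[str, None] = {}
        for g in members:
            seen.setdefault(g)
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = list(seen)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = []
    for name, members in sets.items():
        lines.append("\t".join([name, description, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def toy_gmt_path() -> Path:
    """Path of the bundled synthetic toy gene-set collection (for examples/tests)."""
    return Path(__file__).parent / "data" / "toy_sets.gmt"


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
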