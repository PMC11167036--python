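"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and metadata travel as TSV, gene sets as GMT (set name, description,
then tab-separated members), pseudogene lists as one ID per line, and
structured results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix (gene IDs in column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype("int64")


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table indexed by ``sample_id``."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_pseudogene_list(path: str | Path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_pseudogene_list(ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ids)))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection; returns ``{set_name: members}``.

    The second GMT column (description) is discarded; duplicate members
    within a set are collapsed preserving first occurrence.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 fields): {line!r}")
        name, _desc, *members = fields
        seen: list[str] = []
        for m in members:
            if m and m not in seen:
                seen.append(m)
        sets[name] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = []
    for name, members in sets.items():
        lines.append("\t".join([name, description, *members]))
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
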