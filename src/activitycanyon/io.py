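"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV/CSV; floats are written repr-faithfully so that a
write/read round trip is bit-stable.  Drug and target identifiers are
opaque strings (no case folding, no coercion).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from activitycanyon.errors import InputConsistencyError
from activitycanyon.pair_network import (
    PAIR_COLUMNS,
    ChemSimilarityMatrix,
    DrugTargetNetwork,
)


def read_drug_target_edges(path) -> DrugTargetNetwork:
    """Bipartite network from a two-column TSV of (drug_id, target_id) edges.

    One active drug-target pair per line; duplicate lines are collapsed.
    Drugs and targets appear in first-seen order.
    """
    path = Path(path)
    drugs: list[str] = []
    targets: list[str] = []
    drug_idx: dict[str, int] = {}
    target_idx: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise InputConsistencyError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            d, t = parts[0], parts[1]
            if d not in drug_idx:
                drug_idx[d] = len(drugs)
                drugs.append(d)
            if t not in target_idx:
                target_idx[t] = len(targets)
                targets.append(t)
            edges.add((drug_idx[d], target_idx[t]))
    if not edges:
        raise InputConsistencyError(f"{path}: no edges found")
    activity = np.zeros((len(drugs), len(targets)), dtype=np.int8)
    for i, k in edges:
        activity[i, k] = 1
    return DrugTargetNetwork(drugs, targets, activity)


def write_drug_target_edges(net: DrugTargetNetwork, path) -> None:
    with open(path, "w") as fh:
        for i, drug in enumerate(net.drug_ids):
            for k in np.flatnonzero(net.activity[i]):
                fh.write(f"{drug}\t{net.target_ids[k]}\n")


def read_fingerprints(path) -> tuple[list[str], np.ndarray]:
    """Fingerprints from a TSV of drug_id and a fixed-length 0/1 bitstring."""
    path = Path(path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputConsistencyError(
                    f"{path}:{lineno}: expected drug_id<TAB>bitstring"
                )
            drug, bits = parts[0], parts[1]
            if set(bits) - {"0", "1"}:
                raise InputConsistencyError(
                    f"{path}:{lineno}: bitstring holds characters other than 0/1"
                )
            if width is None:
                width = len(bits)
            elif len(bits) != width:
                raise InputConsistencyError(
                    f"{path}:{lineno}: fingerprint length {len(bits)} != {width}"
                )
            ids.append(drug)
            rows.append(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
    if not ids:
        raise InputConsistencyError(f"{path}: no fingerprints found")
    return ids, np.vstack(rows).astype(np.int8)


def read_similarity_matrix(path) -> ChemSimilarityMatrix:
    """Square similarity matrix from CSV/TSV with header row and id column.

    Symmetry (within 1e-9) and the [0, 1] value range are validated by
    the :class:`ChemSimilarityMatrix` constructor.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    ids = [str(x) for x in df.index]
    if [str(x) for x in df.columns] != ids:
        raise InputConsistencyError(f"{path}: row and column ids differ")
    return ChemSimilarityMatrix(ids, df.to_numpy(dtype=float))


def write_similarity_matrix(chem: ChemSimilarityMatrix, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(chem.values, index=chem.drug_ids, columns=chem.drug_ids)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_pair_weights(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pair_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise InputConsistencyError(f"{path}: missing pair-table columns {missing}")
    return df


def load_config(path) -> dict:
    """Run configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
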