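"""Text-based readers/writers for SPD matrices, collections and result tables.

Formats (all plain text, full round-trip ``%.17g`` float precision):

- single matrix: delimited rows (whitespace or comma), with a one-line
  ``# dim P`` header comment;
- collection container: one file holding N matrices, each introduced by a
  ``> identifier`` line;
- directory collection: one matrix file per subject, ordered
  lexicographically by filename stem (the subject identifier);
- labels sidecar: two-column TSV ``subject_id<TAB>label``;
- result tables: TSV with header, one row per record;
- run manifests: JSON files recording the resolved configuration and seeds
  of a run, written next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .collection import ConnectomeCollection
from .geometry import check_spd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_matrix_collection",
    "write_matrix_collection",
    "read_labels",
    "write_results_table",
    "read_results_table",
    "write_run_manifest",
]

_FLOAT_FMT = "%.17g"


def _parse_rows(lines, origin: str) -> np.ndarray:
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"{origin}: no numeric data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{origin}: ragged rows (widths {sorted(widths)})")
    arr = np.array(rows, dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{origin}: matrix is {arr.shape[0]}x{arr.shape[1]}, not square")
    return arr


def read_matrix(path, validate: bool = True) -> np.ndarray:
    """Read one P x P matrix from a delimited text file (SPD-validated)."""
    path = Path(path)
    arr = _parse_rows(path.read_text().splitlines(), str(path))
    return check_spd(arr, name=str(path)) if validate else arr


def write_matrix(path, matrix) -> None:
    """Write one matrix as delimited text with a dimension header comment."""
    matrix = np.asarray(matrix, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# dim {matrix.shape[0]}\n")
        for row in matrix:
            fh.write("\t".join(_FLOAT_FMT % x for x in row) + "\n")


def read_labels(path) -> dict:
    """Read a ``subject_id<TAB>label`` sidecar table (header row optional)."""
    out: dict = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
        if i == 0 and parts[0].lower() in ("subject_id", "id"):
            continue
        out[parts[0]] = parts[1]
    return out


def read_matrix_collection(path, labels_path=None) -> ConnectomeCollection:
    """Read a collection from a container file or a directory of matrix files.

    A directory is read one file per subject (identifier = filename stem),
    ordered lexicographically; a file is parsed as a ``> id`` container.
    Every matrix is SPD-validated; failures name the subject and the check.
    When a labels sidecar is given, every subject must be labelled.
    """
    path = Path(path)
    ids: list[str] = []
    mats: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
        if not files:
            raise ValueError(f"{path}: empty directory")
        for p in files:
            ids.append(p.stem)
            mats.append(_parse_rows(p.read_text().splitlines(), str(p)))
    else:
        current: list[str] | None = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                if current is not None:
                    mats.append(_parse_rows(current, f"{path}:{ids[-1]}"))
                ids.append(line[1:].strip() or f"{len(ids):03d}")
                current = []
            elif current is not None:
                current.append(line)
        if current is None:
            raise ValueError(f"{path}: not a collection container (no '>' records)")
        mats.append(_parse_rows(current, f"{path}:{ids[-1]}"))
        order = np.argsort(ids, kind="stable")
        ids = [ids[i] for i in order]
        mats = [mats[i] for i in order]
    dims = {m.shape[0] for m in mats}
    if len(dims) != 1:
        raise ValueError(f"{path}: mixed matrix dimensions {sorted(dims)}")
    for sid, m in zip(ids, mats):
        check_spd(m, name=f"subject {sid}")
    labels = None
    if labels_path is not None:
        table = read_labels(labels_path)
        missing = [s for s in ids if s not in table]
        if missing:
            raise ValueError(f"missing label(s) for subject(s): {missing}")
        labels = [table[s] for s in ids]
    return ConnectomeCollection(np.stack(mats), labels=labels, ids=ids)


def write_matrix_collection(path, collection: ConnectomeCollection) -> None:
    """Write a collection as a single ``> id`` container file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(
            f"# spdmean collection n={collection.n_samples} dim={collection.dim}\n"
        )
        for sid, mat in zip(collection.ids, collection.matrices):
            fh.write(f"> {sid}\n")
            for row in mat:
                fh.write("\t".join(_FLOAT_FMT % x for x in row) + "\n")


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise TypeError(f"unsupported record type {type(record)!r}")


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return _FLOAT_FMT % value
    return str(value)


def write_results_table(records, path) -> None:
    """Write homogeneous records (dataclasses or dicts) as a TSV table.

    Floats are written at full round-trip precision; row order is the input
    order, so rewriting identical records is byte-identical. An empty record
    list yields a header-only file (requires dict records or none at all).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dicts = [_record_to_dict(r) for r in records]
    if dicts:
        keys = list(dicts[0])
        for d in dicts:
            if list(d) != keys:
                raise ValueError("records are not homogeneous")
    else:
        keys = []
    with path.open("w") as fh:
        fh.write("\t".join(keys) + "\n")
        for d in dicts:
            fh.write("\t".join(_format_cell(d[k]) for k in keys) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (``NA`` as missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_run_manifest(path, command: str, config: dict, seeds) -> dict:
    """Write a JSON manifest of a run (command, resolved config, seeds)."""
    manifest = {
        "command": command,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "seeds": [int(s) for s in np.atleast_1d(seeds)],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifact_version": _package_version(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v


def _package_version() -> str:
    from . import __version__

    return __version__
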