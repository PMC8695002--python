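"""Reading and writing response CSVs and result tables.

Response files are plain CSV with columns ``item_1 .. item_I`` (integer
categories), ``group`` (0 = reference, 1 = focal) and optionally ``theta``.
Output tables are TSV. Every file written here carries ``#``-prefixed header
comments recording the configuration hash and seed needed to regenerate it;
readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
import re

import numpy as np
import pandas as pd

from .grm import ResponseDataset

__all__ = [
    "ResponseValidationError",
    "read_response_csv",
    "write_response_csv",
    "write_table_tsv",
    "config_hash",
]

_ITEM_RE = re.compile(r"^item_(\d+)$")


class ResponseValidationError(ValueError):
    """A response file failed validation (names the offending row/column)."""


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata_header(metadata: dict | None) -> str:
    metadata = dict(metadata or {})
    metadata.setdefault("config_hash", config_hash(metadata))
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def read_response_csv(path, zero_based: bool = False) -> ResponseDataset:
    """Read and validate a response CSV into a :class:`ResponseDataset`.

    With ``zero_based`` the item columns are 0-coded (e.g. a 0..4 Likert
    scale) and shifted to the internal 1..J coding. Missing values,
    non-integer entries and out-of-range categories raise
    :class:`ResponseValidationError` naming the row and column; missing data
    are never silently imputed.
    """
    df = pd.read_csv(path, comment="#")
    item_cols = sorted((c for c in df.columns if _ITEM_RE.match(c)),
                       key=lambda c: int(_ITEM_RE.match(c).group(1)))
    if not item_cols:
        raise ResponseValidationError("no item_* columns found")
    indices = [int(_ITEM_RE.match(c).group(1)) for c in item_cols]
    if indices != list(range(1, len(item_cols) + 1)):
        raise ResponseValidationError(
            f"item columns must be item_1..item_I without gaps, got {item_cols}"
        )
    if "group" not in df.columns:
        raise ResponseValidationError("missing required column 'group'")
    for col in item_cols + ["group"]:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ResponseValidationError(
                f"missing value in column '{col}', row {int(bad[0])}"
            )
        vals = df[col].to_numpy()
        if not np.all(vals == np.round(vals)):
            row = int(np.nonzero(vals != np.round(vals))[0][0])
            raise ResponseValidationError(
                f"non-integer entry in column '{col}', row {row}"
            )
    resp = df[item_cols].to_numpy(dtype=np.int64)
    if zero_based:
        resp = resp + 1
    lo = resp.min()
    if lo < 1:
        hint = " (0-coded input? pass zero_based=True)" if lo == 0 else ""
        col = item_cols[int(np.argwhere(resp == lo)[0][1])]
        raise ResponseValidationError(
            f"category {lo} below valid range in column '{col}'{hint}"
        )
    group = df["group"].to_numpy(dtype=np.int64)
    if not np.all(np.isin(group, (0, 1))):
        row = int(np.nonzero(~np.isin(group, (0, 1)))[0][0])
        raise ResponseValidationError(
            f"group must be coded 0/1; bad value at row {row}"
        )
    theta = df["theta"].to_numpy(dtype=float) if "theta" in df.columns else None
    return ResponseDataset(responses=resp, group=group, theta_true=theta)


def write_response_csv(dataset: ResponseDataset, path, metadata: dict | None = None,
                       include_theta: bool = False) -> None:
    """Write a dataset as CSV with ``#`` header comments (config hash, seed)."""
    frame = dataset.to_frame(include_theta=include_theta)
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        frame.to_csv(fh, index=False)


def write_table_tsv(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a result table as TSV with ``#`` header comments."""
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        frame.to_csv(fh, sep="\t", index=False)
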