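"""File I/O: compound tables, token-table dumps, reports, run manifests.

The canonical input is a delimited table with a header naming ``smiles``
and ``label`` columns; CORAL-style whitespace-delimited two-column files
(SMILES then endpoint, no header) are accepted read-only.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .descriptor import CorrelationWeightTable

__all__ = [
    "read_compound_table",
    "write_token_table",
    "write_report",
    "write_manifest",
    "sha256_of",
]


def _validate_labels(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = df[~df["label"].astype(str).isin({"0", "1"})]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad.index[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: non-binary labels at line(s) {lines}")
    df["label"] = df["label"].astype(int)
    df["smiles"] = df["smiles"].astype(str)
    return df[["smiles", "label"]]


def read_compound_table(path) -> pd.DataFrame:
    """Read a (smiles, label) table from CSV/TSV (header required) or from
    CORAL-style whitespace-delimited text (no header)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "," in first or "\t" in first:
        sep = "," if "," in first else "\t"
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.strip().lower() for c in df.columns]
        if "smiles" not in df.columns or "label" not in df.columns:
            raise ValueError(f"{path}: header must name 'smiles' and 'label' columns")
        return _validate_labels(df, path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed row at line {lineno} (need 2 columns)")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=["smiles", "label"])
    bad = df[~df["label"].isin({"0", "1"})]
    if len(bad):
        raise ValueError(f"{path}: non-binary label at line {bad.index[0] + 1}")
    df["label"] = df["label"].astype(int)
    return df


def write_token_table(table: CorrelationWeightTable, path) -> None:
    """One attribute per line: kind, display token, frequency, rare flag."""
    with open(path, "w") as fh:
        fh.write("kind\ttoken\tdocument_frequency\trare\n")
        for key in sorted(table.entries):
            e = table.entries[key]
            fh.write(f"{key.kind}\t{key.token}\t{e.document_frequency}\t{int(e.rare)}\n")


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, **fields) -> None:
    """Run manifest: config echo, seeds, input checksums, chosen epoch,
    statistics — everything needed to re-execute a run bit-identically."""
    manifest = {"timestamp": datetime.now(timezone.utc).isoformat(), **fields}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
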