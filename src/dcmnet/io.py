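"""Reading, writing and validating the pipeline's text artifacts.

Sessions travel as TSV (one row per volume, one column per region, BOLD in
signal-change fraction) with a JSON sidecar holding TR, condition, subject,
seed and noise settings. Evidence matrices travel as CSV with subjects as
rows and model ids or family names as columns.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd

from .comparison import EvidenceMatrix
from .forward import SessionData
from .model_space import REGIONS

__all__ = [
    "write_session",
    "read_session",
    "write_evidence",
    "read_evidence",
    "validate_io",
]


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".json"


def write_session(session: SessionData, path: str) -> None:
    """Write a session as TSV plus a JSON sidecar next to it."""
    df = session.data.copy()
    df.insert(0, "volume", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "TR": session.TR,
        "condition": session.condition,
        "subject": session.subject,
        "seed": session.seed,
        "noise": session.noise,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_session(path: str) -> SessionData:
    df = pd.read_csv(path, sep="\t")
    if "volume" in df.columns:
        df = df.drop(columns="volume")
    meta = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    return SessionData(
        data=df,
        TR=float(meta.get("TR", 4.0)),
        condition=meta.get("condition", "unspecified"),
        subject=meta.get("subject", "unknown"),
        seed=meta.get("seed"),
        noise=meta.get("noise"),
    )


def write_evidence(ev: EvidenceMatrix, path: str) -> None:
    pd.DataFrame(ev.values, index=list(ev.subjects), columns=list(ev.columns)).to_csv(
        path, index_label="subject"
    )


def read_evidence(path: str) -> EvidenceMatrix:
    df = pd.read_csv(path, index_col="subject")
    return EvidenceMatrix(
        values=df.to_numpy(dtype=float),
        subjects=tuple(str(s) for s in df.index),
        columns=tuple(str(c) for c in df.columns),
    )


def validate_io(path: str) -> List[str]:
    """Structured diagnostics (empty list = valid) for a session TSV or JSON file."""
    diags: List[str] = []
    if not os.path.exists(path):
        return [f"{path}: file does not exist"]
    if path.endswith(".json"):
        try:
            with open(path) as fh:
                json.load(fh)
        except json.JSONDecodeError as exc:
            diags.append(f"{path}: invalid JSON ({exc})")
        return diags

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed table
        return [f"{path}: unreadable as TSV ({exc})"]
    expected = ["volume", *REGIONS]
    missing = [c for c in expected if c not in df.columns]
    for col in missing:
        diags.append(f"{path}: missing column {col!r}")
    if len(df.columns) != len(expected) and not missing:
        diags.append(f"{path}: expected {len(expected)} columns, found {len(df.columns)}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if len(bad):
            diags.append(
                f"{path}: non-finite or non-numeric value at row {int(bad[0])}, column {col!r}"
            )
    return diags
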