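"""Delimited-text matrix readers/writers and result serialization.

Matrices travel as plain CSV/TSV (comma by default, decimal point only),
floats are printed with ``%.17g`` so round trips are exact, and run
metadata uses a line-oriented ``key: value`` format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .power import Decomposition

__all__ = [
    "LabeledMatrix",
    "read_decomposition",
    "read_key_value",
    "read_matrix",
    "write_decomposition",
    "write_matrix",
]

_FLOAT_FMT = "%.17g"


@dataclass
class LabeledMatrix:
    """A dense matrix with optional row and column labels."""

    values: np.ndarray
    row_names: list[str] | None = None
    col_names: list[str] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_matrix(
    path: str | Path,
    has_header: bool = False,
    has_rownames: bool = False,
    delimiter: str = ",",
) -> LabeledMatrix:
    """Read a rectangular numeric table from delimited text.

    Non-numeric cells and ragged/missing entries are rejected with
    1-based row/column coordinates in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if has_header else None,
            index_col=0 if has_rownames else None,
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged table ({exc})") from None

    raw = frame.to_numpy()
    numeric = frame.apply(lambda col: pd.to_numeric(col, errors="coerce")).to_numpy(dtype=float)
    bad = np.isnan(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = raw[i, j]
        where = f"row {i + 1}, column {j + 1}"
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            raise ValueError(f"{path}: missing value (ragged row?) at {where}")
        raise ValueError(f"{path}: non-numeric value {cell!r} at {where}")

    row_names = [str(v) for v in frame.index] if has_rownames else None
    col_names = [str(v) for v in frame.columns] if has_header else None
    return LabeledMatrix(numeric, row_names, col_names)


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_names: list[str] | None = None,
    col_names: list[str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write a matrix as delimited text; floats round-trip exactly."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    frame = pd.DataFrame(values, index=row_names, columns=col_names)
    frame.to_csv(
        path,
        sep=delimiter,
        header=col_names is not None,
        index=row_names is not None,
        float_format=_FLOAT_FMT,
    )


def read_key_value(path: str | Path) -> dict[str, str]:
    """Parse a ``key: value`` metadata file into a string dict."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            out[key.strip()] = val.strip()
    return out


def write_decomposition(
    dec: Decomposition,
    outdir: str | Path,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Serialize a decomposition: P, Q, delta as CSV plus a metadata sidecar.

    The metadata records the method, per-component iteration counts and
    convergence flags, and the orthogonality/sparsity residuals of the
    written factors so a reader can audit the result without recomputing
    the decomposition.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "P": out / "P.csv",
        "Q": out / "Q.csv",
        "delta": out / "delta.csv",
        "metadata": out / "metadata.txt",
    }
    write_matrix(paths["P"], dec.P)
    write_matrix(paths["Q"], dec.Q)
    write_matrix(paths["delta"], dec.delta.reshape(-1, 1))

    off_p, off_q = dec.max_offdiag_crossprod()
    meta: dict[str, object] = {
        "kind": "decomposition",
        "method": dec.method,
        "rank": dec.rank,
        "iterations": " ".join(str(int(v)) for v in dec.iterations),
        "converged": " ".join(str(bool(v)) for v in dec.converged),
        "max_offdiag_PtP": f"{off_p:.17g}",
        "max_offdiag_QtQ": f"{off_q:.17g}",
        "l1_norm_P": " ".join(_FLOAT_FMT % v for v in np.abs(dec.P).sum(axis=0)),
        "l1_norm_Q": " ".join(_FLOAT_FMT % v for v in np.abs(dec.Q).sum(axis=0)),
    }
    for key, val in dec.diagnostics.items():
        if isinstance(val, np.ndarray):
            meta[key] = " ".join(_FLOAT_FMT % v for v in val)
        else:
            meta[key] = val
    if extra_metadata:
        meta.update(extra_metadata)
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"{key}: {val}\n")
    return paths


def read_decomposition(outdir: str | Path) -> tuple[Decomposition, dict[str, str]]:
    """Reload a decomposition directory written by :func:`write_decomposition`."""
    out = Path(outdir)
    p = read_matrix(out / "P.csv").values
    q = read_matrix(out / "Q.csv").values
    delta = read_matrix(out / "delta.csv").values.ravel()
    meta_path = out / "metadata.txt"
    meta = read_key_value(meta_path) if meta_path.exists() else {}
    rank = p.shape[1]
    iters = np.array([int(v) for v in meta.get("iterations", "").split() or [0] * rank])
    conv = np.array([v == "True" for v in meta.get("converged", "").split() or ["True"] * rank])
    dec = Decomposition(p, q, delta, iters, conv, method=meta.get("method", "unknown"))
    return dec, meta
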