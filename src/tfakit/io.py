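"""Readers and writers for the delimited formats used across the pipeline.

All tables are tab-separated text.  Missing Ct values are written as empty
cells and read back from a tolerant sentinel set ({"", "NA", "NaN", "999"};
999 is a common qPCR no-call code).  Result tables carry a provenance header
of ``# key = value`` lines recording the thresholds and seeds that produced
them, so any output can be traced back to its command.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd

from . import __version__
from .panel import ReducedPanel
from .preprocess import CtMatrix, DataError, ExpressionMatrix

MISSING_SENTINELS = ("", "NA", "NaN", "nan", "999")


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# provenance headers
# --------------------------------------------------------------------------

def _write_header(fh, provenance: dict[str, Any]) -> None:
    fh.write(f"# tfakit = {__version__}\n")
    for key, val in provenance.items():
        fh.write(f"# {key} = {val}\n")


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    header: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_lines += 1
            body = line[1:].strip()
            if "=" not in body:
                raise ParseError(f"{path}: malformed header line {n_lines}: "
                                 f"{line.strip()!r}")
            key, val = body.split("=", 1)
            header[key.strip()] = val.strip()
    return header, n_lines


# --------------------------------------------------------------------------
# Ct matrices and sample metadata
# --------------------------------------------------------------------------

def write_ct_matrix(ct: CtMatrix, path: str | Path,
                    meta_path: str | Path) -> None:
    """Write a Ct matrix (assays × samples) and its sample metadata."""
    path, meta_path = Path(path), Path(meta_path)
    out = ct.values.copy()
    out.insert(0, "housekeeping",
               ct.is_housekeeping.map({True: 1, False: 0}))
    out.rename_axis("assay").to_csv(path, sep="\t", na_rep="")
    ct.meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_ct_matrix(path: str | Path, meta_path: str | Path,
                   detect_max_ct: float = 28.0) -> CtMatrix:
    """Read a Ct matrix and metadata written by :func:`write_ct_matrix`.

    Duplicate assay or sample ids, samples without metadata, and non-numeric
    Ct entries outside the missing-sentinel set are all rejected with the
    offending id or line named.
    """
    path, meta_path = Path(path), Path(meta_path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "assay" or "housekeeping" not in raw.columns:
        raise ParseError(f"{path}: expected 'assay' and 'housekeeping' columns")
    dup_assays = raw["assay"][raw["assay"].duplicated()]
    if len(dup_assays):
        raise ParseError(f"{path}: duplicated assay id {dup_assays.iloc[0]!r}")
    sample_cols = [c for c in raw.columns if c not in ("assay", "housekeeping")]
    seen = set()
    for c in sample_cols:
        base = c.split(".")[0]
        if base in seen:
            raise ParseError(f"{path}: duplicated sample column {base!r}")
        seen.add(base)
    values = raw[sample_cols].replace(list(MISSING_SENTINELS), np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        for i, row in enumerate(raw.itertuples(index=False), start=2):
            for c, cell in zip(raw.columns, row):
                if c in ("assay", "housekeeping") or cell in MISSING_SENTINELS:
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric Ct {cell!r} at line {i}, "
                        f"column {c!r}") from exc
        raise
    values.index = raw["assay"]
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    missing = [s for s in sample_cols if s not in meta.index]
    if missing:
        raise ParseError(f"{meta_path}: no metadata for samples {missing[:5]}")
    return CtMatrix(
        values=values,
        is_housekeeping=raw.set_index("assay")["housekeeping"].astype(int) == 1,
        meta=meta.loc[sample_cols],
        detect_max_ct=detect_max_ct,
    )


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {"scale": expr.scale, **{
            k: v for k, v in expr.provenance.items()}})
        expr.values.rename_axis("gene").to_csv(fh, sep="\t")


def read_expression(path: str | Path,
                    meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    path = Path(path)
    header, n_skip = _read_header(path)
    if "scale" not in header:
        raise ParseError(f"{path}: missing 'scale' in provenance header")
    values = pd.read_csv(path, sep="\t", skiprows=n_skip, index_col="gene")
    if meta is None:
        meta = pd.DataFrame(index=values.columns)
    return ExpressionMatrix(values=values, scale=header["scale"],
                            meta=meta, provenance=dict(header))


# --------------------------------------------------------------------------
# panels
# --------------------------------------------------------------------------

def write_panel(panel: ReducedPanel, path: str | Path) -> None:
    """One row per selected gene with module id, rank and distance."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {**panel.params,
                           "housekeeping": ";".join(panel.housekeeping)})
        panel.table.to_csv(fh, sep="\t", index=False)


def read_panel(path: str | Path) -> ReducedPanel:
    path = Path(path)
    header, n_skip = _read_header(path)
    table = pd.read_csv(path, sep="\t", skiprows=n_skip)
    hk = header.pop("housekeeping", "")
    housekeeping = [g for g in hk.split(";") if g]
    panel = ReducedPanel(table=table, housekeeping=housekeeping, params=header)
    panel.validate()
    return panel


# --------------------------------------------------------------------------
# DEG tables
# --------------------------------------------------------------------------

def write_deg_table(table: pd.DataFrame, path: str | Path,
                    provenance: dict[str, Any] | None = None) -> None:
    """Write a per-gene statistics table with a provenance header."""
    path = Path(path)
    prov = dict(provenance or {})
    prov.setdefault("fc_threshold", table.attrs.get("fc_threshold", 2.0))
    prov.setdefault("alpha", table.attrs.get("alpha", 0.01))
    with open(path, "w") as fh:
        _write_header(fh, prov)
        table.rename_axis("gene").to_csv(fh, sep="\t")


def read_deg_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    header, n_skip = _read_header(path)
    if not header:
        raise ParseError(f"{path}: missing provenance header")
    table = pd.read_csv(path, sep="\t", skiprows=n_skip, index_col="gene")
    if "called" in table:
        table["called"] = table["called"].astype(bool)
    return table, header


# --------------------------------------------------------------------------
# ranked gene-list export (for external enrichment/network services)
# --------------------------------------------------------------------------

def export_gene_list(
    table: pd.DataFrame,
    path: str | Path,
    direction: Literal["all", "up", "down"] = "all",
) -> pd.DataFrame:
    """Export called genes, ranked by |signed FC| then adjusted p.

    Writes a one-symbol-per-line file at ``path`` plus an annotated
    ``<path>.annot.tsv`` with signed FC and adjusted p, for pasting into
    external network/enrichment tools.  Returns the exported frame.  Zero
    called genes yields an empty file (with a warning), not an error.
    """
    import warnings

    if "called" not in table:
        raise DataError("table has no 'called' column; run the DEG caller first")
    sub = table[table["called"]].copy()
    if direction == "up":
        sub = sub[sub["signed_fc"] > 0]
    elif direction == "down":
        sub = sub[sub["signed_fc"] < 0]
    elif direction != "all":
        raise ValueError(f"unknown direction {direction!r}")
    sub = sub.sort_values(["signed_fc", "p_adj"],
                          key=lambda s: s.abs() if s.name == "signed_fc" else s,
                          ascending=[False, True])
    if sub.index.duplicated().any():
        raise DataError("duplicate gene symbols in DEG table")
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in sub.index))
    annot = sub[["signed_fc", "p_adj"]].copy()
    annot["direction"] = np.where(sub["signed_fc"] > 0, "up", "down")
    annot.rename_axis("gene").to_csv(path.with_suffix(path.suffix + ".annot.tsv"),
                                     sep="\t")
    if sub.empty:
        warnings.warn(f"no called genes to export to {path}", stacklevel=2)
    return annot
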