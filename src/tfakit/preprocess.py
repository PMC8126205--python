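"""Upstream processing of targeted qPCR Ct data.

The stages, in the order a run applies them:

1. :func:`mask_out_of_range` — Ct values beyond the detectable range of the
   instrument become missing.
2. :func:`qc_samples` — samples with poor amplification (too many missing
   assays) are excluded.
3. :func:`validate_housekeeping` — the housekeeping pool is validated by
   cross-sample stability before it is trusted for normalization.
4. :func:`normalize_dct` — per-sample normalization against the mean Ct of
   the validated housekeeping pool; higher dCt means lower expression.
5. :func:`impute_missing` — regularized iterative-PCA completion of the
   remaining missing cells.
6. :func:`to_neg_dct` — sign flip for ordination/clustering, where "up" should
   plot as "more".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PHASES = ("I", "II")


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


@dataclass
class CtMatrix:
    """Raw threshold-cycle values for a panel run.

    ``values`` is assays × samples (float; NaN = missing / no call).
    ``is_housekeeping`` flags the normalization assays.  ``meta`` is indexed
    by sample id and carries at least ``participant`` and ``phase`` (I = pre,
    II = post supplementation), plus optional serum 25(OH)D levels.
    """

    values: pd.DataFrame
    is_housekeeping: pd.Series
    meta: pd.DataFrame
    detect_max_ct: float = 28.0

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.is_housekeeping.index):
            self.is_housekeeping = self.is_housekeeping.reindex(self.values.index)
        if self.is_housekeeping.isna().any():
            raise DataError("housekeeping flag missing for some assays")
        missing_meta = [s for s in self.values.columns if s not in self.meta.index]
        if missing_meta:
            raise DataError(f"samples without metadata: {missing_meta[:5]}")
        bad_phase = set(self.meta["phase"]) - set(PHASES)
        if bad_phase:
            raise DataError(f"phases outside {PHASES}: {sorted(bad_phase)}")
        dup = self.meta.reset_index().duplicated(["participant", "phase"])
        if dup.any():
            raise DataError("duplicate (participant, phase) samples in metadata")
        vals = self.values.to_numpy(dtype=float)
        observed = vals[np.isfinite(vals)]
        if observed.size and observed.min() <= 0:
            raise DataError("Ct values must be positive cycles")

    @property
    def target_assays(self) -> pd.Index:
        return self.values.index[~self.is_housekeeping]

    @property
    def housekeeping_assays(self) -> pd.Index:
        return self.values.index[self.is_housekeeping]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, keep: list[str]) -> "CtMatrix":
        return CtMatrix(
            values=self.values[keep],
            is_housekeeping=self.is_housekeeping,
            meta=self.meta.loc[keep],
            detect_max_ct=self.detect_max_ct,
        )


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes × samples, on the dCt or −dCt scale."""

    values: pd.DataFrame
    scale: str  # "dCt" or "neg_dCt"
    meta: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("dCt", "neg_dCt"):
            raise DataError(f"unknown scale tag {self.scale!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def mask_out_of_range(ct: CtMatrix) -> CtMatrix:
    """Set Ct values beyond the detectable range to missing.

    Anything above ``detect_max_ct`` (too few template molecules to cross the
    detection threshold within the trusted cycle range) becomes NaN.
    Non-numeric instrument codes are expected to be NaN already at parse time.
    """
    masked = ct.values.where(ct.values <= ct.detect_max_ct)
    n_masked = int(masked.isna().sum().sum() - ct.values.isna().sum().sum())
    log.info("mask_out_of_range: %d cells beyond Ct %.1f set missing",
             n_masked, ct.detect_max_ct)
    return replace(ct, values=masked)


def qc_samples(
    ct: CtMatrix, max_missing_frac: float = 0.5
) -> tuple[CtMatrix, pd.DataFrame]:
    """Exclude samples with poor amplification signal.

    A sample fails when the fraction of missing assays across the whole panel
    exceeds ``max_missing_frac``.  Returns the passing matrix and a per-sample
    report with missing fractions and pass/fail flags.
    """
    frac = ct.values.isna().mean(axis=0)
    report = pd.DataFrame({
        "missing_frac": frac,
        "excluded": frac > max_missing_frac,
    })
    keep = list(report.index[~report["excluded"]])
    if not keep:
        raise DataError("all samples excluded by QC")
    if report["excluded"].any():
        log.warning("qc_samples: excluded %s",
                    list(report.index[report["excluded"]]))
    return ct.subset_samples(keep), report


def validate_housekeeping(ct: CtMatrix, sd_max: float = 1.5) -> pd.DataFrame:
    """Validate the housekeeping pool by cross-sample Ct stability.

    Housekeeping genes are only usable for normalization if their expression
    is steady across samples; genes whose Ct standard deviation exceeds
    ``sd_max`` cycles are dropped from the pool.  Returns a report (index =
    housekeeping gene) with columns ``sd`` and ``retained``.
    """
    hk = ct.housekeeping_assays
    if len(hk) == 0:
        raise DataError("no housekeeping assays present")
    sds = ct.values.loc[hk].std(axis=1, ddof=1)
    report = pd.DataFrame({"sd": sds, "retained": sds <= sd_max})
    if not report["retained"].any():
        raise DataError(
            "no housekeeping gene passed validation; per-gene SDs: "
            + ", ".join(f"{g}={s:.2f}" for g, s in sds.items())
        )
    dropped = report.index[~report["retained"]]
    if len(dropped):
        log.warning("validate_housekeeping: dropped %s", list(dropped))
    return report


def normalize_dct(ct: CtMatrix, pool: list[str] | pd.Index) -> ExpressionMatrix:
    """Normalize target Ct values to the housekeeping pool, giving dCt.

    dCt(gene, sample) = Ct(gene, sample) − mean(pool Ct of that sample).
    The arithmetic mean of housekeeping Ct corresponds to the geometric mean
    of linear abundances.  Samples missing some pool genes fall back to the
    mean of the pool genes present (logged); a sample with no pool gene at
    all is an error.
    """
    pool = list(pool)
    absent = [g for g in pool if g not in ct.values.index]
    if absent:
        raise DataError(f"pool genes absent from matrix: {absent}")
    pool_ct = ct.values.loc[pool]
    n_present = pool_ct.notna().sum(axis=0)
    if (n_present == 0).any():
        bad = list(n_present.index[n_present == 0])
        raise DataError(f"samples with no detectable housekeeping gene: {bad}")
    partial = n_present.index[(n_present > 0) & (n_present < len(pool))]
    if len(partial):
        log.info("normalize_dct: %d samples use a partial pool", len(partial))
    pool_mean = pool_ct.mean(axis=0, skipna=True)
    dct = ct.values.loc[ct.target_assays].sub(pool_mean, axis=1)
    return ExpressionMatrix(
        values=dct,
        scale="dCt",
        meta=ct.meta.loc[dct.columns],
        provenance={"housekeeping_pool": pool,
                    "detect_max_ct": ct.detect_max_ct},
    )


def impute_missing(
    expr: ExpressionMatrix,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ExpressionMatrix:
    """Complete missing cells by regularized iterative PCA.

    Missing cells start at their gene (row) means; the matrix is then
    alternately approximated by its rank-``n_components`` truncated SVD
    (after row centering) and the missing cells refilled from the
    reconstruction, until the largest refill change drops below ``tol``.
    Observed cells are never altered.  Complete matrices are returned as-is.
    """
    X = expr.values.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return replace(expr, provenance={**expr.provenance, "imputation": "none"})
    empty_rows = mask.all(axis=1)
    if empty_rows.any():
        raise DataError(
            f"gene(s) with no observed value: {list(expr.genes[empty_rows])}"
        )
    empty_cols = mask.all(axis=0)
    if empty_cols.any():
        raise DataError(
            f"sample(s) with no observed value: {list(expr.samples[empty_cols])}"
        )
    row_means = np.nanmean(X, axis=1)
    X[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]
    k = min(n_components, min(X.shape) - 1) if min(X.shape) > 1 else 1
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        center = X.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(X - center, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + center
        delta = np.max(np.abs(recon[mask] - X[mask]))
        X[mask] = recon[mask]
        if delta < tol:
            break
    values = pd.DataFrame(X, index=expr.genes, columns=expr.samples)
    prov = {
        **expr.provenance,
        "imputation": {
            "method": "iterative_pca",
            "n_components": n_components,
            "n_missing": int(mask.sum()),
            "n_iter": n_iter,
            "tol": tol,
        },
    }
    return ExpressionMatrix(values=values, scale=expr.scale,
                            meta=expr.meta, provenance=prov)


def to_neg_dct(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Flip dCt to −dCt so that larger values mean higher expression."""
    if expr.scale != "dCt":
        raise DataError(f"to_neg_dct expects scale 'dCt', got {expr.scale!r}")
    return ExpressionMatrix(
        values=-expr.values,
        scale="neg_dCt",
        meta=expr.meta,
        provenance=dict(expr.provenance),
    )


def preprocess_pipeline(
    ct: CtMatrix,
    max_missing_frac: float = 0.5,
    hk_sd_max: float = 1.5,
    impute_rank: int = 2,
    impute_tol: float = 1e-6,
) -> tuple[ExpressionMatrix, dict[str, Any]]:
    """Run masking, QC, housekeeping validation, dCt and imputation in order.

    Returns the completed dCt matrix and a report dict with the QC table and
    the housekeeping validation table.
    """
    masked = mask_out_of_range(ct)
    passing, qc_report = qc_samples(masked, max_missing_frac=max_missing_frac)
    hk_report = validate_housekeeping(passing, sd_max=hk_sd_max)
    pool = list(hk_report.index[hk_report["retained"]])
    dct = normalize_dct(passing, pool)
    dct = impute_missing(dct, n_components=impute_rank, tol=impute_tol)
    reports = {"qc": qc_report, "housekeeping": hk_report}
    return dct, reports
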