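"""Paired differential expression on normalized qPCR data.

Per gene, the paired difference ddCt = dCt(phase II) − dCt(phase I) is
computed over participants with both phases.  A positive ddCt means more
cycles were needed after supplementation, i.e. the gene went *down*.  The
summary fold change is signed and symmetric around ±1:

    r = 2^(−mean ddCt);   signed FC = r if r ≥ 1 else −1/r

Significance comes from the paired Wilcoxon signed-rank test (exact rank-sum
enumeration for small n without ties, normal approximation with tie and
continuity corrections otherwise) with Bonferroni control over the genes
tested.  A gene is called differentially expressed when |signed FC| exceeds
the fold-change threshold and the adjusted p-value is below alpha.

:class:`PairedExpression` is the model object; :meth:`PairedExpression.fit`
returns a :class:`DEResults` carrying the per-gene table, a text
``summary()``, PCA scores and hierarchical clustering of the −dCt matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import DataError, ExpressionMatrix, to_neg_dct


# --------------------------------------------------------------------------
# Paired design
# --------------------------------------------------------------------------

@dataclass
class PairedDesign:
    """Participant → (phase I sample, phase II sample) plus response class."""

    pairs: pd.DataFrame  # index participant, columns sample_I, sample_II
    response: pd.Series  # participant -> "R" | "NR" (may contain NaN)

    @classmethod
    def from_meta(cls, meta: pd.DataFrame,
                  response: pd.Series | None = None) -> "PairedDesign":
        """Build the design from sample metadata (participant, phase).

        Only participants with both phases present form pairs.  If
        ``response`` is not given it is derived from ``post_25OHD`` metadata
        at the 20 ng/mL threshold when available.
        """
        wide = (
            meta.reset_index(names="sample")
            .pivot(index="participant", columns="phase", values="sample")
        )
        complete = wide.dropna(subset=[c for c in ("I", "II") if c in wide])
        if "I" not in wide.columns or "II" not in wide.columns:
            raise DataError("metadata must contain both phases I and II")
        pairs = complete.rename(columns={"I": "sample_I", "II": "sample_II"})
        if response is None and "post_25OHD" in meta.columns:
            from .cohort import classify_response
            post = meta.groupby("participant")["post_25OHD"].first()
            response = post.map(classify_response)
        if response is None:
            response = pd.Series(index=pairs.index, dtype=object)
        return cls(pairs=pairs[["sample_I", "sample_II"]],
                   response=response.reindex(pairs.index))

    @property
    def participants(self) -> pd.Index:
        return self.pairs.index

    def stratum(self, which: Literal["all", "R", "NR"]) -> "PairedDesign":
        if which == "all":
            return self
        keep = self.response.index[self.response == which]
        keep = keep.intersection(self.pairs.index)
        return PairedDesign(pairs=self.pairs.loc[keep],
                            response=self.response.loc[keep])


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------

def per_pair_ddct(expr: ExpressionMatrix, design: PairedDesign,
                  gene: str) -> np.ndarray:
    """Paired differences dCt_II − dCt_I for one gene, ordered by participant.

    Positive values mean lower expression after supplementation.  Pairs with
    a missing value in either phase are dropped (only relevant when the
    matrix was not imputed).
    """
    if expr.scale != "dCt":
        raise DataError("per_pair_ddct expects a dCt-scale matrix")
    if gene not in expr.values.index:
        raise DataError(f"gene {gene!r} not in expression matrix")
    row = expr.values.loc[gene]
    d = (row[design.pairs["sample_II"]].to_numpy()
         - row[design.pairs["sample_I"]].to_numpy())
    return d[~np.isnan(d)]


def signed_fold_change(ddct: np.ndarray, center: str = "mean") -> float:
    """Signed fold change from paired ddCt values.

    The linear-scale ratio is r = 2^(−centre(ddct)); values below 1 are
    reported as −1/r so magnitudes are symmetric around ±1 (a halving is −2,
    a doubling +2).  ``center`` is "mean" (default, ddCt convention) or
    "median".
    """
    ddct = np.asarray(ddct, dtype=float)
    if ddct.size == 0:
        raise DataError("empty ddCt vector")
    m = np.mean(ddct) if center == "mean" else np.median(ddct)
    r = 2.0 ** (-m)
    return float(r) if r >= 1.0 else float(-1.0 / r)


def _exact_sf_table(n: int) -> np.ndarray:
    """Counts of subsets of {1..n} by rank-sum, via the standard DP."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(
    ddct: np.ndarray, exact_n_max: int = 25
) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped (classic procedure).  |differences| are
    ranked with midranks for ties; W is the sum of ranks of positive
    differences.  For n ≤ ``exact_n_max`` without ties the two-sided p-value
    is computed from the exact null distribution of the rank sum (all 2^n
    sign assignments equally likely); otherwise a normal approximation with
    tie and continuity corrections is used.

    Returns ``(W, p, n_used)``.  An all-zero vector yields p = 1 with a
    warning rather than an error.
    """
    d = np.asarray(ddct, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p set to 1",
                      stacklevel=2)
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size != n
    if n <= exact_n_max and not has_ties:
        counts = _exact_sf_table(n)
        total = 2.0 ** n
        w_int = int(round(W))
        p_le = counts[: w_int + 1].sum() / total
        p_ge = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            return W, 1.0, n
        z = (W - mu - 0.5 * np.sign(W - mu)) / np.sqrt(sigma2)
        # two-sided normal tail via erfc (identical to 2*Phi(-|z|))
        p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return W, float(p), n


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: p_adj = min(1, m·p)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def call_degs(table: pd.DataFrame, fc_threshold: float = 2.0,
              alpha: float = 0.01) -> pd.DataFrame:
    """Flag differentially expressed genes: |signed FC| > threshold and
    adjusted p < alpha."""
    out = table.copy()
    out["called"] = (out["signed_fc"].abs() > fc_threshold) & \
                    (out["p_adj"] < alpha)
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    return out


# --------------------------------------------------------------------------
# Ordination and clustering of the −dCt matrix
# --------------------------------------------------------------------------

def pca_scores(expr: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions from a −dCt matrix.

    Samples are the observations (columns of the matrix); each gene is
    centered across samples before the singular decomposition.  Component
    signs are fixed so the largest-magnitude gene loading is positive.
    """
    if expr.scale != "neg_dCt":
        raise DataError("pca_scores expects a neg_dCt-scale matrix")
    X = expr.values.to_numpy(dtype=float).T  # samples × genes
    if X.shape[0] < 2:
        raise DataError("need at least 2 samples for PCA")
    if np.isnan(X).any():
        raise DataError("PCA requires a complete matrix; impute first")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U * s * flip
    with np.errstate(invalid="ignore", divide="ignore"):
        var_frac = s ** 2 / (s ** 2).sum() if s.sum() > 0 else s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=expr.samples, columns=cols),
            np.asarray(var_frac))


def hierarchical_clustering(
    expr: ExpressionMatrix, axis: Literal["genes", "samples"] = "genes"
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage agglomeration on Euclidean distances.

    Returns the merge tree (scipy linkage matrix: at each step the merged
    pair and the merge height, which for complete linkage is the maximum
    pairwise distance between the joined clusters) and the dendrogram leaf
    order.
    """
    if expr.scale != "neg_dCt":
        raise DataError("hierarchical_clustering expects a neg_dCt matrix")
    X = expr.values if axis == "genes" else expr.values.T
    labels = list(X.index)
    if len(labels) < 2:
        raise DataError("need at least 2 items to cluster")
    if X.isna().any().any():
        raise DataError("clustering requires a complete matrix; impute first")
    Z = hierarchy.linkage(pdist(X.to_numpy(), metric="euclidean"),
                          method="complete")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


# --------------------------------------------------------------------------
# Model / results surface
# --------------------------------------------------------------------------

class PairedExpression:
    """Model object: a complete dCt matrix with its paired design.

    Examples
    --------
    >>> model = PairedExpression(dct, PairedDesign.from_meta(dct.meta))
    >>> res = model.fit()                # all participants
    >>> res_r = model.fit(stratum="R")   # responders only
    >>> print(res.summary())
    """

    def __init__(self, expr: ExpressionMatrix, design: PairedDesign):
        if expr.scale != "dCt":
            raise DataError("PairedExpression expects a dCt matrix")
        self.expr = expr
        self.design = design

    @classmethod
    def from_ct(cls, ct, response: pd.Series | None = None,
                **preprocess_kwargs) -> "PairedExpression":
        """Convenience constructor: preprocess a raw CtMatrix end-to-end."""
        from .preprocess import preprocess_pipeline
        dct, _ = preprocess_pipeline(ct, **preprocess_kwargs)
        return cls(dct, PairedDesign.from_meta(dct.meta, response=response))

    def fit(self, stratum: Literal["all", "R", "NR"] = "all",
            fc_threshold: float = 2.0, alpha: float = 0.01,
            exact_n_max: int = 25, fc_center: str = "mean") -> "DEResults":
        """Run the paired test for every gene in the chosen stratum."""
        design = self.design.stratum(stratum)
        if len(design.pairs) < 2:
            raise DataError(
                f"stratum {stratum!r} has {len(design.pairs)} pair(s); "
                "at least 2 required"
            )
        # one matrix of paired differences, genes × pairs
        diffs = (self.expr.values[design.pairs["sample_II"]].to_numpy()
                 - self.expr.values[design.pairs["sample_I"]].to_numpy())
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero genes flagged via p=1
            for gene, drow in zip(self.expr.genes, diffs):
                d = drow[~np.isnan(drow)]
                if d.size == 0:
                    continue
                W, p, n_used = wilcoxon_signed_rank(d, exact_n_max=exact_n_max)
                rows.append({
                    "gene": gene,
                    "n_pairs": d.size,
                    "mean_ddct": float(np.mean(d)),
                    "signed_fc": signed_fold_change(d, center=fc_center),
                    "W": W,
                    "p": p,
                })
        table = pd.DataFrame(rows).set_index("gene")
        m = len(table)
        table["p_adj"] = bonferroni(table["p"].to_numpy(), m)
        table = call_degs(table, fc_threshold=fc_threshold, alpha=alpha)
        table["log2_ratio"] = -table["mean_ddct"]
        with np.errstate(divide="ignore"):
            table["neg_log10_p_adj"] = -np.log10(table["p_adj"])
        return DEResults(model=self, table=table, stratum=stratum,
                         m_tested=m, fc_threshold=fc_threshold, alpha=alpha,
                         n_pairs=len(design.pairs))


class DEResults:
    """Per-gene paired statistics and calls from one stratum fit."""

    def __init__(self, model: PairedExpression, table: pd.DataFrame,
                 stratum: str, m_tested: int, fc_threshold: float,
                 alpha: float, n_pairs: int):
        self.model = model
        self.table = table
        self.stratum = stratum
        self.m_tested = m_tested
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.n_pairs = n_pairs

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    @property
    def n_called(self) -> int:
        return int(self.table["called"].sum())

    @property
    def nominal_alpha(self) -> float:
        """The nominal per-test threshold equivalent to the adjusted gate."""
        return self.alpha / self.m_tested

    def summary(self, top: int = 10) -> str:
        up = self.called[self.called["signed_fc"] > 0]
        down = self.called[self.called["signed_fc"] < 0]
        lines = [
            "Paired differential expression (Wilcoxon signed-rank)",
            "=" * 56,
            f"stratum:              {self.stratum}",
            f"pairs (participants): {self.n_pairs}",
            f"genes tested (m):     {self.m_tested}",
            f"call criteria:        |FC| > {self.fc_threshold} and "
            f"Bonferroni p < {self.alpha}",
            f"  (nominal p <        {self.nominal_alpha:.3g})",
            f"genes called:         {self.n_called} "
            f"({len(down)} down, {len(up)} up)",
            "",
            f"top genes by |signed FC|:",
        ]
        show = (self.called.reindex(
                    self.called["signed_fc"].abs()
                    .sort_values(ascending=False).index)
                .head(top))
        lines.append(f"{'gene':<12}{'signed_fc':>10}{'W':>9}{'p_adj':>12}")
        for g, row in show.iterrows():
            lines.append(f"{g:<12}{row.signed_fc:>10.2f}{row.W:>9.0f}"
                         f"{row.p_adj:>12.3g}")
        return "\n".join(lines)

    # ---- downstream views -------------------------------------------------

    def pca(self) -> tuple[pd.DataFrame, np.ndarray]:
        return pca_scores(to_neg_dct(self.model.expr))

    def clustering(self, axis: Literal["genes", "samples"] = "genes"):
        return hierarchical_clustering(to_neg_dct(self.model.expr), axis=axis)

    def volcano_frame(self) -> pd.DataFrame:
        """Columns ready for a volcano plot (log2 ratio vs −log10 adj p)."""
        return self.table[["log2_ratio", "neg_log10_p_adj", "called"]].copy()

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano_frame()
        ax.scatter(v["log2_ratio"], v["neg_log10_p_adj"],
                   c=np.where(v["called"], "crimson", "0.4"), s=12)
        ax.axhline(-np.log10(self.alpha), ls="--", c="k", lw=0.8)
        for x in (-np.log2(self.fc_threshold), np.log2(self.fc_threshold)):
            ax.axvline(x, ls="--", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change (−mean ddCt)")
        ax.set_ylabel("−log10 adjusted p")
        return ax


def stratified_dge(expr: ExpressionMatrix, design: PairedDesign,
                   stratum: Literal["all", "R", "NR"] = "all",
                   **fit_kwargs) -> DEResults:
    """Functional wrapper: full pipeline on one stratum's pairs."""
    return PairedExpression(expr, design).fit(stratum=stratum, **fit_kwargs)
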