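"""Panel reduction: from a module repertoire to a targeted assay panel.

The reduction condenses a repertoire of co-expression modules into a panel
small enough for a targeted PCR array while preserving the repertoire's
response diversity:

1. partition the module activity matrix with Hartigan's k-means;
2. drop subgroups that are never *responsive* — no member module reaches at
   least 25% of genes changing in any reference dataset;
3. keep, per retained subgroup, the module closest to the subgroup mean
   vector as its representative;
4. within each representative, rank member genes by distance of their
   profile to the subgroup mean and keep the top four.

With the study geometry (66 retained subgroups, 4 genes each) this yields a
264-gene panel.  :class:`PanelReduction` wraps the steps as a fit-able model;
the free functions implement the individual stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repertoire import ModuleRepertoire

log = logging.getLogger(__name__)


class PanelError(ValueError):
    pass


# --------------------------------------------------------------------------
# Hartigan's k-means
# --------------------------------------------------------------------------

@dataclass
class Partition:
    """A k-means partition of the module activity matrix."""

    K: int
    assignment: pd.Series         # module id -> subgroup label (0..K-1)
    means: np.ndarray             # K × n_datasets subgroup mean vectors
    within_ss: float

    def members(self, subgroup: int) -> list[str]:
        return list(self.assignment.index[self.assignment == subgroup])


def _kmeanspp_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by D^2 sampling."""
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    idx = rng.integers(n)
    centers[0] = X[idx]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, K):
        total = d2.sum()
        if total <= 0:  # fewer distinct points than K: fall back to random
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _hartigan_pass(X, labels, centers, counts) -> int:
    """One sweep of single-point reassignments; returns number of moves.

    Moving point x from cluster c (size n_c) to d (size n_d) changes the
    within-cluster sum of squares by
    n_d/(n_d+1)·‖x−μ_d‖² − n_c/(n_c−1)·‖x−μ_c‖²; the move is taken when the
    best destination strictly decreases the objective.
    """
    n, _ = X.shape
    moves = 0
    for i in range(n):
        c = labels[i]
        if counts[c] <= 1:
            continue
        x = X[i]
        removal_gain = counts[c] / (counts[c] - 1) * ((x - centers[c]) ** 2).sum()
        add_costs = (counts / (counts + 1.0)) * ((centers - x) ** 2).sum(axis=1)
        add_costs[c] = np.inf
        d = int(np.argmin(add_costs))
        if add_costs[d] < removal_gain - 1e-12:
            centers[c] = (centers[c] * counts[c] - x) / (counts[c] - 1)
            centers[d] = (centers[d] * counts[d] + x) / (counts[d] + 1)
            counts[c] -= 1
            counts[d] += 1
            labels[i] = d
            moves += 1
    return moves


def hartigan_kmeans(
    activity: pd.DataFrame,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_sweeps: int = 200,
) -> Partition:
    """Partition modules with Hartigan's k-means (single-point updates).

    Each restart seeds centers with k-means++, assigns points to the nearest
    center, then applies Hartigan reassignment sweeps to convergence.  The
    restart with the lowest total within-subgroup sum of squares wins.
    Deterministic for a fixed seed.
    """
    if len(activity) == 0:
        raise PanelError("empty repertoire")
    if not (1 <= K <= len(activity)):
        raise PanelError(f"K={K} outside [1, {len(activity)}]")
    if activity.isna().any().any():
        raise PanelError("activity matrix contains missing values")
    X = activity.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        centers = _kmeanspp_init(X, K, rng)
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # recompute centers from the initial assignment; empty clusters get
        # re-seeded on points far from their center (only from clusters that
        # can spare a point)
        counts = np.bincount(labels, minlength=K).astype(float)
        nearest = d2.min(axis=1)
        while (counts == 0).any():
            j = int(np.flatnonzero(counts == 0)[0])
            donors = np.flatnonzero(counts[labels] > 1)
            far = donors[int(np.argmax(nearest[donors]))]
            counts[labels[far]] -= 1
            labels[far] = j
            counts[j] += 1
            nearest[far] = 0.0
        centers = np.vstack([X[labels == j].mean(axis=0) for j in range(K)])
        for _sweep in range(max_sweeps):
            if _hartigan_pass(X, labels, centers, counts) == 0:
                break
        wss = float(((X - centers[labels]) ** 2).sum())
        if best is None or wss < best[0] - 1e-12:
            best = (wss, labels.copy(), centers.copy())
    wss, labels, centers = best
    assignment = pd.Series(labels, index=activity.index, name="subgroup")
    # exact means from final labels (incremental updates accumulate fp error)
    means = np.vstack([X[labels == j].mean(axis=0) if (labels == j).any()
                       else centers[j] for j in range(K)])
    wss = float(((X - means[labels]) ** 2).sum())
    return Partition(K=K, assignment=assignment, means=means, within_ss=wss)


def elbow_scan(
    activity: pd.DataFrame,
    k_values: list[int],
    n_restarts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-SS as a function of K, to eyeball a knee when K is unknown."""
    rows = []
    for k in k_values:
        part = hartigan_kmeans(activity, K=k, n_restarts=n_restarts, seed=seed)
        rows.append({"K": k, "within_ss": part.within_ss})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Retention, representatives, gene ranking
# --------------------------------------------------------------------------

def retain_subgroups(
    partition: Partition,
    repertoire: ModuleRepertoire,
    threshold: float = 25.0,
) -> list[int]:
    """Subgroups that contain at least one responsive module.

    A subgroup is retained iff some member module, in some reference dataset,
    has at least ``threshold`` percent of its genes up- or down-regulated
    (|activity| ≥ threshold, inclusive).
    """
    retained = []
    for j in range(partition.K):
        members = partition.members(j)
        if not members:
            continue
        if repertoire.activity.loc[members].abs().to_numpy().max() >= threshold:
            retained.append(j)
    if not retained:
        log.warning("retain_subgroups: no subgroup passes |activity| >= %g",
                    threshold)
    return retained


def select_representative(
    members: list[str], activity: pd.DataFrame
) -> tuple[str, np.ndarray]:
    """The member module closest (Euclidean) to the subgroup mean vector.

    Ties break to the lexicographically smallest module id.  Returns the
    module id and the subgroup mean vector.
    """
    if not members:
        raise PanelError("empty subgroup")
    sub = activity.loc[sorted(members)]
    mean_vec = sub.mean(axis=0).to_numpy()
    dists = np.sqrt(((sub.to_numpy() - mean_vec) ** 2).sum(axis=1))
    best = int(np.argmin(dists))  # argmin takes first minimum = smallest id
    return sub.index[best], mean_vec


def rank_and_pick_genes(
    module: str,
    repertoire: ModuleRepertoire,
    mean_vec: np.ndarray,
    n_pick: int = 4,
    order: str = "closest",
) -> pd.DataFrame:
    """Rank a representative module's genes against the subgroup mean vector.

    Genes are ordered by Euclidean distance of their profile to the subgroup
    mean — ascending for ``order="closest"`` (most representative first, the
    default) or descending for ``order="extreme"``.  Ties break by gene
    symbol.  Returns the full ranking with a ``selected`` flag on the first
    min(n_pick, module size) rows.
    """
    genes = repertoire.genes_of(module)
    missing = [g for g in genes if g not in repertoire.gene_profiles.index]
    if missing:
        raise PanelError(f"gene profile missing for {missing[0]!r}")
    profiles = repertoire.gene_profiles.loc[genes]
    dists = np.sqrt(((profiles.to_numpy() - mean_vec) ** 2).sum(axis=1))
    frame = pd.DataFrame({"gene": genes, "distance": dists})
    ascending = order == "closest"
    if order not in ("closest", "extreme"):
        raise PanelError(f"unknown ranking order {order!r}")
    frame = frame.sort_values(
        ["distance", "gene"], ascending=[ascending, True]
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    n_sel = min(n_pick, len(frame))
    if len(frame) < n_pick:
        log.warning("module %s has only %d genes (< %d requested)",
                    module, len(frame), n_pick)
    frame["selected"] = frame["rank"] <= n_sel
    frame.insert(0, "module", module)
    return frame


# --------------------------------------------------------------------------
# The assembled panel
# --------------------------------------------------------------------------

@dataclass
class ReducedPanel:
    """A reduced targeted panel: selected genes plus provenance.

    ``table`` has one row per selected gene with columns
    (subgroup, module, gene, rank, distance, promoted).
    """

    table: pd.DataFrame
    housekeeping: list[str]
    params: dict = field(default_factory=dict)

    @property
    def target_genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def representatives(self) -> list[str]:
        return list(self.table["module"].unique())

    @property
    def n_target_genes(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        if self.table["gene"].duplicated().any():
            raise PanelError("duplicate gene symbols in panel")
        overlap = set(self.target_genes) & set(self.housekeeping)
        if overlap:
            raise PanelError(f"housekeeping symbols overlap targets: {overlap}")


def generic_panel(n_target_genes: int, n_housekeeping: int) -> ReducedPanel:
    """A placeholder panel with synthetic symbols, for simulation-only runs."""
    genes = [f"G{i:05d}" for i in range(1, n_target_genes + 1)]
    table = pd.DataFrame({
        "subgroup": np.repeat(np.arange((n_target_genes + 3) // 4), 4)[:n_target_genes],
        "module": ["M%04d" % (i // 4 + 1) for i in range(n_target_genes)],
        "gene": genes,
        "rank": (np.arange(n_target_genes) % 4) + 1,
        "distance": 0.0,
        "promoted": False,
    })
    hk = [f"HK{i}" for i in range(1, n_housekeeping + 1)]
    return ReducedPanel(table=table, housekeeping=hk, params={"synthetic": True})


def build_panel(
    repertoire: ModuleRepertoire,
    K: int,
    threshold: float = 25.0,
    n_pick: int = 4,
    housekeeping: list[str] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    order: str = "closest",
) -> ReducedPanel:
    """Run the full reduction and assemble the panel.

    Gene symbols must be unique across the panel; when a top-ranked gene was
    already claimed by an earlier representative, the next-ranked gene of the
    current module is promoted in its place (flagged ``promoted``).
    """
    housekeeping = list(housekeeping or [])
    clash = set(housekeeping) & set(repertoire.gene_profiles.index)
    if clash:
        raise PanelError(f"housekeeping genes overlap repertoire targets: {clash}")
    partition = hartigan_kmeans(repertoire.activity, K=K,
                                n_restarts=n_restarts, seed=seed)
    retained = retain_subgroups(partition, repertoire, threshold=threshold)
    if not retained:
        raise PanelError("no responsive subgroups retained")
    seen: set[str] = set()
    rows = []
    for j in retained:
        members = partition.members(j)
        rep, mean_vec = select_representative(members, repertoire.activity)
        ranking = rank_and_pick_genes(rep, repertoire, mean_vec,
                                      n_pick=n_pick, order=order)
        picked = 0
        want = min(n_pick, len(ranking))
        for row in ranking.itertuples():
            if picked >= want:
                break
            if row.gene in seen:
                continue
            rows.append({
                "subgroup": j,
                "module": rep,
                "gene": row.gene,
                "rank": row.rank,
                "distance": row.distance,
                "promoted": row.rank > want,
            })
            seen.add(row.gene)
            picked += 1
    table = pd.DataFrame(rows)
    panel = ReducedPanel(
        table=table,
        housekeeping=housekeeping,
        params={"K": K, "threshold": threshold, "n_pick": n_pick,
                "n_restarts": n_restarts, "seed": seed, "order": order,
                "within_ss": partition.within_ss,
                "n_retained": len(retained)},
    )
    panel.validate()
    return panel


# --------------------------------------------------------------------------
# Model / results surface
# --------------------------------------------------------------------------

class PanelReduction:
    """Model object: a repertoire awaiting reduction.

    Examples
    --------
    >>> model = PanelReduction(repertoire)
    >>> res = model.fit(K=66, seed=0)
    >>> res.panel.n_target_genes
    264
    """

    def __init__(self, repertoire: ModuleRepertoire,
                 housekeeping: list[str] | None = None):
        self.repertoire = repertoire
        self.housekeeping = list(housekeeping or [])

    def elbow(self, k_values, n_restarts: int = 5, seed: int = 0) -> pd.DataFrame:
        return elbow_scan(self.repertoire.activity, list(k_values),
                          n_restarts=n_restarts, seed=seed)

    def fit(self, K: int = 66, threshold: float = 25.0, n_pick: int = 4,
            n_restarts: int = 10, seed: int = 0,
            order: str = "closest") -> "PanelResults":
        panel = build_panel(
            self.repertoire, K=K, threshold=threshold, n_pick=n_pick,
            housekeeping=self.housekeeping, n_restarts=n_restarts,
            seed=seed, order=order,
        )
        return PanelResults(model=self, panel=panel)


class PanelResults:
    """Fit results: the reduced panel plus a summary view."""

    def __init__(self, model: PanelReduction, panel: ReducedPanel):
        self.model = model
        self.panel = panel

    @property
    def n_target_genes(self) -> int:
        return self.panel.n_target_genes

    @property
    def n_representatives(self) -> int:
        return len(self.panel.representatives)

    def summary(self) -> str:
        p = self.panel.params
        lines = [
            "Panel reduction results",
            "=" * 43,
            f"subgroups (K):        {p.get('K')}",
            f"retained subgroups:   {p.get('n_retained')}",
            f"representatives:      {self.n_representatives}",
            f"target genes:         {self.n_target_genes}",
            f"housekeeping genes:   {len(self.panel.housekeeping)}",
            f"retention threshold:  |activity| >= {p.get('threshold')}%",
            f"genes per module:     <= {p.get('n_pick')}"
            f" ({p.get('order')}-first ranking)",
            f"within-subgroup SS:   {p.get('within_ss', float('nan')):.2f}",
        ]
        n_promoted = int(self.panel.table["promoted"].sum())
        if n_promoted:
            lines.append(f"promoted genes:       {n_promoted} (duplicate symbols)")
        return "\n".join(lines)
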