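"""Synthetic data with known ground truth, mirroring the study design.

Two generators are provided:

* :func:`gen_repertoire` builds a module repertoire whose modules fall into
  well-separated planted subgroups, so that the panel-reduction stages can be
  tested against known labels.
* :func:`gen_cohort_levels` + :func:`gen_ct_matrix` build a paired
  pre/post-supplementation cohort: serum 25(OH)D trajectories with a
  responder/non-responder mixture, and a Ct matrix with planted
  differentially expressed genes, censoring beyond the detectable range,
  random dropout and optional failing samples.

Everything is driven by a :class:`numpy.random.Generator` seeded from the
config, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig, ConfigError, RepertoireConfig
from .panel import ReducedPanel
from .preprocess import CtMatrix
from .repertoire import ModuleRepertoire

SUN_CATEGORIES = ("<1h", "1-2h", ">2h")


@dataclass
class RepertoireTruth:
    """Planted structure behind a synthetic repertoire."""

    subgroup_of_module: pd.Series      # module id -> planted subgroup index
    responsive_subgroups: list[int]    # subgroups passing the retention rule
    centroids: np.ndarray              # n_subgroups × n_datasets


@dataclass
class CohortTruth:
    """Planted structure behind a synthetic Ct matrix.

    ``ddct_shift`` is the true phase-II dCt shift per gene: positive for
    down-regulated genes (later cycles after supplementation = less
    transcript), negative for up-regulated genes, zero for nulls.
    """

    ddct_shift: pd.Series
    direction: pd.Series               # "down" | "up" | "null" per gene
    true_fc: pd.Series                 # signed fold change implied by the shift
    failing_samples: list[str] = field(default_factory=list)
    missing_mask: pd.DataFrame | None = None
    response: pd.Series | None = None  # participant -> "R" | "NR"


def _truncnorm(rng: np.random.Generator, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


# --------------------------------------------------------------------------
# Repertoire generator
# --------------------------------------------------------------------------

def gen_repertoire(
    config: RepertoireConfig,
) -> tuple[ModuleRepertoire, RepertoireTruth]:
    """Simulate a module repertoire with planted, separable subgroups.

    Subgroup centroids are drawn i.i.d. Gaussian with per-coordinate scale
    ``separation`` (in 16 dimensions this puts typical centroid pairs
    ``separation * sqrt(2 * n_datasets)`` apart, far above the within-subgroup
    spread for the defaults).  Responsive subgroups get one coordinate forced
    to a large magnitude so they clear the 25% retention rule; non-responsive
    ones are squashed below it.  Module activity = centroid + noise; gene
    profiles = module activity + noise, all clipped to ±100.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, D = config.n_subgroups_planted, config.n_datasets

    centroids = rng.normal(0.0, config.separation, size=(S, D))
    n_responsive = int(round(config.responsive_fraction * S))
    responsive = list(range(n_responsive))
    for s in range(S):
        if s in responsive:
            j = rng.integers(D)
            sign = rng.choice([-1.0, 1.0])
            centroids[s, j] = sign * rng.uniform(40.0, 90.0)
        else:
            # keep every coordinate safely under the 25% rule
            centroids[s] = np.clip(centroids[s], -15.0, 15.0)
    centroids = np.clip(centroids, -100.0, 100.0)

    module_ids = [f"M{i:04d}" for i in range(1, config.n_modules + 1)]
    subgroup_of_module = pd.Series(
        [i % S for i in range(config.n_modules)], index=module_ids,
        name="subgroup",
    )
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_modules, D)) if config.noise_sd > 0 else 0.0
    activity = np.clip(centroids[subgroup_of_module.to_numpy()] + noise,
                       -100.0, 100.0)
    activity = pd.DataFrame(activity, index=module_ids,
                            columns=[f"D{j + 1}" for j in range(D)])

    membership: dict[str, list[str]] = {}
    profile_rows = []
    gene_ids = []
    counter = 1
    sizes = rng.integers(config.genes_per_module_min,
                         config.genes_per_module_max + 1,
                         size=config.n_modules)
    for m, size in zip(module_ids, sizes):
        genes = [f"G{counter + i:05d}" for i in range(size)]
        counter += size
        membership[m] = genes
        base = activity.loc[m].to_numpy()
        gnoise = (rng.normal(0.0, config.noise_sd, size=(size, D))
                  if config.noise_sd > 0 else np.zeros((size, D)))
        profile_rows.append(np.clip(base + gnoise, -100.0, 100.0))
        gene_ids.extend(genes)
    gene_profiles = pd.DataFrame(np.vstack(profile_rows), index=gene_ids,
                                 columns=activity.columns)

    repertoire = ModuleRepertoire(membership=membership, activity=activity,
                                  gene_profiles=gene_profiles)
    truth = RepertoireTruth(subgroup_of_module=subgroup_of_module,
                            responsive_subgroups=responsive,
                            centroids=centroids)
    return repertoire, truth


# --------------------------------------------------------------------------
# Cohort generators
# --------------------------------------------------------------------------

def gen_cohort_levels(config: CohortConfig) -> pd.DataFrame:
    """Simulate per-participant serum 25(OH)D trajectories and covariates.

    Pre-supplementation levels come from a truncated normal within the
    deficient range; post levels are a responder/non-responder mixture with
    the configured counts.  The highest non-responder is pinned at
    19.36 ng/mL, emulating the one participant who landed just under the
    20 ng/mL response threshold.  Age, BMI and sun-exposure covariates are
    generated for cohort summaries only — they do not feed the expression
    model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_r = config.n_responders
    n_nr = n - n_r

    pre = _truncnorm(rng, config.pre_level_params.mean,
                     config.pre_level_params.sd,
                     config.pre_level_params.low,
                     config.pre_level_params.high, n)
    post = np.empty(n)
    response = np.array(["R"] * n, dtype=object)
    nr_idx = rng.choice(n, size=n_nr, replace=False) if n_nr else np.array([], int)
    response[nr_idx] = "NR"
    r_idx = np.flatnonzero(response == "R")
    lp = config.post_level_params_r
    post[r_idx] = _truncnorm(rng, lp.mean, lp.sd, lp.low, lp.high, len(r_idx))
    if n_nr:
        lp = config.post_level_params_nr
        post[nr_idx] = _truncnorm(rng, lp.mean, lp.sd, lp.low, lp.high, n_nr)
        top = nr_idx[int(np.argmax(post[nr_idx]))]
        post[top] = 19.36

    table = pd.DataFrame({
        "participant": [f"P{i:03d}" for i in range(1, n + 1)],
        "age": rng.integers(17, 29, size=n),
        "bmi": np.clip(rng.normal(24.39, 3.5, size=n), 16.0, 38.0).round(2),
        "sun_exposure": rng.choice(SUN_CATEGORIES, size=n,
                                   p=[0.775, 0.15, 0.075]),
        "pre_25OHD": np.round(pre, 2),
        "post_25OHD": np.round(post, 2),
        "response": response,
    }).set_index("participant")
    return table


def gen_ct_matrix(
    panel: ReducedPanel,
    cohort: pd.DataFrame,
    config: CohortConfig,
) -> tuple[CtMatrix, CohortTruth]:
    """Simulate a raw Ct matrix for a panel run on a paired cohort.

    The Ct model is additive on the cycle (log2 expression) scale::

        Ct(g, s) = hk_baseline_mean + offset(s) + baseline_dCt(g)
                   + shift(g) * [phase(s) == II] + noise

    Down-regulated genes get shift = +log2(FC) (more cycles needed after
    supplementation), the up-regulated gene shift = −log2(FC).  Per-assay
    measurement noise has sd ``pair_noise_sd / sqrt(2)`` so paired dCt
    differences have sd ``pair_noise_sd``.  Values above ``detect_max_ct``
    are censored to missing; independent dropout and whole-sample failures
    add further missingness.
    """
    config.validate()
    targets = panel.target_genes
    if len(targets) != config.n_target_genes:
        raise ConfigError(
            f"panel has {len(targets)} target genes, config expects "
            f"{config.n_target_genes}"
        )
    if len(panel.housekeeping) != config.n_housekeeping:
        raise ConfigError(
            f"panel has {len(panel.housekeeping)} housekeeping genes, config "
            f"expects {config.n_housekeeping}"
        )
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)

    participants = list(cohort.index)
    samples = [f"{p}_{ph}" for p in participants for ph in ("I", "II")]
    meta = pd.DataFrame({
        "sample": samples,
        "participant": np.repeat(participants, 2),
        "phase": ["I", "II"] * len(participants),
    }).set_index("sample")
    meta["pre_25OHD"] = cohort.loc[meta["participant"], "pre_25OHD"].to_numpy()
    meta["post_25OHD"] = cohort.loc[meta["participant"], "post_25OHD"].to_numpy()

    # planted effects
    planted = rng.choice(len(targets),
                         size=config.n_down_planted + config.n_up_planted,
                         replace=False)
    down = planted[:config.n_down_planted]
    up = planted[config.n_down_planted:]
    shift = np.zeros(len(targets))
    fcs = rng.uniform(config.planted_fc_low, config.planted_fc_high,
                      size=config.n_down_planted)
    shift[down] = np.log2(fcs)
    shift[up] = -np.log2(config.up_fc)
    direction = np.array(["null"] * len(targets), dtype=object)
    direction[down] = "down"
    direction[up] = "up"
    true_fc = np.where(shift == 0, 1.0,
                       np.where(shift > 0, -(2.0 ** shift), 2.0 ** (-shift)))

    hk_base = rng.uniform(18.0, 20.0, size=config.n_housekeeping)
    base_dct = rng.uniform(config.baseline_dct_low, config.baseline_dct_high,
                           size=len(targets))
    offsets = rng.normal(0.0, config.sample_offset_sd, size=len(samples))
    phase2 = (meta["phase"] == "II").to_numpy()

    meas_sd = config.pair_noise_sd / np.sqrt(2.0)
    target_ct = (
        hk_base.mean()
        + offsets[None, :]
        + base_dct[:, None]
        + np.outer(shift, phase2.astype(float))
        + rng.normal(0.0, meas_sd, size=(len(targets), len(samples)))
    )
    hk_ct = (
        hk_base[:, None]
        + offsets[None, :]
        + rng.normal(0.0, config.hk_sd,
                     size=(config.n_housekeeping, len(samples)))
    )
    values = pd.DataFrame(
        np.vstack([target_ct, hk_ct]),
        index=list(targets) + list(panel.housekeeping),
        columns=samples,
    )

    censored = values > config.detect_max_ct
    dropout = pd.DataFrame(
        rng.random(values.shape) < config.missing_rate,
        index=values.index, columns=values.columns,
    )
    failing: list[str] = []
    failure_mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    if config.n_failing_samples:
        failing = list(rng.choice(samples, size=config.n_failing_samples,
                                  replace=False))
        for s in failing:
            failure_mask[s] = rng.random(len(values)) < 0.85
    missing = censored | dropout | failure_mask
    values = values.mask(missing)

    ct = CtMatrix(
        values=values,
        is_housekeeping=pd.Series(
            [False] * len(targets) + [True] * len(panel.housekeeping),
            index=values.index,
        ),
        meta=meta,
        detect_max_ct=config.detect_max_ct,
    )
    truth = CohortTruth(
        ddct_shift=pd.Series(shift, index=list(targets), name="ddct_shift"),
        direction=pd.Series(direction, index=list(targets), name="direction"),
        true_fc=pd.Series(true_fc, index=list(targets), name="true_fc"),
        failing_samples=failing,
        missing_mask=missing,
        response=cohort["response"].copy(),
    )
    return ct, truth


def simulate_study(
    config: CohortConfig,
    panel: ReducedPanel | None = None,
) -> tuple[CtMatrix, CohortTruth, pd.DataFrame]:
    """Cohort levels + Ct matrix in one call; fabricates a generic panel
    when none is supplied (symbols only, for simulation-driven tests)."""
    from .panel import generic_panel

    if panel is None:
        panel = generic_panel(config.n_target_genes, config.n_housekeeping)
    cohort = gen_cohort_levels(config)
    ct, truth = gen_ct_matrix(panel, cohort, config)
    return ct, truth, cohort
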