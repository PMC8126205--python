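"""Shared fixtures: small synthetic datasets with known ground truth.

Everything is generated programmatically at collection time; the heavier
study-geometry fixtures are session-scoped so the suite builds them once.
"""

import numpy as np
import pandas as pd
import pytest

import tfakit as tk


@pytest.fixture(scope="session")
def study_repertoire():
    cfg = tk.repertoire_config("study", seed=42)
    repertoire, truth = tk.gen_repertoire(cfg)
    return repertoire, truth


@pytest.fixture(scope="session")
def study_run():
    """Study-default cohort simulated, preprocessed and fitted once."""
    cfg = tk.cohort_config("study", seed=42)
    ct, truth, cohort = tk.simulate_study(cfg)
    dct, reports = tk.preprocess_pipeline(ct)
    design = tk.PairedDesign.from_meta(dct.meta)
    model = tk.PairedExpression(dct, design)
    results = model.fit()
    return {
        "config": cfg, "ct": ct, "truth": truth, "cohort": cohort,
        "dct": dct, "reports": reports, "design": design,
        "model": model, "results": results,
    }


@pytest.fixture
def small_ct():
    """A tiny handcrafted Ct matrix: 3 targets + 2 housekeeping, 2 pairs."""
    samples = ["P1_I", "P1_II", "P2_I", "P2_II"]
    values = pd.DataFrame(
        [
            [25.0, 26.0, 24.0, 25.0],   # TA: down-regulated (dCt +1 in II)
            [20.0, 20.0, 20.0, 20.0],   # TB: flat
            [22.0, 21.0, 22.0, 21.0],   # TC: up-regulated
            [20.0, 20.0, 20.0, 20.0],   # HK1
            [20.0, 20.0, 20.0, 20.0],   # HK2
        ],
        index=["TA", "TB", "TC", "HK1", "HK2"],
        columns=samples,
    )
    meta = pd.DataFrame({
        "participant": ["P1", "P1", "P2", "P2"],
        "phase": ["I", "II", "I", "II"],
        "post_25OHD": [30.0, 30.0, 15.0, 15.0],
    }, index=pd.Index(samples, name="sample"))
    hk = pd.Series([False, False, False, True, True], index=values.index)
    return tk.CtMatrix(values=values, is_housekeeping=hk, meta=meta,
                       detect_max_ct=28.0)


def toy_repertoire(activity_rows, memberships, profiles=None):
    """Build a toy repertoire from explicit matrices (helper for panel tests)."""
    activity = pd.DataFrame(
        activity_rows, dtype=float,
    )
    activity.index = list(memberships)
    if profiles is None:
        rows, index = [], []
        for m, genes in memberships.items():
            for g in genes:
                rows.append(activity.loc[m].to_numpy())
                index.append(g)
        profiles = pd.DataFrame(rows, index=index, columns=activity.columns)
    return tk.ModuleRepertoire(membership=memberships, activity=activity,
                               gene_profiles=profiles)
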