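"""Shared fixtures: synthetic cohorts at desk scale.

The full-size cohort fixtures are session-scoped because generating,
preprocessing and differential-testing a 20,000-probe cohort once is enough
for every test that needs the study-design-scale data.
"""

import numpy as np
import pandas as pd
import pytest

from methinv import (
    CohortSpec,
    SelectionConfig,
    assign_labels,
    fit_moderated_t,
    generate_cohort,
    intersect_sites,
    m_value_frame,
    preprocess,
    sam_permutation,
    select_sites,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    beta, sheet, truth = generate_cohort(default_spec)
    return beta, sheet, truth


@pytest.fixture(scope="session")
def labeled_cohort(default_cohort):
    """Preprocessed default cohort with its distance-derived labels."""
    beta, sheet, truth = default_cohort
    pp = preprocess(beta)
    assignment = assign_labels(pp, sheet)
    return pp, sheet, truth, assignment


@pytest.fixture(scope="session")
def diffmeth_sites(labeled_cohort):
    """Intersected (EB & SAM) significant sites for both contrasts, plus the
    M-value frame and per-contrast sample groupings."""
    pp, sheet, truth, assignment = labeled_cohort
    labels = assignment.labels
    mv = m_value_frame(pp)
    cfg = SelectionConfig(seed=COHORT_SEED)
    out = {}
    for contrast in ("tumor_normal", "invasive_noninvasive"):
        if contrast == "tumor_normal":
            keep = labels[labels.isin(["invasive", "noninvasive", "normal"])]
            groups = keep.replace({"invasive": "tumor", "noninvasive": "tumor"})
        else:
            keep = labels[labels.isin(["invasive", "noninvasive"])]
            groups = keep
        sub = mv.loc[:, keep.index]
        eb, _ = fit_moderated_t(sub, groups.to_numpy())
        sam = sam_permutation(sub, groups.to_numpy(), cfg)
        overlap = intersect_sites(select_sites(eb, cfg), select_sites(sam.table, cfg))
        out[contrast] = {
            "samples": keep.index,
            "groups": groups,
            "eb": eb,
            "sam": sam.table,
            "sites": overlap,
        }
    return mv, out


@pytest.fixture
def small_spec():
    """A cohort small enough for fast structural tests; the labeling margin
    must be rescaled (~3 units) because distances shrink with probe count."""
    return CohortSpec(
        n_probes=1500,
        n_pairs=8,
        n_outlier_pairs=2,
        n_noninvasive=6,
        n_normal=10,
        n_extra_noncg=10,
        seed=7,
    )


@pytest.fixture
def toy_beta():
    rng = np.random.default_rng(0)
    vals = rng.random((12, 6))
    from methinv import BetaMatrix

    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:04d}" for i in range(12)],
            columns=[f"s{j}" for j in range(6)],
        )
    )
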