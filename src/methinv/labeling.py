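"""Genome-wide methylation-distance pseudo-labeling of primary tumors.

Matched primary/metastasis pairs anchor the invasive class: a primary whose
lesion has already seeded a regional lymph-node metastasis is invasive by
definition.  Pairs at aberrant within-pair distance (upper Tukey fence on the
pair-distance distribution) are discarded.  An unpaired primary is called
noninvasive when its minimum Euclidean distance to the retained metastasis
profiles exceeds the maximum retained within-pair distance by more than a
margin (default 10 distance units on the genome-wide beta scale); everything
else stays unlabeled and is excluded from training.  Normals come from the
sample sheet only, never from the distance rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

LABELS = ("invasive", "noninvasive", "normal", "unlabeled")


@dataclass
class LabelingConfig:
    """margin: distance units a candidate must exceed the paired maximum by;
    fence_multiplier: Tukey-fence IQR multiplier for pair-outlier removal."""

    margin: float = 10.0
    fence_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.fence_multiplier < 0:
            raise ValueError("fence_multiplier must be >= 0")


@dataclass
class LabelAssignment:
    """Per-sample label plus the distance evidence behind each candidate call."""

    labels: pd.Series  # sample_id -> one of LABELS
    provenance: pd.DataFrame  # per candidate: dmin, threshold
    retained_pairs: pd.DataFrame  # pair_id, primary, metastasis, distance
    removed_pairs: pd.DataFrame

    def with_label(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def euclidean_distance(a, b) -> float:
    """Plain Euclidean distance between two same-length sample vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def compute_pair_distances(m: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """One Euclidean distance per matched primary/metastasis pair.

    Returns a table (pair_id, primary_sample_id, metastasis_sample_id,
    distance) sorted by pair_id.
    """
    pairs = sheet.pairs()
    missing = [
        s
        for s in pd.concat([pairs["primary"], pairs["metastasis"]])
        if s not in m.sample_ids
    ]
    if missing:
        raise ValueError(f"pair members absent from matrix: {missing[:5]}")
    rows = []
    for _, r in pairs.iterrows():
        d = euclidean_distance(m.data[r["primary"]], m.data[r["metastasis"]])
        rows.append((r["pair_id"], r["primary"], r["metastasis"], d))
    return pd.DataFrame(
        rows, columns=["pair_id", "primary_sample_id", "metastasis_sample_id", "distance"]
    )


def filter_pairs_by_quartile(
    table: pd.DataFrame, cfg: LabelingConfig | None = None
) -> pd.DataFrame:
    """Drop pairs above the upper Tukey fence Q3 + multiplier * IQR.

    Quartiles use linear interpolation (numpy default, type 7).  Requires at
    least 4 pairs for the quartiles to be meaningful.
    """
    cfg = cfg or LabelingConfig()
    if len(table) < 4:
        raise ValueError(f"need >= 4 pairs for the quartile filter, got {len(table)}")
    d = table["distance"].to_numpy()
    q1, q3 = np.quantile(d, [0.25, 0.75])
    fence = q3 + cfg.fence_multiplier * (q3 - q1)
    keep = d <= fence
    logger.info(
        "quartile pair filter: fence=%.4g, removed %d / %d pairs",
        fence, int((~keep).sum()), len(table),
    )
    return table[keep].reset_index(drop=True)


def label_noninvasive(
    candidates: BetaMatrix,
    metastases: BetaMatrix,
    paired: pd.DataFrame,
    cfg: LabelingConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Apply the margin rule to unpaired primary candidates.

    A candidate is noninvasive iff its minimum distance to the metastasis
    profiles strictly exceeds max(paired distance) + margin.  Returns the
    candidate labels ('noninvasive'/'unlabeled') and a provenance table
    (dmin, threshold).
    """
    cfg = cfg or LabelingConfig()
    if metastases.n_samples == 0:
        raise ValueError("no metastasis samples to measure distances against")
    if len(paired) == 0:
        raise ValueError("empty pair-distance table")
    shared = candidates.probe_ids.intersection(metastases.probe_ids)
    if len(shared) < len(candidates.probe_ids):
        logger.info("margin rule: using %d shared probes", len(shared))
    c = candidates.data.loc[shared].to_numpy()
    x = metastases.data.loc[shared].to_numpy()
    if np.isnan(c).any() or np.isnan(x).any():
        raise ValueError("margin rule requires imputed (complete) matrices")
    # (n_candidates, n_metastases) pairwise distances over the probe axis
    d2 = (
        np.sum(c**2, axis=0)[:, None]
        + np.sum(x**2, axis=0)[None, :]
        - 2.0 * c.T @ x
    )
    dmin = np.sqrt(np.maximum(d2, 0.0)).min(axis=1)
    threshold = float(paired["distance"].max()) + cfg.margin
    labels = pd.Series(
        np.where(dmin > threshold, "noninvasive", "unlabeled"),
        index=candidates.sample_ids,
        name="label",
    )
    prov = pd.DataFrame(
        {"dmin": dmin, "threshold": threshold}, index=candidates.sample_ids
    )
    return labels, prov


def assign_labels(
    m: BetaMatrix, sheet: SampleSheet, cfg: LabelingConfig | None = None
) -> LabelAssignment:
    """Full pseudo-labeling flow on a preprocessed cohort.

    Pair distances -> quartile filter -> retained-pair primaries labeled
    invasive -> margin rule on unpaired primaries -> sheet normals.
    """
    cfg = cfg or LabelingConfig()
    dist = compute_pair_distances(m, sheet)
    retained = filter_pairs_by_quartile(dist, cfg)
    removed = dist[~dist["pair_id"].isin(retained["pair_id"])].reset_index(drop=True)

    labels = pd.Series("unlabeled", index=sheet.sample_ids, name="label", dtype=object)
    labels[sheet.samples_with_role("normal")] = "normal"
    labels[retained["primary_sample_id"].to_numpy()] = "invasive"

    paired_samples = set(dist["primary_sample_id"]) | set(dist["metastasis_sample_id"])
    cand_ids = [
        s
        for s in sheet.samples_with_role("primary")
        if s not in paired_samples and s in m.sample_ids
    ]
    prov = pd.DataFrame(columns=["dmin", "threshold"])
    if cand_ids:
        mets = m.select_samples(retained["metastasis_sample_id"])
        cand_labels, prov = label_noninvasive(m.select_samples(cand_ids), mets, retained, cfg)
        labels[cand_labels.index] = cand_labels
    counts = labels.value_counts().to_dict()
    logger.info("labeling: %s (pairs retained %d, removed %d)", counts, len(retained), len(removed))
    return LabelAssignment(labels=labels, provenance=prov, retained_pairs=retained, removed_pairs=removed)


def write_labels(assignment: LabelAssignment, path) -> None:
    out = pd.DataFrame({"label": assignment.labels})
    out = out.join(assignment.provenance)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
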