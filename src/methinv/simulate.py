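"""Synthetic methylation cohorts with ground-truth manifests.

The generator emulates the statistical structure every pipeline stage
assumes: a bimodal (hypo/hyper-methylated) landscape of probe means; matched
primary/metastasis pairs sharing a latent per-pair profile; a noninvasive
tumor subgroup pushed away from the metastases by independent per-probe
jitter; planted differentially methylated CpG sets for the tumor-vs-normal
and invasive-vs-noninvasive contrasts; a handful of aberrant pairs with
inflated within-pair dispersion (quartile-filter fodder); missing entries;
SNP/CpH decoy probes; and clinical indicators enriched in the invasive
group.

Beta values are drawn from Beta distributions parameterized by (mean,
precision): value ~ Beta(mean * precision, (1 - mean) * precision).  Pair
sharing splits the within-group precision into a between-pair and a
within-pair component controlled by ``pair_correlation``.

Defaults mirror the target study design at desk scale: 20,000 probes
(not the full 393,806-probe array), 40 clean pairs + 4 outlier pairs, 20
noninvasive and 40 normal samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, SampleSheet

DEFAULT_INDICATORS: dict[str, tuple[float, float]] = {
    # indicator -> (P(present | invasive), P(present | noninvasive))
    "T3": (0.6, 0.1),
    "N3": (0.6, 0.1),
    "HER2": (0.5, 0.1),
    "LN": (0.6, 0.2),
}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_probes: int = 20_000
    n_pairs: int = 40
    n_outlier_pairs: int = 4
    n_noninvasive: int = 20
    n_normal: int = 40
    frac_dm_tumor_normal: float = 0.05
    delta_beta_tn: float = 0.3
    frac_dm_invasive_noninvasive: float = 0.05
    delta_beta_in: float = 0.3
    pair_correlation: float = 0.75
    noninvasive_distance_offset: float = 0.08
    outlier_pair_dispersion: float = 16.0
    missing_rate: float = 0.002
    precision: float = 50.0
    indicator_probabilities: dict = field(default_factory=lambda: dict(DEFAULT_INDICATORS))
    indicator_missing_rate: float = 0.05
    n_extra_noncg: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dm_tumor_normal", "frac_dm_invasive_noninvasive",
                     "pair_correlation", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.delta_beta_tn < 0.9 and 0 < self.delta_beta_in < 0.9):
            raise ValueError("delta_beta values must keep group means inside (0, 1)")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if min(self.n_probes, self.n_pairs, self.n_normal) < 1:
            raise ValueError("cohort dimensions must be positive")


@dataclass
class TruthManifest:
    """Planted ground truth: DM probe sets, true sample labels, outlier pairs."""

    dm_tumor_normal: list[str]
    dm_invasive_noninvasive: list[str]
    sample_labels: dict[str, str]
    outlier_pairs: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


class _CohortModel:
    """Deterministic latent model shared by training and test cohorts."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        p = spec.n_probes
        # bimodal methylation landscape: hypo- and hyper-methylated peaks
        hypo = rng.beta(1.5, 8.0, size=p)
        hyper = rng.beta(8.0, 1.5, size=p)
        mu = np.where(rng.random(p) < 0.5, hypo, hyper)
        self.mu = np.clip(mu, 0.05, 0.95)
        self.probe_ids = np.array([f"cg{i:07d}" for i in range(p)])

        n_tn = int(round(spec.frac_dm_tumor_normal * p))
        n_in = int(round(spec.frac_dm_invasive_noninvasive * p))
        perm = rng.permutation(p)
        self.tn_idx = np.sort(perm[:n_tn])
        self.in_idx = np.sort(perm[n_tn : n_tn + n_in])

        # shift toward whichever side has room, keeping means inside (0, 1)
        def shifted(base, idx, delta):
            out = base.copy()
            direction = np.where(base[idx] < 0.5, 1.0, -1.0)
            out[idx] = np.clip(base[idx] + direction * delta, 0.02, 0.98)
            return out

        self.mean_normal = self.mu
        tumor_base = shifted(self.mu, self.tn_idx, spec.delta_beta_tn)
        self.mean_noninvasive = tumor_base
        self.mean_invasive = shifted(tumor_base, self.in_idx, spec.delta_beta_in)

    def sample_beta(self, rng, mean: np.ndarray, precision: float) -> np.ndarray:
        m = np.clip(mean, 0.01, 0.99)
        return rng.beta(m * precision, (1.0 - m) * precision)

    def draw_pair(self, rng, outlier: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Matched primary/metastasis sharing a latent pair profile."""
        s = self.spec
        w = min(max(s.pair_correlation, 1e-6), 1 - 1e-6)
        prec_between = s.precision / w
        prec_within = s.precision / (1.0 - w)
        if outlier:
            prec_within /= s.outlier_pair_dispersion
        theta = self.sample_beta(rng, self.mean_invasive, prec_between)
        primary = self.sample_beta(rng, theta, prec_within)
        metastasis = self.sample_beta(rng, theta, prec_within)
        return primary, metastasis

    def draw_noninvasive(self, rng) -> np.ndarray:
        s = self.spec
        jitter = rng.normal(0.0, s.noninvasive_distance_offset, size=s.n_probes)
        return self.sample_beta(rng, self.mean_noninvasive + jitter, s.precision)

    def draw_invasive_unpaired(self, rng) -> np.ndarray:
        return self.sample_beta(rng, self.mean_invasive, self.spec.precision)

    def draw_normal(self, rng) -> np.ndarray:
        return self.sample_beta(rng, self.mean_normal, self.spec.precision)

    def draw_indicators(self, rng, true_label: str) -> dict[str, float]:
        s = self.spec
        out: dict[str, float] = {}
        for name, (p_inv, p_non) in s.indicator_probabilities.items():
            if true_label == "invasive":
                p = p_inv
            elif true_label == "noninvasive":
                p = p_non
            else:
                out[name] = np.nan
                continue
            if rng.random() < s.indicator_missing_rate:
                out[name] = np.nan
            else:
                out[name] = float(rng.random() < p)
        return out


def _extra_noncg(rng, n_extra: int, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    ids = []
    for i in range(n_extra):
        prefix = "rs" if i % 2 == 0 else "ch"
        ids.append(f"{prefix}{i:07d}")
    vals = rng.random((n_extra, n_samples))
    return np.array(ids), vals


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, SampleSheet, TruthManifest]:
    """Training cohort: matched pairs (+ outlier pairs), noninvasive, normals."""
    model = _CohortModel(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    rows_sheet: list[dict] = []
    labels: dict[str, str] = {}
    outlier_pairs: list[str] = []

    total_pairs = spec.n_pairs + spec.n_outlier_pairs
    outlier_set = set(range(spec.n_pairs, total_pairs))
    for i in range(total_pairs):
        is_out = i in outlier_set
        pid = f"pair{i:03d}"
        prim, met = model.draw_pair(rng, outlier=is_out)
        for sid, role, vec in (
            (f"P{i:03d}", "primary", prim),
            (f"M{i:03d}", "metastasis", met),
        ):
            sample_ids.append(sid)
            cols.append(vec)
            ind = model.draw_indicators(rng, "invasive" if role == "primary" else "other")
            rows_sheet.append({"sample_id": sid, "role": role, "pair_id": pid, **ind})
            labels[sid] = "invasive" if role == "primary" else "metastasis"
        if is_out:
            outlier_pairs.append(pid)
    for i in range(spec.n_noninvasive):
        sid = f"N{i:03d}"
        sample_ids.append(sid)
        cols.append(model.draw_noninvasive(rng))
        ind = model.draw_indicators(rng, "noninvasive")
        rows_sheet.append({"sample_id": sid, "role": "primary", "pair_id": np.nan, **ind})
        labels[sid] = "noninvasive"
    for i in range(spec.n_normal):
        sid = f"H{i:03d}"
        sample_ids.append(sid)
        cols.append(model.draw_normal(rng))
        ind = model.draw_indicators(rng, "normal")
        rows_sheet.append({"sample_id": sid, "role": "normal", "pair_id": np.nan, **ind})
        labels[sid] = "normal"

    values = np.column_stack(cols)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    probe_ids = model.probe_ids
    if spec.n_extra_noncg > 0:
        extra_ids, extra_vals = _extra_noncg(rng, spec.n_extra_noncg, values.shape[1])
        probe_ids = np.concatenate([probe_ids, extra_ids])
        values = np.vstack([values, extra_vals])

    beta = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(rows_sheet).set_index("sample_id"))
    truth = TruthManifest(
        dm_tumor_normal=model.probe_ids[model.tn_idx].tolist(),
        dm_invasive_noninvasive=model.probe_ids[model.in_idx].tolist(),
        sample_labels=labels,
        outlier_pairs=outlier_pairs,
    )
    return beta, sheet, truth


def generate_test_cohort(
    spec: CohortSpec,
    n_invasive: int = 70,
    n_noninvasive: int = 30,
    n_normal: int = 20,
    seed: int | None = None,
) -> tuple[BetaMatrix, SampleSheet, pd.Series]:
    """Held-out cohort drawn from the same latent model as the training cohort.

    Unpaired primaries (invasive or noninvasive, without matched metastases)
    plus normals; returns the true labels for generator-truth comparisons.
    """
    model = _CohortModel(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed if seed is None else seed, 2)))
    cols, sample_ids, rows_sheet, truth = [], [], [], {}
    for i in range(n_invasive):
        sid = f"TI{i:03d}"
        sample_ids.append(sid)
        cols.append(model.draw_invasive_unpaired(rng))
        ind = model.draw_indicators(rng, "invasive")
        rows_sheet.append({"sample_id": sid, "role": "primary", "pair_id": np.nan, **ind})
        truth[sid] = "invasive"
    for i in range(n_noninvasive):
        sid = f"TN{i:03d}"
        sample_ids.append(sid)
        cols.append(model.draw_noninvasive(rng))
        ind = model.draw_indicators(rng, "noninvasive")
        rows_sheet.append({"sample_id": sid, "role": "primary", "pair_id": np.nan, **ind})
        truth[sid] = "noninvasive"
    for i in range(n_normal):
        sid = f"TH{i:03d}"
        sample_ids.append(sid)
        cols.append(model.draw_normal(rng))
        ind = model.draw_indicators(rng, "normal")
        rows_sheet.append({"sample_id": sid, "role": "normal", "pair_id": np.nan, **ind})
        truth[sid] = "normal"
    values = np.column_stack(cols)
    beta = BetaMatrix(pd.DataFrame(values, index=model.probe_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(rows_sheet).set_index("sample_id"))
    return beta, sheet, pd.Series(truth, name="true_label")
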