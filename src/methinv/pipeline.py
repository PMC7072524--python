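"""End-to-end orchestration: simulate/read -> preprocess -> label -> test ->
reduce -> classify -> predict -> enrich, with per-stage artifacts.

Every stage writes self-describing TSV/JSON outputs into its own directory
under the run directory, all randomness derives from the single config seed,
and a hash of the canonical config is recorded so artifacts can be matched to
the run that produced them.  A stage failure raises :class:`StageError`
naming the stage; earlier artifacts are left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffmeth, enrichment, labeling, matrix, model, reduce as feature_reduce, simulate

logger = logging.getLogger(__name__)

CONTRASTS = ("tumor_normal", "invasive_noninvasive")
DEFAULT_METHODS = ("mrmd", "mrmr", "pca", "fa")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "methinv_run"
    seed: int = 0
    # inputs: either simulate a cohort or read flat files
    simulate: bool = True
    cohort: simulate.CohortSpec | None = None
    beta_path: str | None = None
    sheet_path: str | None = None
    # held-out cohort for prediction + enrichment
    predict: bool = True
    test_beta_path: str | None = None
    test_sheet_path: str | None = None
    test_n_invasive: int = 70
    test_n_noninvasive: int = 30
    test_n_normal: int = 20
    preprocess: matrix.PreprocessConfig = field(default_factory=matrix.PreprocessConfig)
    labeling: labeling.LabelingConfig = field(default_factory=labeling.LabelingConfig)
    selection: diffmeth.SelectionConfig = field(default_factory=diffmeth.SelectionConfig)
    reduction_methods: tuple[str, ...] = DEFAULT_METHODS
    max_subset: int = 20
    mrmr_bins: int = 3
    pca_variance_threshold: float = 0.95
    n_trees: int = 500
    cv_folds: int = 10
    indicators: tuple[str, ...] | None = None
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.simulate and self.cohort is None:
            self.cohort = simulate.CohortSpec(seed=self.seed)
        if self.selection.seed != self.seed:
            self.selection = dataclasses.replace(self.selection, seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = simulate.CohortSpec(**d["cohort"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = matrix.PreprocessConfig(**d["preprocess"])
        if "labeling" in d and isinstance(d["labeling"], dict):
            d["labeling"] = labeling.LabelingConfig(**d["labeling"])
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = diffmeth.SelectionConfig(**d["selection"])
        for key in ("reduction_methods", "indicators"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_canonical_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            raise TypeError(type(obj))

        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # artifact location is not part of the run identity
        return json.dumps(d, sort_keys=True, default=enc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", **kw)


@dataclass
class PipelineResult:
    outdir: Path
    labels: pd.Series
    sites: dict[str, pd.Index]
    feature_sets: dict[tuple[str, str], feature_reduce.FeatureSet]
    cv_reports: dict[tuple[str, str], model.CVReport]
    test_counts: dict[str, dict]
    enrichments: dict[str, pd.DataFrame]
    summary: pd.DataFrame


def load_bundle(run_dir, method: str) -> model.ClassifierBundle:
    """Rebuild a run's two-stage classifier from its persisted artifacts.

    Forests are retrained deterministically from the stored training designs
    and the run seed, so the reloaded bundle predicts identically to the one
    used inside the run.
    """
    run_dir = Path(run_dir)
    cfgd = json.loads((run_dir / "run_config.json").read_text())
    models = {}
    features = {}
    for contrast in CONTRASTS:
        fs = feature_reduce.FeatureSet.from_json(run_dir / "reduce" / f"{method}_{contrast}.json")
        design = pd.read_csv(run_dir / "train" / f"design_{method}_{contrast}.tsv", sep="\t", index_col=0)
        y = design.pop("group").to_numpy()
        models[contrast] = model.train_rf(
            design.to_numpy(), y, n_trees=cfgd["n_trees"], seed=cfgd["seed"]
        )
        features[contrast] = fs
    return model.ClassifierBundle(
        model_normal=models["tumor_normal"],
        features_normal=features["tumor_normal"],
        model_invasive=models["invasive_noninvasive"],
        features_invasive=features["invasive_noninvasive"],
        n_trees=cfgd["n_trees"],
        seed=cfgd["seed"],
        epsilon=cfgd["epsilon"],
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "run_config.json").write_text(cfg.to_canonical_json())
    logger.info("run %s seed=%d config_hash=%s", out, cfg.seed, chash)

    # ---- inputs --------------------------------------------------------
    stage = "simulate" if cfg.simulate else "read"
    try:
        if cfg.simulate:
            spec = dataclasses.replace(cfg.cohort, seed=cfg.seed)
            beta, sheet, truth = simulate.generate_cohort(spec)
            sdir = out / "simulate"
            sdir.mkdir(exist_ok=True)
            matrix.write_sample_sheet(sheet, sdir / "sample_sheet.tsv")
            truth.to_json(sdir / "truth.json")
        else:
            beta = matrix.read_beta_matrix(cfg.beta_path)
            sheet = matrix.read_sample_sheet(cfg.sheet_path)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    # ---- preprocess ----------------------------------------------------
    try:
        pp = matrix.preprocess(beta, cfg.preprocess)
        pdir = out / "preprocess"
        pdir.mkdir(exist_ok=True)
        (pdir / "stats.json").write_text(json.dumps({
            "config_hash": chash,
            "probes_in": beta.n_probes,
            "probes_out": pp.n_probes,
            "samples": pp.n_samples,
            "missing_imputed": beta.n_missing(),
        }, sort_keys=True))
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", str(e)) from e

    # ---- labeling ------------------------------------------------------
    try:
        assignment = labeling.assign_labels(pp, sheet, cfg.labeling)
        ldir = out / "label"
        ldir.mkdir(exist_ok=True)
        labeling.write_labels(assignment, ldir / "labels.tsv")
        _write_tsv(assignment.retained_pairs, ldir / "pairs_retained.tsv", index=False)
        _write_tsv(assignment.removed_pairs, ldir / "pairs_removed.tsv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("label", str(e)) from e
    labels = assignment.labels

    # ---- differential methylation (both engines, both contrasts) -------
    ddir = out / "diffmeth"
    ddir.mkdir(exist_ok=True)
    mv = diffmeth.m_value_frame(pp, cfg.epsilon)
    sites: dict[str, pd.Index] = {}
    contrast_samples: dict[str, tuple[pd.Index, pd.Series]] = {}
    # validate both contrasts up front so a degenerate labeling halts
    # before any engine runs
    for contrast in CONTRASTS:
        if contrast == "tumor_normal":
            keep = labels[labels.isin(["invasive", "noninvasive", "normal"])]
            groups = keep.replace({"invasive": "tumor", "noninvasive": "tumor"})
        else:
            keep = labels[labels.isin(["invasive", "noninvasive"])]
            groups = keep
        lv = groups.unique()
        if len(lv) < 2:
            raise StageError(
                "diffmeth",
                f"contrast {contrast!r} has a single class {sorted(lv)}; "
                "cannot test differential methylation",
            )
        contrast_samples[contrast] = (keep.index, groups)
    for contrast in CONTRASTS:
        idx, groups = contrast_samples[contrast]
        sub = mv.loc[:, idx]
        try:
            eb_table, hyper = diffmeth.fit_moderated_t(sub, groups.to_numpy(), robust=True)
            eb_table = diffmeth.add_passed(eb_table, cfg.selection)
            sam = diffmeth.sam_permutation(sub, groups.to_numpy(), cfg.selection)
            sam_table = diffmeth.add_passed(sam.table, cfg.selection)
            eb_sites = diffmeth.select_sites(eb_table, cfg.selection)
            sam_sites = diffmeth.select_sites(sam_table, cfg.selection)
            overlap = diffmeth.intersect_sites(eb_sites, sam_sites)
            if len(overlap) == 0:
                raise ValueError(f"no overlapping significant sites for {contrast}")
            sites[contrast] = overlap
            _write_tsv(eb_table, ddir / f"eb_{contrast}.tsv", index_label="probe_id")
            _write_tsv(sam_table, ddir / f"sam_{contrast}.tsv", index_label="probe_id")
            (ddir / f"sites_{contrast}.txt").write_text("\n".join(overlap) + "\n")
            (ddir / f"stats_{contrast}.json").write_text(json.dumps({
                "config_hash": chash,
                "eb_sites": len(eb_sites),
                "sam_sites": len(sam_sites),
                "overlap": len(overlap),
                "eb_d0": hyper.d0,
                "eb_s0_sq": hyper.s0_sq,
                "sam_s0": sam.s0_sam,
                "sam_permutations": sam.M,
            }, sort_keys=True))
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("diffmeth", f"{contrast}: {e}") from e

    # ---- reduction + cross-validated forests ---------------------------
    rdir = out / "reduce"
    rdir.mkdir(exist_ok=True)
    tdir = out / "train"
    tdir.mkdir(exist_ok=True)
    feature_sets: dict[tuple[str, str], feature_reduce.FeatureSet] = {}
    cv_reports: dict[tuple[str, str], model.CVReport] = {}
    for method in cfg.reduction_methods:
        for contrast in CONTRASTS:
            idx, groups = contrast_samples[contrast]
            x = mv.loc[sites[contrast], idx].T  # samples x probes
            y = groups.to_numpy()
            try:
                kw: dict = {}
                if method in ("mrmd", "mrmr"):
                    kw = {"max_subset": cfg.max_subset, "cv": cfg.cv_folds, "random_state": cfg.seed}
                    if method == "mrmr":
                        kw["n_bins"] = cfg.mrmr_bins
                elif method == "pca":
                    kw = {"variance_threshold": cfg.pca_variance_threshold}
                elif method == "fa":
                    kw = {"variance_threshold": cfg.pca_variance_threshold}
                reducer = feature_reduce.make_reducer(method, **kw)
                reducer.fit(x, y)
                fs = reducer.as_feature_set()
                feature_sets[(method, contrast)] = fs
                fs.to_json(rdir / f"{method}_{contrast}.json")
                xt = fs.transform(x)
                design = pd.DataFrame(xt, index=idx)
                design.insert(0, "group", y)
                # default float repr round-trips exactly, so a reloaded
                # bundle retrains on bit-identical designs
                design.to_csv(tdir / f"design_{method}_{contrast}.tsv", sep="\t", index_label="sample_id")
                rep = model.cross_validate_model(xt, y, k=cfg.cv_folds, seed=cfg.seed, n_trees=cfg.n_trees)
                cv_reports[(method, contrast)] = rep
            except Exception as e:  # noqa: BLE001
                raise StageError("reduce", f"{method}/{contrast}: {e}") from e

    # ---- prediction on the held-out cohort + enrichment ----------------
    test_counts: dict[str, dict] = {}
    enrichments: dict[str, pd.DataFrame] = {}
    if cfg.predict:
        try:
            if cfg.test_beta_path:
                tbeta = matrix.read_beta_matrix(cfg.test_beta_path)
                tsheet = matrix.read_sample_sheet(cfg.test_sheet_path)
            else:
                spec = dataclasses.replace(cfg.cohort, seed=cfg.seed)
                tbeta, tsheet, _ = simulate.generate_test_cohort(
                    spec, cfg.test_n_invasive, cfg.test_n_noninvasive, cfg.test_n_normal
                )
                tbeta = matrix.preprocess(tbeta, cfg.preprocess)
        except Exception as e:  # noqa: BLE001
            raise StageError("predict", str(e)) from e
        pdir2 = out / "predict"
        pdir2.mkdir(exist_ok=True)
        edir = out / "enrich"
        edir.mkdir(exist_ok=True)
        for method in cfg.reduction_methods:
            try:
                bundle = model.fit_bundle(
                    mv,
                    labels,
                    feature_sets[(method, "tumor_normal")],
                    feature_sets[(method, "invasive_noninvasive")],
                    n_trees=cfg.n_trees,
                    seed=cfg.seed,
                    epsilon=cfg.epsilon,
                )
                calls, counts = bundle.predict_cohort(tbeta)
                test_counts[method] = counts
                _write_tsv(calls, pdir2 / f"calls_{method}.tsv", index_label="sample_id")
            except Exception as e:  # noqa: BLE001
                raise StageError("predict", f"{method}: {e}") from e
            try:
                enr = enrichment.enrich_indicators(
                    calls["call"],
                    tsheet,
                    list(cfg.indicators) if cfg.indicators else None,
                )
                enrichments[method] = enr
                _write_tsv(enr, edir / f"enrichment_{method}.tsv", index=False)
            except Exception as e:  # noqa: BLE001
                raise StageError("enrich", f"{method}: {e}") from e

    # ---- summary --------------------------------------------------------
    rows = []
    for method in cfg.reduction_methods:
        for contrast in CONTRASTS:
            fs = feature_sets[(method, contrast)]
            rep = cv_reports[(method, contrast)]
            counts = test_counts.get(method, {})
            rows.append({
                "method": method,
                "contrast": contrast,
                "n_sites_input": len(sites[contrast]),
                "n_features": fs.n_features,
                "cv_accuracy": rep.mean_accuracy,
                **{f"test_{k}": v for k, v in counts.items()},
            })
    summary = pd.DataFrame(rows)
    _write_tsv(summary, out / "summary.tsv", index=False)
    return PipelineResult(
        outdir=out,
        labels=labels,
        sites=sites,
        feature_sets=feature_sets,
        cv_reports=cv_reports,
        test_counts=test_counts,
        enrichments=enrichments,
        summary=summary,
    )
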