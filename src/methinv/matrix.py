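"""Beta-value matrices, sample sheets, and array preprocessing.

The universal data carrier is a probes x samples matrix of methylation beta
values (proportion methylated, in [0, 1], NaN = missing), as exported from
HM450-style array pipelines.  Preprocessing follows the usual chain for such
data: drop non-CpG probe classes (SNP ``rs`` and CpH ``ch`` probes), drop
probes with excessive missingness, then impute the remaining gaps from the
k nearest probes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("primary", "metastasis", "normal")

#: tokens treated as missing in flat-file inputs ("", "NA", "NaN", any case)
NA_TOKENS = sorted(
    {""}
    | {"".join(c) for c in itertools.product(*zip("na".upper(), "na"))}
    | {"".join(c) for c in itertools.product(*zip("nan".upper(), "nan"))}
)


class FormatError(ValueError):
    """Malformed flat-file input (duplicates, non-numeric or out-of-range cells)."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1]; NaN marks missing.

    Wraps a :class:`pandas.DataFrame` with probe ids on the index and sample
    ids on the columns.  Construction validates uniqueness of both axes and
    the [0, 1] range of every non-missing value.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if 0 in df.shape:
            self.data = df.astype(float)
            return
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise FormatError("non-numeric cells in beta matrix")
        self.data = df.astype(float)
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                bad = vals[(vals < 0) | (vals > 1)]
                raise FormatError(f"beta values outside [0, 1], e.g. {bad.flat[0]}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def select_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(sample_ids)])

    def select_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probe_ids)])


@dataclass
class SampleSheet:
    """Per-sample role, pair id and clinical indicators.

    ``data`` is indexed by sample id with a ``role`` column in
    {primary, metastasis, normal}, an optional ``pair_id`` column (shared by
    exactly one primary and one metastasis), and any number of indicator
    columns coded 1 (present) / 0 (absent) / NaN (unknown).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in sample sheet")
        if "role" not in df.columns:
            raise FormatError("sample sheet lacks a 'role' column")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise FormatError(f"unknown roles {sorted(bad)}; expected {ROLES}")
        if "pair_id" in df.columns:
            paired = df[df["pair_id"].notna() & (df["pair_id"] != "")]
            for pid, grp in paired.groupby("pair_id"):
                roles = sorted(grp["role"])
                if roles != ["metastasis", "primary"]:
                    raise FormatError(
                        f"pair {pid!r} must have exactly one primary and one "
                        f"metastasis, got roles {roles}"
                    )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def roles(self) -> pd.Series:
        return self.data["role"]

    @property
    def indicator_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("role", "pair_id")]

    def samples_with_role(self, role: str) -> pd.Index:
        return self.data.index[self.data["role"] == role]

    def pairs(self) -> pd.DataFrame:
        """One row per matched pair: pair_id, primary, metastasis."""
        if "pair_id" not in self.data.columns:
            return pd.DataFrame(columns=["pair_id", "primary", "metastasis"])
        paired = self.data[self.data["pair_id"].notna() & (self.data["pair_id"] != "")]
        rows = []
        for pid, grp in paired.groupby("pair_id", sort=True):
            prim = grp.index[grp["role"] == "primary"][0]
            met = grp.index[grp["role"] == "metastasis"][0]
            rows.append((pid, prim, met))
        return pd.DataFrame(rows, columns=["pair_id", "primary", "metastasis"])

    def indicator_status(self, name: str) -> pd.Series:
        """1/0/NaN status of one indicator, indexed by sample id."""
        if name not in self.data.columns:
            raise KeyError(f"indicator {name!r} not in sample sheet")
        return pd.to_numeric(self.data[name], errors="coerce")


@dataclass
class PreprocessConfig:
    """Preprocessing knobs: probe-class filter, missingness cutoff, KNN k."""

    max_na_fraction: float = 0.30
    knn_k: int = 10
    drop_probe_prefixes: tuple[str, ...] = ("rs", "ch")

    def __post_init__(self) -> None:
        if not 0 < self.max_na_fraction < 1:
            raise ValueError("max_na_fraction must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def _sep_for(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_beta_matrix(path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes-in-rows flat table of beta values.

    First column = probe ids, header row = sample ids; empty cells, ``NA``
    and ``NaN`` (any case) denote missing.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path, dialect),
        index_col=0,
        na_values=NA_TOKENS,
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.shape[0] == 0:
        return BetaMatrix(df.astype(float))
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric cell(s) in column {col!r}: {bad.head(3).tolist()}"
            )
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path, dialect: str | None = None) -> None:
    m.data.to_csv(path, sep=_sep_for(path, dialect), na_rep="NA")


def read_sample_sheet(path, dialect: str | None = None) -> SampleSheet:
    df = pd.read_csv(
        path,
        sep=_sep_for(path, dialect),
        na_values=NA_TOKENS,
        keep_default_na=False,
        dtype={"sample_id": str},
    )
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet lacks a 'sample_id' column")
    df = df.set_index("sample_id")
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].astype("object")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, dialect: str | None = None) -> None:
    sheet.data.to_csv(path, sep=_sep_for(path, dialect), na_rep="NA", index_label="sample_id")


def filter_probe_classes(m: BetaMatrix, cfg: PreprocessConfig | None = None) -> BetaMatrix:
    """Keep CpG (``cg``) probes only; SNP/CpH/unknown probe classes are dropped."""
    cfg = cfg or PreprocessConfig()
    if m.n_probes == 0:
        return m
    keep = m.probe_ids.astype(str).str.startswith("cg")
    dropped = m.probe_ids[~keep]
    if len(dropped):
        by_class: dict[str, int] = {}
        for pid in dropped:
            by_class[pid[:2]] = by_class.get(pid[:2], 0) + 1
        logger.info("filter_probe_classes: dropped %d probes %s", len(dropped), by_class)
    return BetaMatrix(m.data.loc[keep])


def filter_missingness(m: BetaMatrix, cfg: PreprocessConfig | None = None) -> BetaMatrix:
    """Drop probes whose missing fraction strictly exceeds ``max_na_fraction``."""
    cfg = cfg or PreprocessConfig()
    if m.n_samples == 0:
        return m
    frac = m.data.isna().mean(axis=1)
    keep = frac <= cfg.max_na_fraction
    logger.info("filter_missingness: dropped %d / %d probes", int((~keep).sum()), m.n_probes)
    return BetaMatrix(m.data.loc[keep])


def _masked_sq_distances(targets: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances over mutually observed columns.

    ``targets``: (t, s) rows with NaN; ``x``: (n, s) all rows.  Returns (t, n)
    with +inf where two rows share no observed column.
    """
    ot = (~np.isnan(targets)).astype(float)
    zt = np.nan_to_num(targets)
    ox = (~np.isnan(x)).astype(float)
    zx = np.nan_to_num(x)
    # sum over mutually observed s of (a_s - b_s)^2, expanded; zeros elsewhere
    d2 = (zt**2) @ ox.T + ot @ (zx**2).T - 2.0 * zt @ zx.T
    shared = ot @ ox.T
    d2 = np.where(shared > 0, np.maximum(d2, 0.0), np.inf)
    return d2


def knn_impute(m: BetaMatrix, cfg: PreprocessConfig | None = None) -> BetaMatrix:
    """Impute each missing entry from the k nearest probes.

    Distance between probe rows is the plain Euclidean distance over their
    mutually observed samples (the target entry's own column is missing for
    the target, hence never contributes).  The imputed value is the unweighted
    mean of the k nearest donor probes that are observed in that sample,
    clipped to [0, 1].
    """
    cfg = cfg or PreprocessConfig()
    vals = m.values.copy()
    n, s = vals.shape
    miss = np.isnan(vals)
    if not miss.any():
        return m
    observed_per_row = (~miss).sum(axis=1)
    if np.any(observed_per_row == 0):
        bad = m.probe_ids[observed_per_row == 0].tolist()
        raise ValueError(f"probe rows with no observed values: {bad[:5]}")
    target_idx = np.flatnonzero(miss.any(axis=1))
    out = vals.copy()
    chunk = max(1, int(2e7) // max(n, 1))  # keep distance blocks ~160 MB max
    for start in range(0, len(target_idx), chunk):
        block = target_idx[start : start + chunk]
        d2 = _masked_sq_distances(vals[block], vals)
        d2[np.arange(len(block)), block] = np.inf  # never self
        for bi, i in enumerate(block):
            drow = d2[bi]
            for j in np.flatnonzero(miss[i]):
                cand = drow.copy()
                cand[miss[:, j]] = np.inf  # donors must be observed in column j
                k = min(cfg.knn_k, int(np.isfinite(cand).sum()))
                if k == 0:
                    raise ValueError(
                        f"no finite-distance donor for probe {m.probe_ids[i]!r} "
                        f"sample {m.sample_ids[j]!r}"
                    )
                nearest = np.argpartition(cand, k - 1)[:k]
                out[i, j] = float(np.clip(vals[nearest, j].mean(), 0.0, 1.0))
    return BetaMatrix(pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids))


def preprocess(m: BetaMatrix, cfg: PreprocessConfig | None = None) -> BetaMatrix:
    """Full chain: probe-class filter -> missingness filter -> KNN imputation."""
    cfg = cfg or PreprocessConfig()
    out = knn_impute(filter_missingness(filter_probe_classes(m, cfg), cfg), cfg)
    logger.info("preprocess: %d -> %d probes, %d samples", m.n_probes, out.n_probes, out.n_samples)
    return out
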