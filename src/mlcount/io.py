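"""Dataset reading, design-matrix construction and pipeline configuration.

Input is a long-format CSV, one row per mother: a cluster (enumeration
area) column, a nonnegative integer outcome column, and covariate columns.
Categorical covariates are expanded to reference-coded indicators with the
first listed category as the reference; continuous covariates pass through
uncentered by default (optional centering) so count-part coefficients keep
their per-unit rate-ratio interpretation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ModelData, TermInfo

log = logging.getLogger("mlcount")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Input data violates the pipeline contract."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``categories`` optionally pins the level order per categorical
    covariate (first = reference); unlisted categoricals use order of first
    appearance.  ``count_covariates`` / ``zero_covariates`` may differ, as
    the two model parts need not share covariates.
    """

    input: str | None = None
    cluster_col: str = "cluster"
    outcome_col: str = "y"
    count_covariates: list = field(default_factory=list)
    zero_covariates: list = field(default_factory=list)
    families: list = field(default_factory=lambda: ["ZIP", "ZINB", "PH", "NBH"])
    categories: dict = field(default_factory=dict)
    center_continuous: bool = False
    quad_points: int = 15
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        bad = [f for f in self.families if f not in ("ZIP", "ZINB", "PH", "NBH")]
        if bad:
            raise ConfigError(f"unknown families: {bad}")
        if not self.outcome_col or not self.cluster_col:
            raise ConfigError("outcome and cluster columns are mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(f"bad configuration keys in {path}: {e}") from e

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "cluster_col": self.cluster_col,
            "outcome_col": self.outcome_col,
            "count_covariates": list(self.count_covariates),
            "zero_covariates": list(self.zero_covariates),
            "families": list(self.families),
            "categories": {k: list(v) for k, v in self.categories.items()},
            "center_continuous": self.center_continuous,
            "quad_points": self.quad_points,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def read_dataset(path, config: PipelineConfig) -> pd.DataFrame:
    """Read and validate the mother-level CSV.

    Rows with a missing outcome or cluster are dropped with a logged count;
    the outcome must be nonnegative integer.
    """
    df = pd.read_csv(path)
    needed = [config.cluster_col, config.outcome_col]
    needed += [c for c in set(config.count_covariates) | set(config.zero_covariates)]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"missing mandatory columns: {missing}")
    n0 = len(df)
    df = df.dropna(subset=[config.cluster_col, config.outcome_col])
    dropped = n0 - len(df)
    if dropped:
        log.warning("dropped %d rows with missing outcome or cluster", dropped)
    if len(df) == 0:
        raise DataError("no usable rows after dropping missing outcome/cluster")
    y = df[config.outcome_col].to_numpy()
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise DataError(f"outcome column {config.outcome_col!r} must be "
                        "nonnegative integers")
    df = df.copy()
    df[config.outcome_col] = y.astype(np.int64)
    return df.reset_index(drop=True)


def build_design(df: pd.DataFrame, covariates, categories: dict | None = None,
                 center_continuous: bool = False):
    """Intercept-plus-covariates design matrix with reference coding.

    Returns (matrix, column names, term infos).  Categoricals (object /
    categorical dtype, or listed in ``categories``) expand to indicator
    columns for every non-reference level, named ``var=level``; the first
    listed (or first observed) level is the reference.  Columns with zero
    variance after expansion are dropped with a warning.
    """
    categories = categories or {}
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    terms = []
    for var in covariates:
        s = df[var]
        is_cat = var in categories or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype)
        if is_cat:
            levels = list(categories.get(var, pd.unique(s.astype(str))))
            seen = set(pd.unique(s.astype(str)))
            unknown = seen - set(map(str, levels))
            if unknown:
                raise DataError(f"unknown category level(s) {sorted(unknown)} "
                                f"for covariate {var!r}")
            ref = str(levels[0])
            term_cols = []
            for lev in map(str, levels[1:]):
                col = (s.astype(str) == lev).astype(float).to_numpy()
                name = f"{var}={lev}"
                if col.std() == 0:
                    log.warning("dropping zero-variance design column %s", name)
                    continue
                cols.append(col)
                names.append(name)
                term_cols.append(name)
            terms.append(TermInfo(var, term_cols, reference=ref))
        else:
            col = s.to_numpy(dtype=float)
            if np.any(~np.isfinite(col)):
                raise DataError(f"non-finite values in continuous covariate {var!r}")
            if center_continuous:
                col = col - col.mean()
            if col.std() == 0:
                log.warning("dropping zero-variance design column %s", var)
                continue
            cols.append(col)
            names.append(var)
            terms.append(TermInfo(var, [var]))
    return np.column_stack(cols), names, terms


def make_model_data(df: pd.DataFrame, config: PipelineConfig) -> ModelData:
    """Assemble the compact fitting representation from a validated frame."""
    codes, labels = pd.factorize(df[config.cluster_col], sort=True)
    X, count_names, count_terms = build_design(
        df, config.count_covariates, config.categories, config.center_continuous)
    Z, zero_names, zero_terms = build_design(
        df, config.zero_covariates, config.categories, config.center_continuous)
    return ModelData(
        y=df[config.outcome_col].to_numpy(),
        X=X, Z=Z, cluster=codes, n_clusters=len(labels),
        count_names=count_names, zero_names=zero_names,
        count_terms=count_terms, zero_terms=zero_terms,
        cluster_labels=np.asarray(labels),
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
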