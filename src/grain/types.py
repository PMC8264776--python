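"""Domain containers for the regulatory-network pipeline.

All containers validate their invariants on construction and are thin
wrappers over pandas/numpy objects so that downstream numerical code can
work directly on arrays and DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The five single-algorithm method tags plus the consensus tag.
METHOD_TAGS = ("pcc", "scc", "clr", "aracne", "genie3", "consensus")

MIN_SAMPLES = 4  # expression datasets with fewer samples are rejected


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns. ``condition`` optionally assigns a categorical label (e.g.
    control/stress) to each sample.
    """

    values: pd.DataFrame
    condition: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_g = idx[idx.duplicated()].unique()
        if len(dup_g):
            raise ValidationError(f"duplicate gene id(s): {list(dup_g)}")
        dup_s = cols[cols.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample id(s): {list(dup_s)}")
        if self.values.shape[0] < 2:
            raise ValidationError("expression matrix needs at least 2 genes")
        if self.values.shape[1] < MIN_SAMPLES:
            raise ValidationError(
                f"expression matrix needs at least {MIN_SAMPLES} samples, "
                f"got {self.values.shape[1]}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.condition is not None:
            cond = self.condition.reindex(cols)
            if cond.isna().any():
                missing = list(cond.index[cond.isna()])
                raise ValidationError(f"condition missing for sample(s): {missing}")
            self.condition = cond

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class RegulatorSet:
    """The set of gene ids permitted as edge sources (transcription factors)."""

    tf_ids: frozenset[str]

    def __init__(self, tf_ids) -> None:
        self.tf_ids = frozenset(tf_ids)
        if not self.tf_ids:
            raise ValidationError("regulator set must be nonempty")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = self.tf_ids - set(expr.gene_ids)
        if missing:
            raise ValidationError(
                f"regulator(s) absent from expression matrix: {sorted(missing)[:5]}"
            )

    def __contains__(self, tf: str) -> bool:
        return tf in self.tf_ids

    def __len__(self) -> int:
        return len(self.tf_ids)

    def __iter__(self):
        return iter(sorted(self.tf_ids))


EDGE_COLUMNS = ("regulator", "target", "score", "rank")


@dataclass
class RankedEdgeList:
    """Directed regulator->target edges with scores and dense ranks.

    ``edges`` has columns (regulator, target, score, rank) and is stored
    in rank order. Ranks must be a permutation of 1..n and score must be
    non-increasing along the rank order.
    """

    method: str
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.edges
        missing = [c for c in EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"edge list missing column(s): {missing}")
        df = df.loc[:, list(EDGE_COLUMNS)].reset_index(drop=True)
        self_loops = df[df["regulator"] == df["target"]]
        if len(self_loops):
            offender = self_loops.iloc[0]["regulator"]
            raise ValidationError(f"self-edge on {offender!r}")
        n = len(df)
        ranks = df["rank"].to_numpy()
        if n and (not np.issubdtype(ranks.dtype, np.integer)):
            if not np.allclose(ranks, ranks.astype(int)):
                raise ValidationError("ranks must be integers")
            ranks = ranks.astype(int)
        if sorted(ranks) != list(range(1, n + 1)):
            raise ValidationError(f"ranks are not a permutation of 1..{n}")
        df = df.assign(rank=ranks).sort_values("rank", kind="mergesort")
        scores = df["score"].to_numpy(dtype=float)
        if n > 1 and np.any(np.diff(scores) > 1e-12):
            raise ValidationError("scores must be non-increasing in rank order")
        dup = df.duplicated(subset=["regulator", "target"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["regulator", "target"]]
            raise ValidationError(
                f"duplicate edge ({pair['regulator']}, {pair['target']})"
            )
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def targets_of(self) -> dict[str, set[str]]:
        """Map each regulator to its set of predicted targets."""
        out: dict[str, set[str]] = {}
        for reg, tgt in zip(self.edges["regulator"], self.edges["target"]):
            out.setdefault(reg, set()).add(tgt)
        return out

    def validate_regulators(self, tfs: RegulatorSet) -> None:
        bad = set(self.edges["regulator"]) - tfs.tf_ids
        if bad:
            raise ValidationError(f"edge regulator(s) not in TF set: {sorted(bad)[:5]}")


@dataclass
class LabelSet:
    """Binary positive/negative class assignments for TFs, with optional
    family tags used by the family-matched baseline."""

    assignments: dict[str, str]
    family: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        bad = {v for v in self.assignments.values()} - {"positive", "negative"}
        if bad:
            raise ValidationError(f"labels must be positive/negative, got {sorted(bad)}")

    @property
    def positives(self) -> set[str]:
        return {t for t, l in self.assignments.items() if l == "positive"}

    @property
    def negatives(self) -> set[str]:
        return {t for t, l in self.assignments.items() if l == "negative"}

    def require_trainable(self) -> None:
        if not self.positives or not self.negatives:
            raise ValidationError(
                "training requires at least one positive and one negative TF"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id -> (description, genes)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for sid, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {sid!r} is empty")

    def genes(self, set_id: str) -> set[str]:
        return set(self.sets[set_id][1])

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# -- pipeline configuration ---------------------------------------------------

_CONFIG_DEFAULTS: dict = {
    # edge filtering and aggregation
    "top_k": 500000,
    # mutual-information estimation; 0 = ceil(sqrt(n_samples))
    "mi_bins": 0,
    "dpi_tolerance": 0.0,
    "n_trees": 100,
    # module detection
    "inflation": 2.0,
    "coreg_quantile": 0.95,
    # classifier
    "c_grid": (0.001, 10.0, 0.1),
    "n_folds": 5,
    "n_runs": 10,
    "n_bins_decile": 100,
    "q_threshold": 0.05,
    "seed": 1,
    # synthetic benchmark generator
    "n_programs": 4,
    "tfs_per_program": 5,
    "targets_per_program": 50,
    "n_stress_programs": 1,
    "p_bg": 0.01,
    "weight_scale": 1.0,
    "delta": 2.0,
    "sigma": 0.5,
    "n_control": 75,
    "n_stress": 75,
    # methods excluded from the aggregate (e.g. ["pcc", "scc"])
    "exclude": (),
}


@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end pipeline.

    Defaults follow the published procedure where it states a value
    (top 500,000 edges, inflation 2.0, C grid 0.001..10 step 0.1,
    5 folds, 10 runs, 100 decile bins, q<0.05) and this package's
    documented choices elsewhere.
    """

    top_k: int = _CONFIG_DEFAULTS["top_k"]
    mi_bins: int = _CONFIG_DEFAULTS["mi_bins"]
    dpi_tolerance: float = _CONFIG_DEFAULTS["dpi_tolerance"]
    n_trees: int = _CONFIG_DEFAULTS["n_trees"]
    inflation: float = _CONFIG_DEFAULTS["inflation"]
    coreg_quantile: float = _CONFIG_DEFAULTS["coreg_quantile"]
    c_grid: tuple[float, float, float] = _CONFIG_DEFAULTS["c_grid"]
    n_folds: int = _CONFIG_DEFAULTS["n_folds"]
    n_runs: int = _CONFIG_DEFAULTS["n_runs"]
    n_bins_decile: int = _CONFIG_DEFAULTS["n_bins_decile"]
    q_threshold: float = _CONFIG_DEFAULTS["q_threshold"]
    seed: int = _CONFIG_DEFAULTS["seed"]
    n_programs: int = _CONFIG_DEFAULTS["n_programs"]
    tfs_per_program: int = _CONFIG_DEFAULTS["tfs_per_program"]
    targets_per_program: int = _CONFIG_DEFAULTS["targets_per_program"]
    n_stress_programs: int = _CONFIG_DEFAULTS["n_stress_programs"]
    p_bg: float = _CONFIG_DEFAULTS["p_bg"]
    weight_scale: float = _CONFIG_DEFAULTS["weight_scale"]
    delta: float = _CONFIG_DEFAULTS["delta"]
    sigma: float = _CONFIG_DEFAULTS["sigma"]
    n_control: int = _CONFIG_DEFAULTS["n_control"]
    n_stress: int = _CONFIG_DEFAULTS["n_stress"]
    exclude: tuple[str, ...] = _CONFIG_DEFAULTS["exclude"]

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.mi_bins < 0:
            raise ValidationError("mi_bins must be >= 0 (0 = automatic)")
        if self.dpi_tolerance < 0:
            raise ValidationError("dpi_tolerance must be >= 0")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if not (0 < self.coreg_quantile < 1):
            raise ValidationError("coreg_quantile must be in (0, 1)")
        self.c_grid = tuple(float(x) for x in self.c_grid)  # type: ignore[assignment]
        lo, hi, step = self.c_grid
        if not (0 < lo <= hi and step > 0):
            raise ValidationError(f"invalid C grid {self.c_grid}")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_runs < 0:
            raise ValidationError("n_runs must be >= 0")
        if self.n_bins_decile < 1:
            raise ValidationError("n_bins_decile must be >= 1")
        if not (0 < self.q_threshold < 1):
            raise ValidationError("q_threshold must be in (0, 1)")
        for name in ("n_programs", "tfs_per_program", "targets_per_program",
                     "n_stress_programs", "n_control", "n_stress"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 <= self.p_bg < 1):
            raise ValidationError("p_bg must be in [0, 1)")
        if self.weight_scale <= 0 or self.sigma <= 0:
            raise ValidationError("weight_scale and sigma must be > 0")
        self.exclude = tuple(self.exclude)
        bad = set(self.exclude) - set(METHOD_TAGS[:5])
        if bad:
            raise ValidationError(f"unknown method(s) in exclude: {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        unknown = set(data) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "c_grid" in kwargs:
            grid = kwargs["c_grid"]
            if not (isinstance(grid, (list, tuple)) and len(grid) == 3):
                raise ValidationError("c_grid must be a [lo, hi, step] triple")
            kwargs["c_grid"] = tuple(float(x) for x in grid)
        if "exclude" in kwargs:
            ex = kwargs["exclude"]
            if isinstance(ex, str):
                ex = ex.split()
            kwargs["exclude"] = tuple(ex)
        return cls(**kwargs)
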