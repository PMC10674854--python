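"""End-to-end glue: run configuration, single-recording feature extraction
and feature-table I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import TreeConfig
from .errors import ValidationError
from .features import DEFAULT_ALPHA, FEATURE_NAMES, FeatureVector, build_feature_vector
from .keypoints import Demographics, HandPoseSeries
from .preprocess import PreprocessConfig, preprocess


@dataclass
class RunConfig:
    """All tunables of the pipeline in one validated place."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = DEFAULT_ALPHA
    tree: TreeConfig = field(default_factory=TreeConfig)
    split_seed: int = 0
    test_fraction: float = 0.2
    profile_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.tree.max_depth < 1 or self.tree.min_samples_leaf < 1:
            raise ValidationError("tree hyperparameters must be >= 1")
        p = self.preprocess
        if p.n_keep_imfs < 1 or p.smooth_window_s <= 0 or p.min_separation_s <= 0:
            raise ValidationError("invalid preprocessing parameters")
        if not 0 < p.min_prominence_frac < 1:
            raise ValidationError("min_prominence_frac must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pre = PreprocessConfig(**raw.get("preprocess", {}))
        tree = TreeConfig(**raw.get("tree", {}))
        top = {
            k: v
            for k, v in raw.items()
            if k in ("alpha", "split_seed", "test_fraction", "profile_path")
        }
        return cls(preprocess=pre, tree=tree, **top)

    def to_yaml(self) -> str:
        payload = {
            "preprocess": asdict(self.preprocess),
            "tree": asdict(self.tree),
            "alpha": self.alpha,
            "split_seed": self.split_seed,
            "test_fraction": self.test_fraction,
            "profile_path": self.profile_path,
        }
        return yaml.safe_dump(payload, sort_keys=True)


def extract_features(
    series: HandPoseSeries,
    demographics: Demographics,
    config: RunConfig | None = None,
) -> FeatureVector:
    """Preprocess one recording and compute its 15-feature vector."""
    cfg = config or RunConfig()
    _, peaks = preprocess(series, cfg.preprocess)
    return build_feature_vector(
        peaks, demographics, alpha=cfg.alpha, subject_id=series.subject_id
    )


def features_to_frame(
    vectors: list[FeatureVector], labels: list[int] | None = None
) -> pd.DataFrame:
    """Feature table with the 15 canonical columns plus subject_id (+ label)."""
    rows = []
    for i, fv in enumerate(vectors):
        row = {"subject_id": fv.subject_id}
        row.update({name: fv.values[name] for name in FEATURE_NAMES})
        if labels is not None:
            row["label"] = int(labels[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    return df


def frame_to_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 15) matrix in canonical column order."""
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float)
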