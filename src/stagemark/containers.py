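"""Core data containers: expression matrices and stage-annotated sample designs.

Both are thin, validated wrappers around pandas objects.  An
:class:`ExpressionMatrix` holds non-negative abundance estimates (RSEM-style
normalized counts) with genes as rows; a :class:`StageDesign` holds the
per-sample diagnosis (``cancer``/``normal``) and pathologic stage coded
0-4, where 0 denotes a control.  The design exposes the two encodings used
by the stage models: four stage indicator columns and a single numeric
stage covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CLASS_CANCER = "cancer"
CLASS_NORMAL = "normal"
STAGES = (0, 1, 2, 3, 4)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative, finite expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ConfigurationError("expression matrix is empty")
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ConfigurationError("expression values must be finite")
        if (arr < 0).any():
            raise ConfigurationError("expression values must be non-negative")

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

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])


@dataclass
class StageDesign:
    """Per-sample class and stage annotation.

    Invariant: ``class == normal`` exactly when ``stage == 0``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "class", "stage"}
        missing = required - set(t.columns)
        if missing:
            raise ConfigurationError(f"annotation missing columns: {sorted(missing)}")
        t = t.copy()
        t["stage"] = t["stage"].astype(int)
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConfigurationError(f"duplicate sample ids in annotation: {dups}")
        bad_class = set(t["class"]) - {CLASS_CANCER, CLASS_NORMAL}
        if bad_class:
            raise ConfigurationError(f"unknown class labels: {sorted(bad_class)}")
        if not t["stage"].isin(STAGES).all():
            bad = sorted(set(t["stage"]) - set(STAGES))
            raise ConfigurationError(f"stages outside 0..4: {bad}")
        normal = t["class"] == CLASS_NORMAL
        if not (normal == (t["stage"] == 0)).all():
            raise ConfigurationError(
                "class/stage mismatch: controls must have stage 0 and tumors stage 1-4"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def classes(self) -> pd.Series:
        return self.table.set_index("sample_id")["class"]

    @property
    def numeric_stage(self) -> np.ndarray:
        """Stage as a numeric covariate X in {0,1,2,3,4}; 0 = control."""
        return self.table["stage"].to_numpy(dtype=float)

    @property
    def stage_indicators(self) -> np.ndarray:
        """n x 4 indicator matrix (x1..x4); all-zero rows are controls."""
        stage = self.table["stage"].to_numpy()
        out = np.zeros((len(stage), 4), dtype=float)
        for s in (1, 2, 3, 4):
            out[stage == s, s - 1] = 1.0
        return out

    def subset(self, sample_ids) -> "StageDesign":
        wanted = list(sample_ids)
        sub = self.table.set_index("sample_id").loc[wanted].reset_index()
        return StageDesign(sub)

    def stage_counts(self) -> dict[int, int]:
        return {s: int((self.table["stage"] == s).sum()) for s in STAGES}
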