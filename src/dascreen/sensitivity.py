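"""Per-cell-line sensitivity values for the ranking stage.

The ranking consumes sensitivity on an oriented, larger-is-more-sensitive
scale (pGI50-like): ``to_oriented`` converts molar GI50. Values can come
from a precomputed CSV (the usual route) or from the descriptor-kNN
baseline predictor, a deliberately simple stand-in behind the same
contract: any model producing a per-molecule, per-cell-line oriented
matrix can be plugged in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .pattern import SensitivityPattern, normalize_pattern


@dataclass
class SensitivityMatrix:
    """Molecules x cell lines matrix of oriented sensitivity values."""

    values: pd.DataFrame  # index molecule_id, columns cell lines

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("sensitivity values must be finite")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    def patterns(self) -> list[SensitivityPattern]:
        """Normalized (NGI50) pattern per molecule."""
        return [SensitivityPattern(mid,
                                   normalize_pattern(self.values.loc[mid].to_dict()))
                for mid in self.molecule_ids]


@dataclass
class TrainingPanel:
    """Reference molecules with both descriptors and known sensitivity."""

    descriptors: DescriptorMatrix
    sensitivity: SensitivityMatrix

    def __post_init__(self) -> None:
        missing = set(self.sensitivity.molecule_ids) ^ set(
            self.descriptors.molecule_ids)
        if missing:
            raise ValueError(
                f"reference molecules lack a descriptor or sensitivity row: "
                f"{sorted(missing)[:10]}")

    @property
    def size(self) -> int:
        return len(self.sensitivity.molecule_ids)


def to_oriented(gi50_molar: float) -> float:
    """Convert a molar GI50 to the oriented scale: -log10(GI50)."""
    if gi50_molar <= 0:
        raise ValueError(f"GI50 must be positive, got {gi50_molar}")
    return -math.log10(gi50_molar)


def knn_predict(query_row: pd.Series, panel: TrainingPanel,
                k: int = 5) -> dict[str, float]:
    """Inverse-distance-weighted k-nearest-neighbour sensitivity profile.

    Distances are Euclidean over the z-score-standardized descriptors shared
    between query and panel (standardization statistics from the panel only;
    constant descriptors are dropped). Weights are 1/(d + 1e-12), so a
    zero-distance reference dominates; every prediction lies inside the k
    neighbours' value range.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > panel.size:
        raise ValueError(f"k={k} exceeds panel size {panel.size}")
    ref = panel.descriptors.values
    q = query_row.reindex(ref.columns).to_numpy(dtype=float)
    ref_arr = ref.to_numpy(dtype=float)
    shared = np.isfinite(q) & np.isfinite(ref_arr).all(axis=0)
    mu = ref_arr[:, shared].mean(axis=0)
    sd = ref_arr[:, shared].std(ddof=0, axis=0)
    nonconst = sd > 0
    if not shared.any() or not nonconst.any():
        raise ValueError("no shared, non-constant descriptors for kNN")
    z_ref = (ref_arr[:, shared][:, nonconst] - mu[nonconst]) / sd[nonconst]
    z_q = (q[shared][nonconst] - mu[nonconst]) / sd[nonconst]
    d = np.sqrt(((z_ref - z_q) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    w = 1.0 / (d[order] + 1e-12)
    w = w / w.sum()
    sens = panel.sensitivity.values.to_numpy(dtype=float)[order]
    pred = (w[:, None] * sens).sum(axis=0)
    return dict(zip(panel.sensitivity.cell_lines, pred.tolist()))


def knn_predict_matrix(queries: DescriptorMatrix, panel: TrainingPanel,
                       k: int = 5) -> SensitivityMatrix:
    rows = {mid: knn_predict(queries.values.loc[mid], panel, k)
            for mid in queries.molecule_ids}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=panel.sensitivity.cell_lines)
    df.index.name = "molecule_id"
    return SensitivityMatrix(df)


# ---------------------------------------------------------------- file I/O

def read_sensitivity_csv(path: str | Path) -> SensitivityMatrix:
    """Long-format CSV: molecule_id, cell_line, value."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"molecule_id", "cell_line", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"sensitivity CSV must have columns {sorted(required)}")
    wide = df.pivot(index="molecule_id", columns="cell_line", values="value")
    wide.index = wide.index.astype(str)
    wide.columns = [str(c) for c in wide.columns]
    return SensitivityMatrix(wide.astype(float))


def write_sensitivity_csv(matrix: SensitivityMatrix, path: str | Path) -> None:
    long = matrix.values.stack().reset_index()
    long.columns = ["molecule_id", "cell_line", "value"]
    long.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
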