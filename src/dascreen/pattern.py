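"""Expression-pattern / chemosensitivity correlation ranking.

The protocol: a target protein's expression measurements over a tumor
cell-line panel are averaged per isoform, mean-centered and normalized by
the largest absolute deviation to give the normalized expression pattern
NEP (values in [-1, 1]). Each candidate molecule's per-line sensitivity
values (oriented larger = more sensitive, pGI50-like) are reduced the same
way to NGI50. The per-isoform fitting score is the L1 mismatch
phi = sum_i |NEP_i - NGI50_i| over shared cell lines, and molecules are
ranked by Phi, the mean of phi across isoforms — low Phi means the
molecule's chemosensitivity tracks the target's expression, the protocol's
evidence that activity runs through the target.

Because the normalization is invariant under positive affine transforms of
the raw values, Phi is unit-free across expression platforms and
sensitivity scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionExperiment:
    """One expression-profiling experiment for one target isoform."""

    experiment_id: str
    isoform: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(
                f"experiment {self.experiment_id!r} needs >= 2 cell lines")


@dataclass(frozen=True)
class TargetPattern:
    isoform: str
    nep: dict[str, float]
    n_experiments: int


@dataclass(frozen=True)
class SensitivityPattern:
    molecule_id: str
    ngi: dict[str, float]


@dataclass(frozen=True)
class FitScores:
    molecule_id: str
    phi: dict[str, float]
    Phi: float
    rank: int


def aggregate_expression(
    experiments: Sequence[ExpressionExperiment], isoform: str
) -> dict[str, float]:
    """Available-case mean expression per cell line for one isoform."""
    rows = [e for e in experiments if e.isoform == isoform]
    if not rows:
        raise ValueError(f"no experiments for isoform {isoform!r}")
    acc: dict[str, list[float]] = {}
    for e in rows:
        for line, v in e.values.items():
            acc.setdefault(line, []).append(v)
    return {line: float(np.mean(vs)) for line, vs in acc.items()}


def normalize_pattern(values: Mapping[str, float]) -> dict[str, float]:
    """Mean-center, then scale by the largest absolute deviation.

    Constant input (all deviations zero) maps to all zeros by declared rule.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 cell lines to normalize a pattern")
    lines = list(values)
    v = np.array([values[l] for l in lines], dtype=float)
    d = v - v.mean()
    m = np.abs(d).max()
    if m == 0.0:
        return {l: 0.0 for l in lines}
    return dict(zip(lines, (d / m).tolist()))


def target_patterns(
    experiments: Sequence[ExpressionExperiment],
    isoforms: Sequence[str] | None = None,
) -> list[TargetPattern]:
    """Aggregate-then-normalize expression for each isoform present."""
    if isoforms is None:
        seen: list[str] = []
        for e in experiments:
            if e.isoform not in seen:
                seen.append(e.isoform)
        isoforms = seen
    out = []
    for iso in isoforms:
        agg = aggregate_expression(experiments, iso)
        n = sum(1 for e in experiments if e.isoform == iso)
        out.append(TargetPattern(iso, normalize_pattern(agg), n))
    return out


def fitting_score(nep: Mapping[str, float], ngi: Mapping[str, float]) -> float:
    """phi = sum over shared cell lines of |NEP_i - NGI50_i|.

    Computed on the intersection of the two panels; fewer than 2 shared
    lines is an error (silent imputation would fabricate correlation).
    """
    shared = [l for l in nep if l in ngi]
    if len(shared) < 2:
        missing = sorted(set(nep) ^ set(ngi))
        raise ValueError(
            f"only {len(shared)} shared cell line(s); mismatched lines: "
            f"{missing[:10]}")
    return float(sum(abs(nep[l] - ngi[l]) for l in shared))


def rank_by_phi(
    sensitivity: Sequence[SensitivityPattern],
    targets: Sequence[TargetPattern],
) -> list[FitScores]:
    """Rank molecules ascending by Phi = mean over isoforms of phi.

    Ties are broken by molecule id (lexicographic) so output is
    deterministic; ranks are 1-based.
    """
    if not targets:
        raise ValueError("need >= 1 target pattern")
    rows = []
    for sp in sensitivity:
        phi = {t.isoform: fitting_score(t.nep, sp.ngi) for t in targets}
        rows.append((sp.molecule_id, phi, float(np.mean(list(phi.values())))))
    rows.sort(key=lambda r: (r[2], r[0]))
    return [FitScores(mid, phi, Phi, rank)
            for rank, (mid, phi, Phi) in enumerate(rows, start=1)]


def select_top(scores: Sequence[FitScores], k: int) -> list[str]:
    """The k lowest-Phi molecule ids in rank order (all of them if k > N)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores, key=lambda s: s.rank)
    return [s.molecule_id for s in ordered[:k]]


def fit_scores_to_frame(scores: Sequence[FitScores]) -> pd.DataFrame:
    isoforms = list(scores[0].phi) if scores else []
    data = {"molecule_id": [s.molecule_id for s in scores]}
    for iso in isoforms:
        data[f"phi_{iso}"] = [s.phi[iso] for s in scores]
    data["Phi"] = [s.Phi for s in scores]
    data["rank"] = [s.rank for s in scores]
    return pd.DataFrame(data)


# ---------------------------------------------------------------- file I/O

def read_expression_csv(path: str | Path) -> list[ExpressionExperiment]:
    """Long-format CSV: experiment_id, isoform, cell_line, value."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"experiment_id", "isoform", "cell_line", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression CSV must have columns {sorted(required)}")
    out = []
    for (eid, iso), grp in df.groupby(["experiment_id", "isoform"], sort=False):
        if grp["cell_line"].duplicated().any():
            raise ValueError(f"duplicate cell line in experiment {eid!r}")
        out.append(ExpressionExperiment(
            str(eid), str(iso),
            dict(zip(grp["cell_line"].astype(str), grp["value"].astype(float)))))
    return out


def write_expression_csv(experiments: Iterable[ExpressionExperiment],
                         path: str | Path) -> None:
    rows = [(e.experiment_id, e.isoform, line, v)
            for e in experiments for line, v in e.values.items()]
    pd.DataFrame(rows, columns=["experiment_id", "isoform", "cell_line",
                                "value"]).to_csv(
        path, index=False, float_format="%.17g", lineterminator="\n")
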