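"""Descriptor-template building and the descriptor affinity score (DAS).

A template summarizes a set of known actives as one (mu, sigma) pair per
descriptor. A query molecule is scored by the fraction of its descriptors
falling inside the closed interval mu +/- sigma: each descriptor contributes
a binary alpha (1 in range, 0 outside) and DAS = sum(alpha) / n, so DAS is
in [0, 1] with high values meaning template-like chemistry.

Conventions (declared, since the score's original description leaves them
open): sigma is the population standard deviation (divide by N), which makes
the template invariant to duplicating the actives set and gives a natural
single-active degenerate case (all sigma = 0); the interval is closed with a
small relative tolerance so boundary values and sigma = 0 constraints remain
satisfiable; descriptors missing for a query shrink the denominator rather
than scoring 0, and n_evaluated is reported so callers can threshold
coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

#: relative/absolute guard against float round-off at interval boundaries
_EPS_ABS = 1e-9


@dataclass(frozen=True)
class TemplateEntry:
    name: str
    mu: float
    sigma: float
    n_used: int


@dataclass
class Template:
    """Per-descriptor (mu, sigma) summary of an actives set."""

    descriptor_set_id: str
    entries: list[TemplateEntry]
    built_from: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.sigma < 0:
                raise ValueError(f"negative sigma for {e.name}")
            if not 1 <= e.n_used <= self.built_from:
                raise ValueError(f"bad n_used for {e.name}")

    @property
    def degenerate(self) -> bool:
        """True when built from a single active (every sigma is 0)."""
        return self.built_from == 1

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def mu_sigma(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([e.mu for e in self.entries]),
                np.array([e.sigma for e in self.entries]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "descriptor_set_id": self.descriptor_set_id,
            "built_from": self.built_from,
            "entries": [vars(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Template":
        payload = json.loads(Path(path).read_text())
        return cls(
            descriptor_set_id=payload["descriptor_set_id"],
            entries=[TemplateEntry(**e) for e in payload["entries"]],
            built_from=payload["built_from"],
        )


@dataclass(frozen=True)
class DasScore:
    molecule_id: str
    das: float
    n_evaluated: int
    n_in_range: int


def build_template(actives_matrix: DescriptorMatrix) -> Template:
    """Summarize an actives descriptor matrix into a template.

    Per descriptor: available-case mean and population standard deviation
    over the actives that have a value. Descriptors missing for every active
    are dropped; ``n_used`` records per-descriptor availability.
    """
    df = actives_matrix.values
    if df.shape[0] == 0:
        raise ValueError("cannot build a template from an empty matrix")
    n_used = df.count()
    keep = n_used[n_used > 0].index
    if len(keep) == 0:
        raise ValueError("no descriptor has a value for any active")
    mu = df[keep].mean()
    sigma = df[keep].std(ddof=0)
    entries = [TemplateEntry(name, float(mu[name]), float(sigma[name]),
                             int(n_used[name]))
               for name in keep]
    return Template(actives_matrix.descriptor_set_id, entries, df.shape[0])


def das_score(query_row: pd.Series, template: Template,
              descriptor_set_id: str | None = None) -> DasScore:
    """DAS of one molecule's descriptor row against a template.

    ``query_row`` is a Series indexed by descriptor name (a row of a
    DescriptorMatrix computed with the template's descriptor set); missing
    (NaN) descriptors are excluded from numerator and denominator.
    """
    if descriptor_set_id is not None and \
            descriptor_set_id != template.descriptor_set_id:
        raise ValueError(
            f"descriptor set mismatch: query {descriptor_set_id!r} vs "
            f"template {template.descriptor_set_id!r}")
    mu, sigma = template.mu_sigma()
    values = query_row.reindex(template.names).to_numpy(dtype=float)
    available = np.isfinite(values)
    n_eval = int(available.sum())
    if n_eval == 0:
        raise ValueError(
            f"DAS undefined for {query_row.name!r}: no descriptor of the "
            "template could be evaluated")
    eps = np.maximum(_EPS_ABS, _EPS_ABS * np.abs(mu))
    in_range = available & (values >= mu - sigma - eps) & \
        (values <= mu + sigma + eps)
    n_in = int(in_range.sum())
    return DasScore(str(query_row.name), n_in / n_eval, n_eval, n_in)


def score_matrix(matrix: DescriptorMatrix, template: Template) -> list[DasScore]:
    """DAS for every row of a descriptor matrix (set ids must match)."""
    if matrix.descriptor_set_id != template.descriptor_set_id:
        raise ValueError(
            f"descriptor set mismatch: matrix {matrix.descriptor_set_id!r} "
            f"vs template {template.descriptor_set_id!r}")
    return [das_score(matrix.values.loc[mid], template)
            for mid in matrix.molecule_ids]


def apply_das_cutoff(scores: Iterable[DasScore], cutoff: float) -> list[str]:
    """Ids with das >= cutoff, input order preserved."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    return [s.molecule_id for s in scores if s.das >= cutoff]


def scores_to_frame(scores: Sequence[DasScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {"molecule_id": [s.molecule_id for s in scores],
         "das": [s.das for s in scores],
         "n_evaluated": [s.n_evaluated for s in scores],
         "n_in_range": [s.n_in_range for s in scores]})
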