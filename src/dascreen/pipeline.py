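"""End-to-end screening orchestration and the PCA chemical-space report.

``screen`` runs the whole protocol: descriptors -> template -> DAS cutoff
-> sensitivity -> Phi ranking -> top-k shortlist -> drug-likeness filter
panel, writing a ranking CSV, a filter CSV (when structures are available)
and a JSON run manifest with the stage counts. Stage counts always
reconcile: shortlist is a subset of the post-cutoff set, which is a subset
of the input database.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chem_io
from .descriptors import (DEFAULT_DESCRIPTOR_SET, DescriptorMatrix,
                          compute_descriptors)
from .filters import filter_panel, reports_to_frame
from .pattern import (fit_scores_to_frame, rank_by_phi, read_expression_csv,
                      select_top, target_patterns)
from .sensitivity import (SensitivityMatrix, TrainingPanel,
                          knn_predict_matrix, read_sensitivity_csv)
from .template import (Template, apply_das_cutoff, build_template,
                       score_matrix, scores_to_frame)

log = logging.getLogger(__name__)

_MOLECULE_SUFFIXES = {".smi", ".smiles", ".sdf", ".sd"}


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScreenConfig:
    """Configuration of a full screening run."""

    actives: str
    database: str
    expression: str
    out_dir: str
    sensitivity: Optional[str] = None
    predictor: str = "csv"           # "csv" or "knn"
    train_descriptors: Optional[str] = None
    train_sensitivity: Optional[str] = None
    das_cutoff: float = 0.8
    top_k: int = 24
    knn_k: int = 5
    descriptor_set_id: str = DEFAULT_DESCRIPTOR_SET
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.das_cutoff <= 1.0:
            raise ValueError(
                f"das_cutoff must be in [0, 1], got {self.das_cutoff}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.predictor not in {"csv", "knn"}:
            raise ValueError(f"predictor must be 'csv' or 'knn', "
                             f"got {self.predictor!r}")
        if self.predictor == "csv" and self.sensitivity is None:
            raise ValueError("predictor 'csv' requires a sensitivity path")
        if self.predictor == "knn" and (self.train_descriptors is None or
                                        self.train_sensitivity is None):
            raise ValueError("predictor 'knn' requires train_descriptors "
                             "and train_sensitivity paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ScreenConfig":
        """Load a key: value config file; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_side(path: str, descriptor_set_id: str, stage: str):
    """Load molecules+descriptors (structure file) or a descriptor CSV."""
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"input not found: {p}")
    if p.suffix.lower() in _MOLECULE_SUFFIXES:
        molecules = chem_io.read_molecules(p)
        return molecules, compute_descriptors(molecules, descriptor_set_id)
    return None, DescriptorMatrix.from_csv(p, descriptor_set_id="external")


def screen(config: ScreenConfig) -> dict:
    """Run the full protocol; returns the run manifest (also written as
    JSON next to the outputs). Any stage error aborts and removes partial
    output files."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def _stage(name: str):
        log.info("stage %s ...", name)
        manifest["stages"][name] = {"t": round(time.time() - t0, 3)}
        return manifest["stages"][name]

    try:
        st = _stage("descriptors")
        _, actives_dm = _load_side(config.actives, config.descriptor_set_id,
                                   "descriptors")
        db_mols, db_dm = _load_side(config.database, config.descriptor_set_id,
                                    "descriptors")
        if actives_dm.descriptor_set_id != db_dm.descriptor_set_id:
            raise StageError("descriptors", "actives and database descriptor "
                             "sets differ")
        st["n_actives"] = len(actives_dm.molecule_ids)
        st["n_database"] = len(db_dm.molecule_ids)

        st = _stage("template")
        try:
            template = build_template(actives_dm)
        except ValueError as e:
            raise StageError("template", str(e))
        st["n_descriptors"] = len(template.entries)
        template.to_json(out_dir / "template.json")
        written.append(out_dir / "template.json")

        st = _stage("das")
        try:
            scores = score_matrix(db_dm, template)
            survivors = apply_das_cutoff(scores, config.das_cutoff)
        except ValueError as e:
            raise StageError("das", str(e))
        chem_io.write_table(scores_to_frame(scores), out_dir / "das.csv")
        written.append(out_dir / "das.csv")
        st["n_scored"] = len(scores)
        st["n_post_cutoff"] = len(survivors)
        log.info("DAS cutoff %.2f: %d -> %d molecules", config.das_cutoff,
                 len(scores), len(survivors))
        if not survivors:
            raise StageError("das", "no molecule survives the DAS cutoff")

        st = _stage("sensitivity")
        if config.predictor == "csv":
            sens = read_sensitivity_csv(config.sensitivity)
        else:
            panel = TrainingPanel(
                DescriptorMatrix.from_csv(config.train_descriptors),
                read_sensitivity_csv(config.train_sensitivity))
            queries = DescriptorMatrix(db_dm.values.loc[survivors],
                                       db_dm.descriptor_set_id)
            sens = knn_predict_matrix(queries, panel, k=config.knn_k)
        missing = [m for m in survivors if m not in set(sens.molecule_ids)]
        if missing:
            raise StageError("sensitivity",
                             f"no sensitivity row for {missing[:10]}")
        sens = SensitivityMatrix(sens.values.loc[survivors])
        st["n_molecules"] = len(sens.molecule_ids)

        st = _stage("ranking")
        experiments = read_expression_csv(config.expression)
        targets = target_patterns(experiments)
        try:
            fits = rank_by_phi(sens.patterns(), targets)
        except ValueError as e:
            raise StageError("ranking", str(e))
        shortlist = select_top(fits, config.top_k)
        st["n_ranked"] = len(fits)
        st["n_shortlist"] = len(shortlist)

        ranking = fit_scores_to_frame(fits)
        das_by_id = {s.molecule_id: s.das for s in scores}
        ranking["das"] = ranking["molecule_id"].map(das_by_id)
        ranking["shortlisted"] = ranking["molecule_id"].isin(set(shortlist))
        chem_io.write_table(ranking, out_dir / "ranking.csv")
        written.append(out_dir / "ranking.csv")

        st = _stage("filters")
        if db_mols is not None:
            by_id = {m.id: m for m in db_mols}
            reports = filter_panel([by_id[m] for m in shortlist])
            chem_io.write_table(reports_to_frame(reports),
                                out_dir / "filters.csv")
            written.append(out_dir / "filters.csv")
            st["n_clean"] = sum(r.clean for r in reports)
            log.info("filter panel: %d/%d clean", st["n_clean"],
                     len(reports))
        else:
            st["skipped"] = ("database input is a descriptor matrix, not "
                            "structures; filter panel needs structures")

        # set-inclusion audit: no molecule appears downstream that was
        # absent upstream
        assert set(shortlist) <= set(survivors) <= set(db_dm.molecule_ids)
        manifest["shortlist"] = shortlist
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def pca_report(
    matrix: DescriptorMatrix,
    group_labels: Sequence[str] | dict[str, str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of the z-scored descriptor matrix.

    Descriptor columns are standardized before the decomposition (their
    scales differ by orders of magnitude, so an unscaled PCA would just
    rank variances); columns with missing values or zero variance are
    dropped. Component signs are fixed (largest-magnitude loading positive)
    so output is deterministic. Returns (coordinates with group labels,
    explained-variance fractions in descending order).
    """
    df = matrix.values
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("PCA needs >= 3 molecules and >= 2 descriptors")
    complete = df.dropna(axis=1)
    sd = complete.std(ddof=0)
    usable = complete.loc[:, sd > 0]
    if usable.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant complete descriptors")
    z = (usable - usable.mean()) / usable.std(ddof=0)
    x = z.to_numpy(dtype=float)
    # SVD of the centered (already) matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(2):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    var = s ** 2
    evr = var / var.sum()
    coords = pd.DataFrame(
        {"molecule_id": list(df.index),
         "pc1": u[:, 0] * s[0],
         "pc2": u[:, 1] * s[1]})
    if group_labels is not None:
        if isinstance(group_labels, dict):
            coords["group"] = [group_labels.get(m, "") for m in df.index]
        else:
            coords["group"] = list(group_labels)
    return coords, evr[:2]
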