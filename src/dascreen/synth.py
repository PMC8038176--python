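"""Synthetic fixtures with the statistical structure the pipeline assumes.

Everything the screening protocol consumes can be generated here with a
planted, noise-controlled signal:

* actives/decoys descriptor matrices — actives drawn around a latent
  per-descriptor (mu_d, sigma_d); decoys shifted 3*sigma_d away with a
  random sign per descriptor, which separates DAS scores sharply without
  being degenerate;
* multi-experiment expression patterns per isoform — a latent pattern over
  the cell-line panel plus per-experiment Gaussian noise (one shared latent
  across isoforms by default, so the noise-free planted case reaches
  Phi = 0 exactly);
* sensitivity matrices where chosen "planted" molecules track the target
  pattern with tunable Gaussian noise and the rest are panel-independent
  noise.

Defaults mirror the study conditions the pipeline was designed around:
117 actives, a 60-line panel, three isoforms with 10/6/10 experiments, and
a 1,000-molecule screening catalog stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .pattern import ExpressionExperiment, TargetPattern, target_patterns
from .sensitivity import SensitivityMatrix

SYNTH_DESCRIPTOR_SET = "synthetic-v1"


def _default_panel() -> list[str]:
    return [f"CL{i:02d}" for i in range(1, 61)]


def _default_experiments() -> dict[str, int]:
    return {"A": 10, "B": 6, "C": 10}


@dataclass
class SynthConfig:
    """Knobs of the generator; reproducible given ``seed``."""

    seed: int = 0
    n_actives: int = 117
    n_decoys: int = 1000
    n_planted: int = 10
    n_descriptors: int = 200
    panel: list[str] = field(default_factory=_default_panel)
    noise_sigma: float = 0.0
    expression_noise: float = 0.25
    experiments_per_isoform: dict[str, int] = field(
        default_factory=_default_experiments)
    shared_latent: bool = True

    @property
    def isoforms(self) -> list[str]:
        return list(self.experiments_per_isoform)


def _descriptor_names(n: int) -> list[str]:
    return [f"d{i:04d}" for i in range(n)]


def _latent_chemistry(config: SynthConfig):
    """Per-descriptor latent (mu_d, sigma_d) and decoy shift sign."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mu = rng.uniform(-10.0, 10.0, size=config.n_descriptors)
    sigma = rng.uniform(0.5, 2.0, size=config.n_descriptors)
    sign = rng.choice([-1.0, 1.0], size=config.n_descriptors)
    return mu, sigma, sign


def make_chemical_sets(
    config: SynthConfig,
) -> tuple[DescriptorMatrix, DescriptorMatrix]:
    """Actives and decoys descriptor matrices.

    Actives ~ Normal(mu_d, sigma_d) per descriptor; decoys ~
    Normal(mu_d + 3*sigma_d*s_d, sigma_d) with a random fixed sign s_d per
    descriptor, so a template built from the actives separates the two sets
    by DAS.
    """
    mu, sigma, sign = _latent_chemistry(config)
    names = _descriptor_names(config.n_descriptors)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    actives = mu + sigma * rng.standard_normal(
        (config.n_actives, config.n_descriptors))
    decoys = mu + 3.0 * sigma * sign + sigma * rng.standard_normal(
        (config.n_decoys, config.n_descriptors))

    a_df = pd.DataFrame(actives, columns=names,
                        index=[f"active_{i:04d}" for i in range(config.n_actives)])
    d_df = pd.DataFrame(decoys, columns=names,
                        index=[f"decoy_{i:04d}" for i in range(config.n_decoys)])
    a_df.index.name = d_df.index.name = "molecule_id"
    return (DescriptorMatrix(a_df, SYNTH_DESCRIPTOR_SET),
            DescriptorMatrix(d_df, SYNTH_DESCRIPTOR_SET))


def make_planted_descriptors(config: SynthConfig) -> DescriptorMatrix:
    """Descriptor rows for the planted molecules, drawn like actives.

    Planted molecules must survive the DAS cutoff in end-to-end runs, so
    their descriptors follow the actives' distribution.
    """
    mu, sigma, _ = _latent_chemistry(config)
    names = _descriptor_names(config.n_descriptors)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 12]))
    vals = mu + sigma * rng.standard_normal(
        (config.n_planted, config.n_descriptors))
    df = pd.DataFrame(vals, columns=names,
                      index=[f"planted_{i:04d}" for i in range(config.n_planted)])
    df.index.name = "molecule_id"
    return DescriptorMatrix(df, SYNTH_DESCRIPTOR_SET)


def make_expression(config: SynthConfig) -> list[ExpressionExperiment]:
    """Per-isoform expression experiments over the panel.

    One latent pattern (shared across isoforms by default) plus
    Normal(0, expression_noise) per experiment and line.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_lines = len(config.panel)
    shared = rng.standard_normal(n_lines)
    out: list[ExpressionExperiment] = []
    for iso, n_exp in config.experiments_per_isoform.items():
        latent = shared if config.shared_latent else rng.standard_normal(n_lines)
        for j in range(n_exp):
            noise = config.expression_noise * rng.standard_normal(n_lines)
            values = dict(zip(config.panel, (latent + noise).tolist()))
            out.append(ExpressionExperiment(f"{iso}_exp{j:02d}", iso, values))
    return out


def make_sensitivity(
    config: SynthConfig,
    targets: list[TargetPattern],
    n_nonplanted: int | None = None,
) -> tuple[SensitivityMatrix, list[str]]:
    """Sensitivity matrix with planted pattern-followers.

    Planted molecules: oriented sensitivity = mean over isoforms of the
    normalized expression pattern, plus Normal(0, noise_sigma) per line.
    Non-planted molecules: panel-independent standard normal noise.
    Returns the matrix and the planted ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lines = config.panel
    nep_mean = np.array([
        np.mean([t.nep[l] for t in targets]) for l in lines])
    n_non = config.n_decoys if n_nonplanted is None else n_nonplanted
    rows: dict[str, np.ndarray] = {}
    planted_ids = [f"planted_{i:04d}" for i in range(config.n_planted)]
    for pid in planted_ids:
        rows[pid] = nep_mean + config.noise_sigma * rng.standard_normal(
            len(lines))
    for i in range(n_non):
        rows[f"decoy_{i:04d}"] = rng.standard_normal(len(lines))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=lines)
    df.index.name = "molecule_id"
    return SensitivityMatrix(df), planted_ids


def make_screen_fixture(config: SynthConfig, outdir) -> dict[str, str]:
    """Write a complete drop-in input set for the screening pipeline.

    Files (all CSV, same formats the real pipeline reads): actives
    descriptor matrix, database descriptor matrix (planted + decoys),
    long-format expression table, long-format sensitivity table. Returns
    the path of each file keyed by role.
    """
    from pathlib import Path

    from .pattern import write_expression_csv
    from .sensitivity import write_sensitivity_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    actives, decoys = make_chemical_sets(config)
    planted = make_planted_descriptors(config)
    database = DescriptorMatrix(
        pd.concat([planted.values, decoys.values]), SYNTH_DESCRIPTOR_SET)
    experiments = make_expression(config)
    targets = target_patterns(experiments)
    sens, _ = make_sensitivity(config, targets)

    paths = {
        "actives": outdir / "actives_descriptors.csv",
        "database": outdir / "database_descriptors.csv",
        "expression": outdir / "expression.csv",
        "sensitivity": outdir / "sensitivity.csv",
    }
    actives.to_csv(paths["actives"])
    database.to_csv(paths["database"])
    write_expression_csv(experiments, paths["expression"])
    write_sensitivity_csv(sens, paths["sensitivity"])
    return {k: str(v) for k, v in paths.items()}


def planted_recovery_fraction(
    config: SynthConfig, top_k: int | None = None
) -> float:
    """Fraction of planted molecules ranked inside the top-k by Phi.

    Runs the generator and the ranking end to end for one seed; ``top_k``
    defaults to 2 * n_planted.
    """
    from .pattern import rank_by_phi, select_top

    if top_k is None:
        top_k = 2 * config.n_planted
    experiments = make_expression(config)
    targets = target_patterns(experiments)
    matrix, planted = make_sensitivity(config, targets)
    scores = rank_by_phi(matrix.patterns(), targets)
    top = set(select_top(scores, top_k))
    return sum(1 for p in planted if p in top) / len(planted)
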