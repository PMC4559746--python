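"""Synthetic expression cohorts with planted modes of abnormality.

The generator emulates the statistical structure the scoring model
assumes: UPC-scale expression in [0, 1], a pathway gene whose per-sample
expression (drawn from the same law in both groups, Uniform(0, 1) by
default) determines the low/high region of each sample, and target genes
whose case-group expression is shifted only where the planted mode
dictates:

* ``none`` -- no shift anywhere (null pairs);
* ``high_only_up`` / ``high_only_down`` -- case samples shifted up/down
  only in the high region (the restorable, good-target pattern);
* ``low_only`` -- case samples shifted only in the low region;
* ``constitutive`` -- case samples shifted in both regions.

Target values are ``baseline + effect * direction * active +
Normal(0, noise_sd)`` clipped to [0, 1]; the clipped fraction is
reported so tests can assert the Gaussian model stays honest near the
bounds.  Each pathway gene gets one synthetic TF linking it to its
targets, so the generated pathway-unit and GMT files reproduce exactly
the planted pairs, and a truth table records every pair's planted mode.

Pairs are dealt to pathway genes in contiguous blocks in a fixed mode
order, so mode counts that align with the per-gene block size yield
mode-pure pathway genes (useful for rank-recovery designs).  Everything
is fully determined by the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    GroupLabels,
    read_expression,
    read_groups,
    write_expression,
    write_groups,
)
from .pathway_map import PathwayUnitMap, TFTargetMap, read_gmt, read_pathway_units
from .scoring import REGION_THRESHOLD

log = logging.getLogger(__name__)

#: canonical mode order; also the dealing order for block assignment
MODES = ("none", "high_only_up", "high_only_down", "low_only", "constitutive")

#: planted direction of the case-group shift per mode
_MODE_DIRECTION = {
    "none": 0,
    "high_only_up": +1,
    "high_only_down": -1,
    "low_only": +1,
    "constitutive": +1,
}

FIXTURE_FILES = (
    "expression.tsv",
    "groups.tsv",
    "pathway_units.tsv",
    "tf_targets.gmt",
    "truth.tsv",
)


class SimulationError(ValueError):
    pass


def _default_modes() -> dict:
    return {m: 40 for m in MODES}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 50 samples per group, additive effect 0.3 on a baseline of
    0.4 with Gaussian noise sd 0.1, 40 pairs of each mode over 10
    pathway genes -- a moderately powered two-phenotype design in which
    a high-region shift of 0.3 is comfortably detectable at p = 0.01
    with roughly 25 case and 25 reference samples per region.
    """

    seed: int
    n_ref: int = 50
    n_case: int = 50
    effect: float = 0.3
    noise_sd: float = 0.1
    baseline: float = 0.4
    modes: dict = field(default_factory=_default_modes)
    n_pathway_genes: int = 10
    pathway_gene_law: Callable | None = None  # (rng, size) -> values in [0,1]

    def __post_init__(self) -> None:
        if self.n_ref < 4 or self.n_case < 4:
            raise SimulationError("n_ref and n_case must be >= 4")
        if self.effect <= 0:
            raise SimulationError("effect must be positive")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not (0.0 <= self.baseline <= 1.0):
            raise SimulationError("baseline must lie in [0, 1]")
        if self.n_pathway_genes < 1:
            raise SimulationError("n_pathway_genes must be >= 1")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise SimulationError(f"unknown mode(s): {sorted(unknown)}")
        if any(c < 0 for c in self.modes.values()):
            raise SimulationError("mode counts must be >= 0")
        if sum(self.modes.values()) == 0:
            raise SimulationError("mode counts are all zero")


@dataclass(frozen=True)
class FixtureBundle:
    """Everything the pipeline needs, plus ground truth."""

    matrix: ExpressionMatrix
    labels: GroupLabels
    units: PathwayUnitMap
    tft: TFTargetMap
    truth: pd.DataFrame  # pathway_gene, target_gene, mode, direction, effect
    clip_fraction: float


def _expected_label(mode: str) -> str:
    """The mode label the classifier should recover for a planted mode."""
    return {
        "none": "normal",
        "high_only_up": "high_only",
        "high_only_down": "high_only",
        "low_only": "low_only",
        "constitutive": "constitutive",
    }[mode]


def generate(config: SimulationConfig) -> FixtureBundle:
    """Generate a cohort, pathway/TFT maps and the truth table."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_ref + config.n_case
    samples = [f"N{i:03d}" for i in range(config.n_ref)] + [
        f"C{i:03d}" for i in range(config.n_case)
    ]
    is_case = np.array([False] * config.n_ref + [True] * config.n_case)
    labels = GroupLabels(
        assignments={
            s: ("cancer" if c else "normal") for s, c in zip(samples, is_case)
        },
        reference_group="normal",
        case_group="cancer",
    )

    mode_sequence = [m for m in MODES for _ in range(config.modes.get(m, 0))]
    total = len(mode_sequence)
    npg = config.n_pathway_genes
    width = max(len(str(npg)), 2)
    pg_names = [f"PG{i + 1:0{width}d}" for i in range(npg)]

    law = config.pathway_gene_law or (lambda r, size: r.uniform(0.0, 1.0, size))
    pg_values = np.asarray(law(rng, (npg, n_samples)), dtype=float)
    if pg_values.shape != (npg, n_samples):
        raise SimulationError("pathway_gene_law returned the wrong shape")
    high = pg_values > REGION_THRESHOLD

    # deal pairs to pathway genes in balanced contiguous blocks
    base, extra = divmod(total, npg)
    block_sizes = [base + (1 if i < extra else 0) for i in range(npg)]
    owner = np.repeat(np.arange(npg), block_sizes)

    tg_width = max(len(str(total)), 4)
    target_values = np.empty((total, n_samples))
    truth_rows = []
    n_clipped = 0
    for j, mode in enumerate(mode_sequence):
        pg_idx = owner[j]
        direction = _MODE_DIRECTION[mode]
        if mode == "none":
            active = np.zeros(n_samples, dtype=bool)
        elif mode in ("high_only_up", "high_only_down"):
            active = is_case & high[pg_idx]
        elif mode == "low_only":
            active = is_case & ~high[pg_idx]
        else:  # constitutive
            active = is_case
        raw = (
            config.baseline
            + config.effect * direction * active
            + rng.normal(0.0, config.noise_sd, n_samples)
        )
        n_clipped += int(np.sum((raw < 0.0) | (raw > 1.0)))
        target_values[j] = np.clip(raw, 0.0, 1.0)
        truth_rows.append(
            {
                "pathway_gene": pg_names[pg_idx],
                "target_gene": f"TG{j + 1:0{tg_width}d}",
                "mode": mode,
                "direction": {1: "up", -1: "down", 0: "none"}[direction],
                "effect": config.effect if mode != "none" else 0.0,
            }
        )
    truth = pd.DataFrame(truth_rows)

    all_values = np.vstack([pg_values, target_values])
    clip_fraction = n_clipped / all_values.size
    if clip_fraction > 0:
        log.info("clipped %.3f%% of generated values into [0, 1]", 100 * clip_fraction)
    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.clip(all_values, 0.0, 1.0),
            index=pg_names + list(truth["target_gene"]),
            columns=samples,
        )
    )

    units_d: dict[str, set[str]] = {}
    tft_d: dict[str, set[str]] = {}
    for pg, sub in truth.groupby("pathway_gene"):
        tf = f"TF_{pg}"
        units_d[pg] = {tf}
        tft_d[tf] = set(sub["target_gene"])
    return FixtureBundle(
        matrix=matrix,
        labels=labels,
        units=PathwayUnitMap(units_d),
        tft=TFTargetMap(tft_d),
        truth=truth,
        clip_fraction=clip_fraction,
    )


def write_fixture(bundle: FixtureBundle, directory) -> None:
    """Write the bundle as five plain-text files (see FIXTURE_FILES)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.matrix, directory / "expression.tsv")
    write_groups(bundle.labels, directory / "groups.tsv")
    with open(directory / "pathway_units.tsv", "w", encoding="utf-8") as fh:
        fh.write("pathway_gene\ttf\n")
        for gene in sorted(bundle.units.units):
            for tf in sorted(bundle.units.units[gene]):
                fh.write(f"{gene}\t{tf}\n")
    with open(directory / "tf_targets.gmt", "w", encoding="utf-8") as fh:
        for tf in sorted(bundle.tft.sets):
            members = "\t".join(sorted(bundle.tft.sets[tf]))
            fh.write(f"{tf}\tsynthetic\t{members}\n")
    bundle.truth.sort_values(["pathway_gene", "target_gene"]).to_csv(
        directory / "truth.tsv", sep="\t", index=False
    )


def read_fixture(directory) -> FixtureBundle:
    """Re-read a written fixture bundle (clip fraction is not recoverable)."""
    directory = Path(directory)
    matrix = read_expression(directory / "expression.tsv")
    labels = read_groups(directory / "groups.tsv", matrix)
    units = read_pathway_units(directory / "pathway_units.tsv")
    tft = read_gmt(directory / "tf_targets.gmt")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    return FixtureBundle(matrix, labels, units, tft, truth, float("nan"))
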