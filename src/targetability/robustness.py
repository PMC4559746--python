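"""Rank stability of drug targetability under sample subsampling.

The gene ranking is recomputed on repeated stratified subsamples of the
cohort (default: 100 repeats, 80% of each group drawn without
replacement) and the (full-data rank, subsample rank) points, pooled
over genes and repeats, are summarized by their Pearson correlation and
the least-squares slope of subsample rank on full rank with its t
statistic.  A stable ranking yields r near 1 and a significantly
non-zero slope; pure noise yields neither.

One master seed spawns the per-repeat seeds deterministically, so the
whole report is reproducible bit for bit from (inputs, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression_io import ExpressionMatrix, GroupLabels
from .pathway_map import PairMap
from .scoring import score_all, DEFAULT_TRANSFORM
from .targetability import (
    DEFAULT_COMBINER,
    MERGE_FRACTION,
    MODE_THRESHOLD,
    attach_scores,
    merge_genes,
    rank_genes,
)

log = logging.getLogger(__name__)

MIN_SUBSAMPLE_GROUP = 4


class RobustnessError(ValueError):
    pass


@dataclass(frozen=True)
class RobustnessReport:
    """Summary of rank stability over subsampling repeats.

    ``per_repeat_ranks[i, r]`` is gene ``genes[i]``'s rank in repeat
    ``r`` (NaN when the gene was unscoreable in that repeat).
    """

    n_repeats: int
    subsample_fraction: float
    seed: int
    genes: tuple
    full_ranks: np.ndarray
    per_repeat_ranks: np.ndarray
    pearson_r: float
    pearson_p: float
    regression_slope: float
    slope_t: float


def subsample(labels: GroupLabels, fraction: float, seed: int) -> GroupLabels:
    """Stratified subsample: ceil(fraction * n) per group, no replacement."""
    if not (0.0 < fraction <= 1.0):
        raise RobustnessError(f"subsample fraction {fraction!r} outside (0, 1]")
    rng = np.random.default_rng(seed)
    kept: dict[str, str] = {}
    for members in (labels.reference_samples, labels.case_samples):
        k = math.ceil(fraction * len(members))
        if k < MIN_SUBSAMPLE_GROUP:
            raise RobustnessError(
                f"fraction {fraction} leaves {k} samples in a group; "
                f">={MIN_SUBSAMPLE_GROUP} required"
            )
        for s in rng.choice(members, size=k, replace=False):
            kept[s] = labels.assignments[s]
    return GroupLabels(kept, labels.reference_group, labels.case_group)


def _gene_ranks(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    pairs: PairMap,
    method: str,
    transform: str,
    combiner: str,
    threshold: float,
    merge_fraction: float,
) -> dict[str, int]:
    scores = score_all(matrix, labels, pairs, method=method, transform=transform)
    attach_scores(scores, combiner=combiner, threshold=threshold)
    ranked = rank_genes(merge_genes(scores, fraction=merge_fraction))
    return {g.pathway_gene: g.rank for g in ranked}


def rank_stability(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    pairs: PairMap,
    n_repeats: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    method: str = "welch",
    transform: str = DEFAULT_TRANSFORM,
    combiner: str = DEFAULT_COMBINER,
    threshold: float = MODE_THRESHOLD,
    merge_fraction: float = MERGE_FRACTION,
) -> RobustnessReport:
    """Run the full pipeline on repeated subsamples and correlate ranks."""
    if n_repeats < 2:
        raise RobustnessError(f"n_repeats must be >=2, got {n_repeats}")
    full = _gene_ranks(matrix, labels, pairs, method, transform, combiner, threshold, merge_fraction)
    genes = tuple(sorted(full))
    gene_pos = {g: i for i, g in enumerate(genes)}
    full_ranks = np.array([full[g] for g in genes], dtype=float)
    repeat_seeds = np.random.SeedSequence(seed).generate_state(n_repeats)
    per_repeat = np.full((len(genes), n_repeats), np.nan)
    xs: list[float] = []
    ys: list[float] = []
    for r, child_seed in enumerate(repeat_seeds):
        sub_labels = subsample(labels, fraction, int(child_seed))
        sub_matrix = matrix.subset_samples(sub_labels.sample_ids)
        try:
            sub = _gene_ranks(
                sub_matrix, sub_labels, pairs, method, transform, combiner, threshold, merge_fraction
            )
        except ValueError as exc:
            raise RobustnessError(f"repeat {r}: no scoreable genes ({exc})") from exc
        for g, rank in sub.items():
            if g in gene_pos:
                per_repeat[gene_pos[g], r] = rank
                xs.append(full[g])
                ys.append(float(rank))
    x = np.array(xs)
    y = np.array(ys)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RobustnessError("too little rank variation to correlate")
    if np.array_equal(x, y):
        # identity limit (e.g. fraction = 1): the correlation and slope of a
        # vector with itself are 1 by definition; avoid sqrt rounding noise
        r_val, p_val, slope, slope_t = 1.0, 0.0, 1.0, float("inf")
    else:
        r_val, p_val = stats.pearsonr(x, y)
        reg = stats.linregress(x, y)
        slope = reg.slope
        slope_t = float("inf") if reg.stderr == 0 else reg.slope / reg.stderr
    log.info(
        "rank stability over %d repeats (fraction %.2f): r=%.4f slope=%.4f t=%.2f",
        n_repeats, fraction, r_val, slope, slope_t,
    )
    return RobustnessReport(
        n_repeats=n_repeats,
        subsample_fraction=fraction,
        seed=seed,
        genes=genes,
        full_ranks=full_ranks,
        per_repeat_ranks=per_repeat,
        pearson_r=float(r_val),
        pearson_p=float(p_val),
        regression_slope=float(slope),
        slope_t=float(slope_t),
    )


def write_report(report: RobustnessReport, path) -> None:
    """Write the per-gene rank summary plus a commented summary header."""
    import pandas as pd

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# pearson_r={:.10g}\tregression_slope={:.10g}\tslope_t={:.10g}\t"
            "n_repeats={}\tfraction={:.10g}\tseed={}\n".format(
                report.pearson_r,
                report.regression_slope,
                report.slope_t,
                report.n_repeats,
                report.subsample_fraction,
                report.seed,
            )
        )
        rows = []
        for i, gene in enumerate(report.genes):
            ranks = report.per_repeat_ranks[i]
            ok = ranks[~np.isnan(ranks)]
            rows.append(
                {
                    "gene": gene,
                    "full_rank": int(report.full_ranks[i]),
                    "mean_subsample_rank": float(np.mean(ok)) if ok.size else float("nan"),
                    "sd_subsample_rank": float(np.std(ok, ddof=1)) if ok.size > 1 else float("nan"),
                    "n_repeats_scored": int(ok.size),
                }
            )
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
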