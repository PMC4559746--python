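"""Region-conditional differential expression and the signed P-score.

For each pathway gene, samples (pooled across both groups) are split at
the fixed UPC threshold 0.5 into a *low region* (expression <= 0.5) and a
*high region* (> 0.5).  Within each region the target gene's expression
is compared between the reference and case groups with a two-sample test
(Welch's t by default), and the two-sided p-value is mapped onto a
bounded, signed *P-score*:

    pscore(p) = sign * x / (x + 2),      x = -log10(p)

The transform is continuous and strictly decreasing in p, equals 0 at
p = 1, reaches the calibration anchor 0.5 at p = 0.01, and saturates
toward 1 as p -> 0.  The sign is positive when the case-group mean in the
region exceeds the reference-group mean and negative when it is lower.
No multiple-testing correction is applied: P-scores feed a continuous
targetability score downstream, not a significance cutoff.

A region is *testable* only with >=2 reference and >=2 case samples;
otherwise the region score is flagged undefined and the pair is excluded
from downstream merging rather than imputed (imputing a score of 0 would
bias |LP| downward and inflate targetability).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression_io import ExpressionMatrix, GroupLabels
from .pathway_map import PairMap

log = logging.getLogger(__name__)

#: region-split threshold on the UPC scale; <= goes to the low region
REGION_THRESHOLD = 0.5

#: p-values are floored here before the log transform so a degenerate
#: zero-variance comparison yields |pscore| < 1 rather than a division error
MIN_PVALUE = 1e-300

#: minimum samples per group per region for a two-sample test
MIN_REGION_GROUP = 2

METHODS = ("welch", "student", "mannwhitney")


class ScoringError(ValueError):
    pass


def _transform_log10_ratio(p: np.ndarray) -> np.ndarray:
    # anchored so that g(0.01) = 2/(2+2) = 0.5
    x = -np.log10(p) + 0.0  # +0.0 turns the -0.0 at p=1 into 0.0
    return x / (x + 2.0)


#: pluggable p-value -> |score| transforms; each maps (0,1] onto [0,1),
#: is strictly decreasing, and hits 0.5 at p = 0.01
TRANSFORMS = {"log10-ratio": _transform_log10_ratio}

DEFAULT_TRANSFORM = "log10-ratio"


@dataclass(frozen=True)
class RegionSplit:
    """Partition of the samples by one pathway gene's expression."""

    pathway_gene: str
    low_samples: frozenset
    high_samples: frozenset


@dataclass(frozen=True)
class RegionScore:
    """Signed P-score of the case/reference contrast within one region.

    ``defined`` is False when either group has fewer than
    :data:`MIN_REGION_GROUP` samples in the region; ``pscore`` is then 0
    and ``pvalue`` is NaN, and the pair is excluded downstream.
    """

    pscore: float
    pvalue: float
    n_ref: int
    n_case: int
    defined: bool


@dataclass
class PairScore:
    """LP/HP scores for one (pathway gene, target gene) pair.

    ``targetability`` and ``mode`` are filled by the targetability
    module; a pair enters merging only if both regions are defined.
    """

    pathway_gene: str
    target_gene: str
    lp: RegionScore
    hp: RegionScore
    targetability: float | None = None
    mode: object = None

    @property
    def defined(self) -> bool:
        return self.lp.defined and self.hp.defined


def split_regions(matrix: ExpressionMatrix, pathway_gene: str) -> RegionSplit:
    """Split samples at 0.5 on the pathway gene's expression.

    The boundary value 0.5 itself belongs to the low region.  Samples of
    both groups are pooled: region membership depends only on the
    pathway gene's value in each sample.
    """
    if pathway_gene not in matrix.data.index:
        raise ScoringError(f"pathway gene '{pathway_gene}' absent from the matrix")
    row = matrix.data.loc[pathway_gene]
    high = frozenset(row.index[row > REGION_THRESHOLD])
    low = frozenset(row.index[row <= REGION_THRESHOLD])
    return RegionSplit(pathway_gene, low, high)


def _block_pvalues(ref: np.ndarray, case: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-values and mean-difference signs, row-wise.

    ``ref`` and ``case`` are (k, n_ref) and (k, n_case) blocks of target
    values.  Degenerate zero-variance rows follow the conventions: equal
    means -> p = 1; unequal means with no variance -> p floored at
    :data:`MIN_PVALUE`.
    """
    if method not in METHODS:
        raise ScoringError(f"unknown test method '{method}'; choose from {METHODS}")
    mean_diff = case.mean(axis=1) - ref.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "mannwhitney":
            res = stats.mannwhitneyu(case, ref, axis=1, alternative="two-sided")
        else:
            res = stats.ttest_ind(case, ref, axis=1, equal_var=(method == "student"))
        p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # 0/0 t statistics (both groups constant) surface as NaN
    p = np.where(np.isfinite(p), p, np.where(mean_diff == 0.0, 1.0, MIN_PVALUE))
    p = np.clip(p, MIN_PVALUE, 1.0)
    return p, np.sign(mean_diff)


def two_sample_pvalue(x, y, method: str = "welch") -> float | None:
    """Two-sided p-value comparing reference values ``x`` to case ``y``.

    Returns ``None`` (the undefined-region signal, not an exception)
    when either side has fewer than two observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_REGION_GROUP or y.size < MIN_REGION_GROUP:
        return None
    p, _ = _block_pvalues(x[None, :], y[None, :], method)
    return float(p[0])


def pscore(pvalue: float, sign: float, transform: str = DEFAULT_TRANSFORM) -> float:
    """Signed P-score of a p-value; magnitude 0.5 corresponds to p = 0.01."""
    if not (0.0 < pvalue <= 1.0):
        raise ScoringError(f"p-value {pvalue!r} outside (0, 1]")
    if sign not in (-1, 0, 1, -1.0, 0.0, 1.0):
        raise ScoringError(f"sign must be -1, 0 or +1, got {sign!r}")
    g = float(TRANSFORMS[transform](np.asarray([max(pvalue, MIN_PVALUE)]))[0])
    return float(sign) * g


def _region_scores(
    tmat: np.ndarray,
    ref_cols: np.ndarray,
    case_cols: np.ndarray,
    method: str,
    transform: str,
) -> list[RegionScore]:
    """Score all rows of ``tmat`` within one region; one entry per row."""
    n_ref, n_case = len(ref_cols), len(case_cols)
    if n_ref < MIN_REGION_GROUP or n_case < MIN_REGION_GROUP:
        return [RegionScore(0.0, float("nan"), n_ref, n_case, False)] * tmat.shape[0]
    p, sign = _block_pvalues(tmat[:, ref_cols], tmat[:, case_cols], method)
    scores = sign * TRANSFORMS[transform](p)
    return [
        RegionScore(float(s), float(pv), n_ref, n_case, True)
        for s, pv in zip(scores, p)
    ]


def score_pair(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    pathway_gene: str,
    target_gene: str,
    method: str = "welch",
    transform: str = DEFAULT_TRANSFORM,
) -> PairScore:
    """Compute LP and HP for a single pair."""
    if target_gene not in matrix.data.index:
        raise ScoringError(f"target gene '{target_gene}' absent from the matrix")
    split = split_regions(matrix, pathway_gene)
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    tmat = matrix.data.loc[[target_gene]].to_numpy()
    region_scores = []
    for region in (split.low_samples, split.high_samples):
        ref_cols = np.array([cols[s] for s in labels.reference_samples if s in region], dtype=int)
        case_cols = np.array([cols[s] for s in labels.case_samples if s in region], dtype=int)
        region_scores.append(_region_scores(tmat, ref_cols, case_cols, method, transform)[0])
    return PairScore(pathway_gene, target_gene, lp=region_scores[0], hp=region_scores[1])


def score_all(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    pairs: PairMap,
    method: str = "welch",
    transform: str = DEFAULT_TRANSFORM,
) -> list[PairScore]:
    """Score every pair whose genes are present in the matrix.

    The region split is computed once per pathway gene and reused for
    all of its targets; within a pathway gene the two-sample tests run
    vectorized over targets.  Pairs referencing missing genes are
    dropped with a logged count.  The result is ordered by (pathway
    gene, target gene) and independent of the input pair order.
    """
    index = set(matrix.gene_ids)
    by_gene: dict[str, list[str]] = defaultdict(list)
    n_dropped = 0
    for pg, tg in pairs.sorted_pairs:
        if pg in index and tg in index:
            by_gene[pg].append(tg)
        else:
            n_dropped += 1
    if not by_gene:
        raise ScoringError("zero scoreable pairs: no pair has both genes in the matrix")
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    ref_ids = labels.reference_samples
    case_ids = labels.case_samples
    out: list[PairScore] = []
    n_undefined = 0
    for pg in sorted(by_gene):
        split = split_regions(matrix, pg)
        targets = by_gene[pg]
        tmat = matrix.data.loc[targets].to_numpy()
        lows, highs = None, None
        for region in (split.low_samples, split.high_samples):
            ref_cols = np.array([cols[s] for s in ref_ids if s in region], dtype=int)
            case_cols = np.array([cols[s] for s in case_ids if s in region], dtype=int)
            scored = _region_scores(tmat, ref_cols, case_cols, method, transform)
            if lows is None:
                lows = scored
            else:
                highs = scored
        for tg, lp, hp in zip(targets, lows, highs):
            ps = PairScore(pg, tg, lp=lp, hp=hp)
            if not ps.defined:
                n_undefined += 1
            out.append(ps)
    log.info(
        "scored %d pairs (%d dropped for missing genes, %d with undefined regions)",
        len(out), n_dropped, n_undefined,
    )
    return out


def write_pair_table(scores: list[PairScore], path) -> None:
    """Write the per-pair score table as TSV.

    Includes targetability/mode columns when they have been attached;
    they are empty otherwise.
    """
    import pandas as pd

    rows = []
    for s in scores:
        rows.append(
            {
                "pathway_gene": s.pathway_gene,
                "target_gene": s.target_gene,
                "n_low_ref": s.lp.n_ref,
                "n_low_case": s.lp.n_case,
                "n_high_ref": s.hp.n_ref,
                "n_high_case": s.hp.n_case,
                "lp_pvalue": s.lp.pvalue,
                "lp_pscore": s.lp.pscore,
                "hp_pvalue": s.hp.pvalue,
                "hp_pscore": s.hp.pscore,
                "defined": s.defined,
                "targetability": "" if s.targetability is None else s.targetability,
                "mode": "" if s.mode is None else s.mode.label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
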