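"""Drug targetability: combining (LP, HP) into scores, modes and gene ranks.

A pathway gene is a promising drug target when its target genes are
transcriptionally abnormal *only while the pathway gene is highly
expressed*: inhibiting the pathway gene is then predicted to restore a
normal transcriptional response.  The pair-level score

    targetability(LP, HP) = |HP| * (1 - |LP|)

captures exactly this: it is maximal (1) when the high-region contrast is
fully significant and the low region looks normal, zero whenever the
high region is unremarkable, and it decays as low-region abnormality
grows (a constitutively abnormal target cannot be restored by lowering
the pathway gene).  The direction of the abnormality does not matter --
only where it occurs -- so the score depends on |LP| and |HP| alone.

Pairs are classified into qualitative *modes of abnormality* by whether
|LP| and |HP| cross the significance threshold 0.5, i.e. p <= 0.01 under
the P-score anchor: ``normal`` (neither), ``high_only`` (HP only -- the
good-target mode), ``low_only`` (LP only) and ``constitutive`` (both).

Per pathway gene, pair scores are merged by averaging the top 5% of its
pairs (at least one), which highlights a gene's most abnormal-but-
restorable targets instead of diluting them across hundreds of quiet
pairs.  Genes are then dense-ranked by merged targetability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .scoring import PairScore

log = logging.getLogger(__name__)

#: |P-score| at which a region counts as significantly abnormal
#: (0.5 corresponds to p = 0.01, the transform's calibration anchor)
MODE_THRESHOLD = 0.5

#: fraction of a gene's pairs merged into its score
MERGE_FRACTION = 0.05


class TargetabilityError(ValueError):
    pass


def _combine_product(lp: float, hp: float) -> float:
    return abs(hp) * (1.0 - abs(lp))


def _combine_difference(lp: float, hp: float) -> float:
    return max(abs(hp) - abs(lp), 0.0)


#: pluggable (LP, HP) -> [0, 1] combiners; all are sign-invariant,
#: increasing in |HP| and decreasing in |LP|
COMBINERS = {"product": _combine_product, "difference": _combine_difference}

DEFAULT_COMBINER = "product"


@dataclass(frozen=True)
class ModeLabel:
    """Qualitative (LP, HP) pattern with per-region directions."""

    label: str  # normal | high_only | low_only | constitutive
    direction_low: str  # up | down | none
    direction_high: str


@dataclass
class GeneScore:
    """Merged targetability of one pathway gene.

    ``n_pairs_used`` is ``max(1, ceil(fraction * n_pairs_total))``;
    ``rank`` is a 1-based dense rank (1 = most targetable), assigned by
    :func:`rank_genes`.
    """

    pathway_gene: str
    merged_targetability: float
    n_pairs_total: int
    n_pairs_used: int
    rank: int | None = None


def _check_range(name: str, value: float) -> None:
    if not (-1.0 <= value <= 1.0) or not math.isfinite(value):
        raise TargetabilityError(f"{name}={value!r} outside [-1, 1]")


def drug_targetability(lp: float, hp: float, combiner: str = DEFAULT_COMBINER) -> float:
    """Pair-level drug targetability from the two signed region scores."""
    _check_range("lp", lp)
    _check_range("hp", hp)
    if combiner not in COMBINERS:
        raise TargetabilityError(f"unknown combiner '{combiner}'; choose from {sorted(COMBINERS)}")
    return COMBINERS[combiner](lp, hp)


def _direction(score: float, threshold: float) -> str:
    if abs(score) < threshold:
        return "none"
    return "up" if score > 0 else "down"


def classify_mode(lp: float, hp: float, threshold: float = MODE_THRESHOLD) -> ModeLabel:
    """Classify the abnormality pattern of a pair.

    ``high_only`` -- abnormal only in the high region -- is the
    good-target mode: lowering the pathway gene moves its samples into
    the region where the target behaves normally.
    """
    _check_range("lp", lp)
    _check_range("hp", hp)
    low_sig = abs(lp) >= threshold
    high_sig = abs(hp) >= threshold
    if high_sig and not low_sig:
        label = "high_only"
    elif high_sig and low_sig:
        label = "constitutive"
    elif low_sig:
        label = "low_only"
    else:
        label = "normal"
    return ModeLabel(label, _direction(lp, threshold), _direction(hp, threshold))


def attach_scores(
    pair_scores: list[PairScore],
    combiner: str = DEFAULT_COMBINER,
    threshold: float = MODE_THRESHOLD,
) -> list[PairScore]:
    """Fill targetability and mode on every defined pair (in place)."""
    for ps in pair_scores:
        if ps.defined:
            ps.targetability = drug_targetability(ps.lp.pscore, ps.hp.pscore, combiner)
            ps.mode = classify_mode(ps.lp.pscore, ps.hp.pscore, threshold)
    return pair_scores


def merge_gene(pair_scores: list[PairScore], fraction: float = MERGE_FRACTION) -> GeneScore:
    """Merge one pathway gene's pair scores into a single value.

    The ``k = max(1, ceil(fraction * n))`` largest pair targetabilities
    are averaged.  Ties at the cutoff are broken by the smaller |LP|,
    then lexicographic target gene id, so the merge is deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise TargetabilityError(f"merge fraction {fraction!r} outside (0, 1]")
    defined = [p for p in pair_scores if p.defined and p.targetability is not None]
    if not defined:
        raise TargetabilityError("no defined pairs to merge")
    genes = {p.pathway_gene for p in defined}
    if len(genes) != 1:
        raise TargetabilityError(f"merge_gene got pairs for several genes: {sorted(genes)}")
    defined.sort(key=lambda p: (-p.targetability, abs(p.lp.pscore), p.target_gene))
    n = len(defined)
    k = max(1, math.ceil(fraction * n))
    merged = float(np.mean([p.targetability for p in defined[:k]]))
    return GeneScore(defined[0].pathway_gene, merged, n_pairs_total=n, n_pairs_used=k)


def merge_genes(pair_scores: list[PairScore], fraction: float = MERGE_FRACTION) -> list[GeneScore]:
    """Merge pairs gene by gene; genes with zero defined pairs are omitted."""
    by_gene: dict[str, list[PairScore]] = {}
    for ps in pair_scores:
        by_gene.setdefault(ps.pathway_gene, []).append(ps)
    out: list[GeneScore] = []
    n_skipped = 0
    for gene in sorted(by_gene):
        try:
            out.append(merge_gene(by_gene[gene], fraction))
        except TargetabilityError:
            n_skipped += 1
    if n_skipped:
        log.info("%d pathway gene(s) without defined pairs omitted from merging", n_skipped)
    if not out:
        raise TargetabilityError("no pathway gene has any defined pair")
    return out


def rank_genes(gene_scores: list[GeneScore]) -> list[GeneScore]:
    """Dense-rank genes by merged targetability, descending.

    Exact ties share a rank; output order is by rank then gene symbol,
    so it is independent of input order.
    """
    if not gene_scores:
        raise TargetabilityError("no gene scores to rank")
    ordered = sorted(gene_scores, key=lambda g: (-g.merged_targetability, g.pathway_gene))
    out: list[GeneScore] = []
    rank = 0
    previous: float | None = None
    for g in ordered:
        if previous is None or g.merged_targetability != previous:
            rank += 1
            previous = g.merged_targetability
        out.append(replace(g, rank=rank))
    return out


@dataclass(frozen=True)
class Histogram2D:
    """2D histogram of pairs over (LP, HP) in [-1, 1]^2.

    ``counts[i, j]`` is the number of defined pairs with LP in bin i and
    HP in bin j; ``log_counts`` is ``log10(counts + 1)``.  Bins are
    half-open ``[lo, lo + w)`` except the final bin, which is closed so
    that scores of exactly 1 are kept.
    """

    counts: np.ndarray
    log_counts: np.ndarray
    edges: np.ndarray


def heatmap_histogram(pair_scores: list[PairScore], bin_width: float = 0.05) -> Histogram2D:
    """Bin the defined pairs' (LP, HP) values on a regular grid."""
    if bin_width <= 0:
        raise TargetabilityError(f"bin width must be positive, got {bin_width!r}")
    defined = [p for p in pair_scores if p.defined]
    if not defined:
        raise TargetabilityError("no defined pairs to histogram")
    n_bins = max(1, round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    lp = np.array([p.lp.pscore for p in defined])
    hp = np.array([p.hp.pscore for p in defined])
    counts, _, _ = np.histogram2d(lp, hp, bins=[edges, edges])
    counts = counts.astype(int)
    return Histogram2D(counts, np.log10(counts + 1.0), edges)


def write_histogram(hist: Histogram2D, path) -> None:
    """Write the log10(count+1) grid as TSV, bin lower edges as labels."""
    import pandas as pd

    labels = [f"{e:.6g}" for e in hist.edges[:-1]]
    df = pd.DataFrame(hist.log_counts, index=labels, columns=labels)
    df.to_csv(path, sep="\t", index_label="lp_bin\\hp_bin")


def write_gene_table(gene_scores: list[GeneScore], path) -> None:
    import pandas as pd

    rows = [
        {
            "pathway_gene": g.pathway_gene,
            "merged_targetability": g.merged_targetability,
            "n_pairs_total": g.n_pairs_total,
            "n_pairs_used": g.n_pairs_used,
            "rank": g.rank,
        }
        for g in sorted(gene_scores, key=lambda g: (g.rank or 0, g.pathway_gene))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def foldchange_concordance(
    fc_reference: dict,
    fc_experiment: dict,
    cutoff_hi: float = 1.2,
    cutoff_lo: float = 0.8,
) -> tuple[float, float, int]:
    """Concordance of dataset fold changes with a perturbation experiment.

    Genes whose experimental fold change is within ``(cutoff_lo,
    cutoff_hi)`` -- less than a 20% change at the defaults -- are
    discarded; the Pearson correlation of the log2 fold changes of the
    surviving shared genes is returned as ``(r, p, n)``.
    """
    shared = sorted(set(fc_reference) & set(fc_experiment))
    kept = [g for g in shared if fc_experiment[g] > cutoff_hi or fc_experiment[g] < cutoff_lo]
    for g in kept:
        if fc_reference[g] <= 0 or fc_experiment[g] <= 0:
            raise TargetabilityError(f"non-positive fold change for gene '{g}'")
    if len(kept) < 3:
        raise TargetabilityError(
            f"insufficient genes after cutoff: {len(kept)} survive, >=3 required"
        )
    ref = np.log2([fc_reference[g] for g in kept])
    exp = np.log2([fc_experiment[g] for g in kept])
    r, p = stats.pearsonr(ref, exp)
    return float(r), float(p), len(kept)
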