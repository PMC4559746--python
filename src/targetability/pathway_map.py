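"""Building (pathway gene, target gene) pairs from pathway units and TF target sets.

A *pathway gene* is a signaling molecule that connects, within its
pathway unit, to one or more transcription factors (TFs).  The target
genes of those TFs serve as the transcriptional readout of the pathway
gene.  This module reads the two inputs -- a flat pathway_gene -> TF
edge list, and TF -> target gene sets in Broad GMT format -- and forms
the deduplicated set of scoreable pairs.

MSigDB TFT set names encode the factor plus motif metadata (for example
``V$E2F1_Q6``), so set names are matched against pathway-unit TF symbols
verbatim by default; an optional alias table (``tf_symbol<TAB>gmt_set_name``)
maps between the two vocabularies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)


class PathwayMapError(ValueError):
    """Malformed pathway-unit / GMT input or an empty pair set."""


@dataclass(frozen=True)
class PathwayUnitMap:
    """Map pathway gene -> set of TF symbols reachable within its unit."""

    units: dict

    def __post_init__(self) -> None:
        for gene, tfs in self.units.items():
            if not gene:
                raise PathwayMapError("blank pathway gene symbol")
            if not tfs:
                raise PathwayMapError(f"pathway gene '{gene}' maps to no TFs")
        object.__setattr__(
            self, "units", {g: frozenset(tfs) for g, tfs in self.units.items()}
        )


@dataclass(frozen=True)
class TFTargetMap:
    """Map TF (or GMT set name) -> set of target gene symbols."""

    sets: dict

    def __post_init__(self) -> None:
        for tf, targets in self.sets.items():
            if not targets:
                raise PathwayMapError(f"TF set '{tf}' has no target genes")
        object.__setattr__(
            self, "sets", {tf: frozenset(t) for tf, t in self.sets.items()}
        )


@dataclass(frozen=True)
class PairMap:
    """The (pathway gene, target gene) pairs to score.

    ``provenance`` records, for every pair, the TF set name(s) through
    which the target was reached.  Self-pairs (a pathway gene as its own
    target) are never present: the region split and the response would
    be the same measurement.
    """

    pairs: frozenset
    provenance: dict

    @property
    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    @property
    def pathway_genes(self) -> list[str]:
        return sorted({g for g, _ in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


def read_gmt(path) -> TFTargetMap:
    """Read TF target-gene sets from a Broad-dialect GMT file.

    Each line is ``set_name<TAB>description<TAB>member1<TAB>member2...``.
    Members are deduplicated; repeated set names are merged by union with
    a warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayMapError(
                    f"{path}: line {lineno}: expected set_name, description "
                    f"and >=1 member, found {len(fields)} fields"
                )
            name = fields[0].strip()
            members = {m.strip() for m in fields[2:] if m.strip()}
            if not name:
                raise PathwayMapError(f"{path}: line {lineno}: blank set name")
            if not members:
                raise PathwayMapError(f"{path}: line {lineno}: set '{name}' has no members")
            if name in sets:
                log.warning("%s: duplicate gene set '%s'; members merged by union", path.name, name)
                sets[name] |= members
            else:
                sets[name] = members
    if not sets:
        raise PathwayMapError(f"{path}: no gene sets")
    return TFTargetMap(sets)


def read_pathway_units(path) -> PathwayUnitMap:
    """Read a pathway_gene<TAB>tf edge list (optional header auto-skipped)."""
    path = Path(path)
    units: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2:
                raise PathwayMapError(
                    f"{path}: line {lineno}: expected pathway_gene<TAB>tf"
                )
            gene, tf = fields
            if lineno == 1 and gene.lower() == "pathway_gene" and tf.lower() == "tf":
                continue
            if not gene or not tf:
                raise PathwayMapError(f"{path}: line {lineno}: blank symbol")
            units.setdefault(gene, set()).add(tf)
    if not units:
        raise PathwayMapError(f"{path}: no pathway-unit edges")
    return PathwayUnitMap(units)


def read_aliases(path) -> dict:
    """Read an optional ``tf_symbol<TAB>gmt_set_name`` alias table."""
    path = Path(path)
    aliases: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise PathwayMapError(
                    f"{path}: line {lineno}: expected tf_symbol<TAB>gmt_set_name"
                )
            aliases[fields[0]] = fields[1]
    return aliases


def build_pairs(units: PathwayUnitMap, tft: TFTargetMap, aliases: dict | None = None) -> PairMap:
    """Form all (pathway gene, target gene) pairs.

    For pathway gene ``g`` the targets are the union over its unit's TFs
    of each TF's target set; ``(g, g)`` self-pairs are excluded.  TFs
    with no matching GMT set (after optional aliasing) are skipped with a
    logged count.
    """
    aliases = aliases or {}
    pairs: dict[tuple[str, str], set[str]] = {}
    missing_tfs: set[str] = set()
    for gene in sorted(units.units):
        for tf in sorted(units.units[gene]):
            set_name = aliases.get(tf, tf)
            targets = tft.sets.get(set_name)
            if targets is None:
                missing_tfs.add(tf)
                continue
            for target in targets:
                if target == gene:
                    continue
                pairs.setdefault((gene, target), set()).add(set_name)
    if missing_tfs:
        log.warning(
            "%d pathway-unit TF(s) absent from the GMT sets and skipped (e.g. %s)",
            len(missing_tfs), ", ".join(sorted(missing_tfs)[:3]),
        )
    if not pairs:
        raise PathwayMapError("no pathway gene-target gene pairs")
    return PairMap(
        pairs=frozenset(pairs),
        provenance={p: frozenset(tfs) for p, tfs in pairs.items()},
    )
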