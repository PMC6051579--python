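"""DNA-barcode locus scoring by terminal-clade resolution.

A candidate barcode locus is judged by how well its single-locus tree
resolves each putative species as a *terminal clade*: the smallest clade
containing all samples of the species.  Per species the outcome is one of

* ``supported`` — ≥2 samples, monophyletic, subtending bootstrap ≥ the floor
  (score = that bootstrap percentage);
* ``monophyletic_below_threshold`` — monophyletic but under the floor
  (score kept, but contributes to neither summary number);
* ``resolved_unscored`` — the lineage is resolved but no support value can
  be computed (a single sample);
* ``not_resolved`` — samples do not form a clade (or the clade carries no
  support annotation);
* ``not_tested`` — the species has no samples in that tree.

A locus is then scored by the **number of terminal clades** (supported +
resolved-unscored) and the **total score** (sum of bootstrap values over
supported clades only), and loci are ranked on that pair.  Monophyly is
assessed in the unrooted (bipartition) sense after excluding any declared
outgroup tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Iterable, Optional, Sequence

import pandas as pd

from .morpho import SPECIES
from .phylo import SupportTree

__all__ = [
    "STATUSES",
    "SupportThresholds",
    "CladeRecord",
    "LocusScore",
    "TaxonMap",
    "assess_terminal_clades",
    "score_locus",
    "rank_loci",
    "score_table_report",
    "parse_score_table",
    "load_printed_support_table",
    "read_taxon_map_tsv",
    "write_taxon_map_tsv",
]

STATUSES = (
    "supported",
    "monophyletic_below_threshold",
    "resolved_unscored",
    "not_resolved",
    "not_tested",
)

_SCORED = ("supported", "monophyletic_below_threshold")


@dataclass(frozen=True)
class SupportThresholds:
    """Support floors for calling a clade well-supported.

    ``pp_floor`` applies only when a second (posterior-probability) support
    annotation is supplied alongside bootstrap; the in-repo bootstrap stage
    produces bootstrap-style supports only.
    """

    ml_bs_floor: float = 75.0
    pp_floor: float = 95.0

    def __post_init__(self) -> None:
        for v in (self.ml_bs_floor, self.pp_floor):
            if not 0 <= v <= 100:
                raise ValueError(f"threshold {v} outside [0, 100]")


@dataclass(frozen=True)
class CladeRecord:
    species: str
    status: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status in _SCORED) != (self.score is not None):
            raise ValueError(f"status {self.status!r} must carry a score iff it is scored")
        if self.score is not None and not 0 <= self.score <= 100:
            raise ValueError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class LocusScore:
    locus_name: str
    n_terminal_clades: int
    total_score: float

    def __post_init__(self) -> None:
        if self.n_terminal_clades < 0 or self.total_score < 0:
            raise ValueError("scores must be non-negative")
        if self.total_score > 100 * max(self.n_terminal_clades, 0):
            raise ValueError("total_score exceeds 100 per terminal clade")


@dataclass
class TaxonMap:
    """tip label → species assignment, with the species universe to score."""

    tip_to_species: dict[str, str]
    species: tuple[str, ...] = SPECIES

    def __post_init__(self) -> None:
        unknown = set(self.tip_to_species.values()) - set(self.species)
        if unknown:
            raise ValueError(f"mapped species outside the species universe: {sorted(unknown)}")

    def tips_of(self, species: str) -> set[str]:
        return {t for t, s in self.tip_to_species.items() if s == species}


def assess_terminal_clades(tree: SupportTree, taxon_map: TaxonMap,
                           thresholds: SupportThresholds = SupportThresholds(),
                           outgroup_tips: Iterable[str] = ()) -> list[CladeRecord]:
    """Assess per-species terminal-clade resolution on one support tree."""
    tips = set(tree.tip_labels)
    unmapped = tips - set(taxon_map.tip_to_species)
    if unmapped:
        raise ValueError(f"tree tips missing from the taxon map: {sorted(unmapped)}")
    outgroup = set(outgroup_tips) & tips
    ingroup = frozenset(tips - outgroup)

    # project tree splits onto the ingroup universe once
    ref = min(ingroup) if ingroup else None
    projected: dict[frozenset, Optional[float]] = {}
    for split, support in tree.bipartitions(include_trivial=True).items():
        side = frozenset(split & ingroup)
        if ref in side:
            side = ingroup - side
        prev = projected.get(side)
        if side not in projected or prev is None or (support is not None and support > prev):
            projected[side] = support

    records: list[CladeRecord] = []
    for species in taxon_map.species:
        species_tips = taxon_map.tips_of(species) & tips
        if not species_tips:
            records.append(CladeRecord(species, "not_tested"))
            continue
        if len(species_tips) == 1:
            records.append(CladeRecord(species, "resolved_unscored"))
            continue
        if species_tips <= outgroup:
            universe, target = frozenset(tips), frozenset(species_tips)
            sides = tree.bipartitions(include_trivial=True)
            key = tree.canonical_split(target)
            monophyletic = key in sides or len(species_tips) in (1, len(tips))
            support = sides.get(key)
        else:
            target = frozenset(species_tips & ingroup)
            if ref in target:
                target = ingroup - target
            monophyletic = target in projected or len(species_tips) in (1, len(ingroup))
            support = projected.get(target)
        if not monophyletic:
            records.append(CladeRecord(species, "not_resolved"))
        elif support is None:
            records.append(CladeRecord(species, "not_resolved"))
        elif support >= thresholds.ml_bs_floor:
            records.append(CladeRecord(species, "supported", support))
        else:
            records.append(CladeRecord(species, "monophyletic_below_threshold", support))
    return records


def score_locus(records: Sequence[CladeRecord], locus_name: str = "",
                thresholds: SupportThresholds = SupportThresholds()) -> LocusScore:
    """Summarize one locus: clade count and cumulative bootstrap total.

    A scored record counts as well-supported iff its score meets the floor
    (so raising the floor can only shrink both numbers); resolved-unscored
    lineages count toward the clade total but contribute no score.
    """
    seen: set[str] = set()
    for r in records:
        if r.species in seen:
            raise ValueError(f"duplicate record for {r.species!r}")
        seen.add(r.species)
    n_clades = 0
    total = 0.0
    for r in records:
        if r.status == "resolved_unscored":
            n_clades += 1
        elif r.status in _SCORED and r.score >= thresholds.ml_bs_floor:
            n_clades += 1
            total += r.score
    return LocusScore(locus_name=locus_name, n_terminal_clades=n_clades, total_score=total)


def rank_loci(scores: Sequence[LocusScore]) -> list[LocusScore]:
    """Rank loci, best first: most terminal clades, then highest total score,
    alphabetical on ties."""
    if not scores:
        raise ValueError("no locus scores to rank")
    return sorted(scores, key=lambda s: (-s.n_terminal_clades, -s.total_score, s.locus_name))


# ---------------------------------------------------------------------------
# Report rendering / parsing
# ---------------------------------------------------------------------------

_CELL_CODES = {"not_resolved": "NR", "resolved_unscored": "R*", "not_tested": "NT"}


def _format_cell(record: CladeRecord) -> str:
    if record.status in _SCORED:
        return f"{record.score:g}"
    return _CELL_CODES[record.status]


def _parse_cell(cell: str, species: str, thresholds: SupportThresholds) -> CladeRecord:
    cell = cell.strip()
    if cell in ("NR",):
        return CladeRecord(species, "not_resolved")
    if cell in ("R*", "NR*"):  # both codes denote a resolved lineage without a computable support
        return CladeRecord(species, "resolved_unscored")
    if cell == "NT":
        return CladeRecord(species, "not_tested")
    score = float(cell)
    status = "supported" if score >= thresholds.ml_bs_floor else "monophyletic_below_threshold"
    return CladeRecord(species, status, score)


def score_table_report(per_locus_records: dict[str, Sequence[CladeRecord]],
                       thresholds: SupportThresholds = SupportThresholds()) -> pd.DataFrame:
    """Matrix report (taxa × loci) with summary rows.

    Cells carry the support score, or NR / R* / NT codes; the bottom rows
    are TOTAL SCORE and NUMBER OF TERMINAL CLADES computed via
    :func:`score_locus`.
    """
    loci = list(per_locus_records)
    species_order: list[str] = []
    for records in per_locus_records.values():
        for r in records:
            if r.species not in species_order:
                species_order.append(r.species)
    table: dict[str, dict[str, str]] = {locus: {} for locus in loci}
    for locus, records in per_locus_records.items():
        for r in records:
            table[locus][r.species] = _format_cell(r)
    rows = []
    for sp in species_order:
        rows.append({"taxon": sp, **{locus: table[locus].get(sp, "NT") for locus in loci}})
    for label, attr in (("TOTAL SCORE", "total_score"), ("NUMBER OF TERMINAL CLADES", "n_terminal_clades")):
        summary = {"taxon": label}
        for locus in loci:
            value = getattr(score_locus(per_locus_records[locus], locus, thresholds), attr)
            summary[locus] = f"{value:g}"
        rows.append(summary)
    return pd.DataFrame(rows, columns=["taxon"] + loci)


def parse_score_table(table: pd.DataFrame,
                      thresholds: SupportThresholds = SupportThresholds()) -> dict[str, list[CladeRecord]]:
    """Inverse of :func:`score_table_report` (summary rows are recomputed,
    not trusted)."""
    loci = [c for c in table.columns if c != "taxon"]
    out: dict[str, list[CladeRecord]] = {locus: [] for locus in loci}
    for _, row in table.iterrows():
        if row["taxon"] in ("TOTAL SCORE", "NUMBER OF TERMINAL CLADES"):
            continue
        for locus in loci:
            out[locus].append(_parse_cell(str(row[locus]), row["taxon"], thresholds))
    return out


def load_printed_support_table(thresholds: SupportThresholds = SupportThresholds()) -> dict[str, list[CladeRecord]]:
    """The published per-taxon support matrix for ITS, tef1α, rpb1, rpb2 and
    the four-locus concatenation, shipped as package data."""
    text = resources.files("ganokit.data").joinpath("table4_support.tsv").read_text("utf-8")
    table = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    return parse_score_table(table, thresholds)


# ---------------------------------------------------------------------------
# Taxon map I/O
# ---------------------------------------------------------------------------

def write_taxon_map_tsv(taxon_map: TaxonMap, path) -> None:
    df = pd.DataFrame(
        [{"tip_label": t, "species": s} for t, s in taxon_map.tip_to_species.items()],
        columns=["tip_label", "species"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_taxon_map_tsv(path, species: Optional[tuple[str, ...]] = None) -> TaxonMap:
    """Read a tip→species map; the species universe defaults to the file's
    species in order of first appearance."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tip_label", "species"} <= set(df.columns):
        raise ValueError("taxon map TSV needs tip_label and species columns")
    if species is None:
        species = tuple(dict.fromkeys(df.species))
    return TaxonMap(dict(zip(df.tip_label, df.species)), species=species)
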