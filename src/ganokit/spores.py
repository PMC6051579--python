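"""Basidiospore morphometrics.

Spores are measured in µm: length from the base to the truncated apex, width
at the widest point from outer wall to outer wall.  Two per-spore shape
statistics are used:

* spore shape index, SSI = 100 · width / length — the percentage of the
  length explained by the width ("squat" spores score high);
* Q-ratio, Q = length / width — elongation.

The two are exact reciprocals: SSI · Q = 100 for every spore.  Taxon
summaries average the *per-spore* statistics (mean of SSI, mean of Q), never
the ratio of mean dimensions, and report dimensions in the conventional
"mean (min–max)" form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .morpho import round_half_away

__all__ = [
    "SporeMeasurement",
    "SporeSummary",
    "spore_shape_index",
    "q_ratio",
    "summarize_spores",
    "read_spores_tsv",
    "write_spores_tsv",
    "summary_table",
]


@dataclass(frozen=True)
class SporeMeasurement:
    """One spore's length × width in µm."""

    specimen_id: str
    spore_id: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError(
                f"spore {self.spore_id!r}: dimensions must be positive "
                f"({self.length} x {self.width})"
            )
        if self.width > self.length:
            # Broadly ovoid-to-elliptical spores are expected longer than
            # wide; an inverted pair is suspicious but not impossible.
            warnings.warn(
                f"spore {self.spore_id!r}: width {self.width} exceeds length {self.length}",
                stacklevel=2,
            )


def spore_shape_index(length: float, width: float) -> float:
    """Per-spore shape index, 100·(width/length)."""
    if not (length > 0 and width > 0):
        raise ValueError(f"dimensions must be positive ({length} x {width})")
    return 100.0 * width / length


def q_ratio(length: float, width: float) -> float:
    """Per-spore elongation ratio, length/width."""
    if not (length > 0 and width > 0):
        raise ValueError(f"dimensions must be positive ({length} x {width})")
    return length / width


@dataclass(frozen=True)
class SporeSummary:
    n: int
    mean_length: float
    min_length: float
    max_length: float
    mean_width: float
    min_width: float
    max_width: float
    mean_ssi: float
    mean_q: float

    def format_length(self, dp: int = 1) -> str:
        return _mean_range(self.mean_length, self.min_length, self.max_length, dp)

    def format_width(self, dp: int = 1) -> str:
        return _mean_range(self.mean_width, self.min_width, self.max_width, dp)


def _mean_range(mean: float, lo: float, hi: float, dp: int) -> str:
    fmt = f"{{:.{dp}f}}"
    return f"{fmt.format(round_half_away(mean, dp))} ({fmt.format(round_half_away(lo, dp))}–{fmt.format(round_half_away(hi, dp))})"


def summarize_spores(measurements: Sequence[SporeMeasurement]) -> SporeSummary:
    """Summarize a set of spore measurements.

    mean_ssi and mean_q are means of the per-spore statistics; with
    unpublished raw data these generally differ (slightly) from the ratio of
    the printed mean dimensions.
    """
    if not measurements:
        raise ValueError("no spore measurements to summarize")
    lengths = [m.length for m in measurements]
    widths = [m.width for m in measurements]
    ssi = [spore_shape_index(m.length, m.width) for m in measurements]
    q = [q_ratio(m.length, m.width) for m in measurements]
    n = len(measurements)
    return SporeSummary(
        n=n,
        mean_length=sum(lengths) / n,
        min_length=min(lengths),
        max_length=max(lengths),
        mean_width=sum(widths) / n,
        min_width=min(widths),
        max_width=max(widths),
        mean_ssi=sum(ssi) / n,
        mean_q=sum(q) / n,
    )


def summary_table(groups: dict[str, Sequence[SporeMeasurement]],
                  group_letters: Optional[dict[str, dict[str, str]]] = None,
                  dp: int = 1) -> pd.DataFrame:
    """Render per-taxon summaries as a table of "mean (min–max)" strings.

    ``group_letters`` optionally attaches externally computed means-separation
    letters per taxon and statistic (keys: length, width, ssi, q); the letters
    are rendered verbatim, no test is run here.
    """
    rows = []
    for name, measurements in groups.items():
        s = summarize_spores(list(measurements))
        letters = (group_letters or {}).get(name, {})

        def cell(value: str, stat: str) -> str:
            suffix = letters.get(stat, "")
            return f"{value} {suffix}".strip()

        rows.append({
            "taxon": name,
            "n": s.n,
            "length": cell(s.format_length(dp), "length"),
            "width": cell(s.format_width(dp), "width"),
            "ssi": cell(f"{round_half_away(s.mean_ssi, dp):.{dp}f}", "ssi"),
            "q_ratio": cell(f"{round_half_away(s.mean_q, dp):.{dp}f}", "q"),
        })
    return pd.DataFrame(rows, columns=["taxon", "n", "length", "width", "ssi", "q_ratio"])


_SPORE_COLUMNS = ["specimen_id", "spore_id", "length_um", "width_um"]


def write_spores_tsv(measurements: Iterable[SporeMeasurement], path) -> None:
    df = pd.DataFrame(
        [
            {"specimen_id": m.specimen_id, "spore_id": m.spore_id,
             "length_um": m.length, "width_um": m.width}
            for m in measurements
        ],
        columns=_SPORE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_spores_tsv(path) -> list[SporeMeasurement]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_SPORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spores TSV missing columns {sorted(missing)}")
    return [
        SporeMeasurement(str(r.specimen_id), str(r.spore_id), float(r.length_um), float(r.width_um))
        for r in df.itertuples(index=False)
    ]
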