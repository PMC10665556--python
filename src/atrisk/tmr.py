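"""Tetramer arm: antigen-specific CD4+ T-cell frequencies.

Magnetic enrichment concentrates rare tetramer-positive (Tmr+) cells;
1% of each sample is reserved before enrichment to count total CD4+
T cells. The frequency per million CD4 cells is

    F = (1e6 * tmr_events) / (100 * cd4_pre)

where ``tmr_events`` is the Tmr+ count in the enriched fraction and
``cd4_pre`` the CD4+ count in the reserved 1% fraction (the factor 100
scales the 1% aliquot back to the full sample). Group contrasts use
the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._stats import wilcoxon_rank_sum
from .types import DEFAULT_PAIRS, GroupComparison

log = logging.getLogger("atrisk")

CIT_ANTIGENS = ("cit-aggrecan", "cit-CILP", "cit-vimentin/fibrinogen", "cit-enolase")
CONTROL_ANTIGEN = "influenza"
ANTIGENS = CIT_ANTIGENS + (CONTROL_ANTIGEN,)


@dataclass
class TmrCount:
    """Per-subject, per-antigen event counts from one staining run."""

    subject: str
    group: str
    antigen: str
    tmr_events: int
    cd4_pre: int

    def __post_init__(self) -> None:
        if self.tmr_events < 0 or self.cd4_pre < 0:
            raise ValueError("counts must be non-negative")


def frequency(count: TmrCount) -> float:
    """Tmr+ frequency per million CD4 T cells."""
    if count.cd4_pre == 0:
        raise ValueError(f"subject {count.subject}: cd4_pre is zero, frequency undefined")
    return (1_000_000 * count.tmr_events) / (100 * count.cd4_pre)


def frequency_table(counts) -> pd.DataFrame:
    """Per-subject, per-antigen frequency table from TmrCount records.

    Subjects with ``cd4_pre == 0`` are excluded (logged), not imputed.
    """
    rows = []
    for c in counts:
        if c.cd4_pre == 0:
            log.warning("subject %s antigen %s excluded: cd4_pre=0", c.subject, c.antigen)
            continue
        rows.append((c.subject, c.group, c.antigen, frequency(c)))
    return pd.DataFrame(rows, columns=["subject", "group", "antigen", "frequency"])


def combine_cit(freqs: dict, mode: str = "sum") -> float:
    """Combined citrullinated-antigen frequency for one subject.

    ``freqs`` maps antigen name to frequency; all four citrullinated
    specificities must be present (the influenza control is excluded).
    ``mode`` is "sum" (default) or "mean".
    """
    missing = [a for a in CIT_ANTIGENS if a not in freqs]
    if missing:
        raise ValueError(f"missing cit antigens: {missing}")
    vals = [freqs[a] for a in CIT_ANTIGENS]
    if mode == "sum":
        return float(sum(vals))
    if mode == "mean":
        return float(sum(vals) / len(vals))
    raise ValueError(f"unknown mode {mode!r}")


def combined_cit_table(freq_table: pd.DataFrame, mode: str = "sum") -> pd.DataFrame:
    """Per-subject combined cit frequency from a frequency_table output."""
    rows = []
    for (subject, group), sub in freq_table.groupby(["subject", "group"], sort=True):
        freqs = dict(zip(sub["antigen"], sub["frequency"]))
        rows.append((subject, group, combine_cit(freqs, mode=mode)))
    return pd.DataFrame(rows, columns=["subject", "group", "frequency"])


def compare_groups(values: pd.Series, groups: pd.Series, pairs=DEFAULT_PAIRS,
                   outcome: str = "frequency") -> list[GroupComparison]:
    """Two-sided Wilcoxon rank-sum comparisons between group pairs."""
    out = []
    for ga, gb in pairs:
        a = values[groups == ga].to_numpy(dtype=float)
        b = values[groups == gb].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            log.warning("comparison %s vs %s skipped: fewer than 2 subjects", ga, gb)
            continue
        stat, p = wilcoxon_rank_sum(a, b)
        out.append(GroupComparison(
            comparison=f"{ga}_vs_{gb}", outcome=outcome, estimate=stat, p=p,
            method="wilcoxon_rank_sum",
        ))
    return out


def read_counts(path) -> list[TmrCount]:
    """Read TmrCount rows from CSV (subject, group, antigen, tmr_events, cd4_pre)."""
    df = pd.read_csv(path)
    return [
        TmrCount(str(r.subject), str(r.group), str(r.antigen), int(r.tmr_events), int(r.cd4_pre))
        for r in df.itertuples(index=False)
    ]
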