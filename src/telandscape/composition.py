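"""Genome-composition bookkeeping: repeat content as percent of assembly."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .models import TECopy


def genome_percentages(
    total_lengths_bp: Mapping[str, float], genome_bp: float, digits: int = 2
) -> dict[str, float]:
    """Percent of the assembly occupied by each repeat group.

    ``total_lengths_bp`` maps a label (superfamily, order, ...) to its summed
    base pairs; percentages are rounded to ``digits`` decimals, matching the
    precision of published repeat-content tables.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    return {
        k: round(100.0 * v / genome_bp, digits) for k, v in total_lengths_bp.items()
    }


def superfamily_lengths(tes: Iterable[TECopy]) -> dict[str, int]:
    """Summed interval length per superfamily (each copy counted as-is)."""
    out: dict[str, int] = defaultdict(int)
    for te in tes:
        out[te.superfamily] += te.interval.length
    return dict(out)


def composition_table(tes: Iterable[TECopy], genome_bp: float, digits: int = 2):
    """Copy number, total length and genome percentage per superfamily."""
    import pandas as pd

    counts: dict[str, int] = defaultdict(int)
    lengths: dict[str, int] = defaultdict(int)
    for te in tes:
        counts[te.superfamily] += 1
        lengths[te.superfamily] += te.interval.length
    pct = genome_percentages(lengths, genome_bp, digits)
    return pd.DataFrame({
        "n_copies": pd.Series(counts),
        "total_bp": pd.Series(lengths),
        "genome_pct": pd.Series(pct),
    }).sort_values("total_bp", ascending=False)
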