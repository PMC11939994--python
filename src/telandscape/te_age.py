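"""Kimura two-parameter divergence, LTR insertion dating and age landscapes.

The Kimura 2-parameter (K2P) distance corrects observed transition (P) and
transversion (Q) fractions for multiple hits:

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Divergence of a copy from its family consensus proxies its age; for an
intact LTR retrotransposon, the two long terminal repeats are identical at
insertion, so the time since insertion is

    T = K_LTR / (2 * mu)

with mu the per-site per-year substitution rate (default 1.3e-8, a standard
plant rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class AgeParams:
    """mu: substitutions/site/year; bin_width and max_divergence in
    divergence (substitutions/site) units."""

    mu: float = 1.3e-8
    bin_width: float = 0.01
    max_divergence: float = 0.40

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not (0 < self.bin_width <= self.max_divergence):
            raise ValueError("require 0 < bin_width <= max_divergence")


@dataclass
class DivergenceRecord:
    te_id: str
    superfamily: str
    divergence: float
    aligned_bp: int

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.aligned_bp <= 0:
            raise ValueError("aligned_bp must be > 0")


def kimura2p(P: float, Q: float) -> float:
    """K2P distance from transition fraction P and transversion fraction Q.

    Raises ValueError outside the formula's domain (saturated alignments
    with 2P + Q >= 1 or 2Q >= 1 have no finite K2P distance).
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise ValueError(
            f"K2P distance saturated/undefined for P={P}, Q={Q} "
            "(require 2P+Q < 1 and 2Q < 1)"
        )
    return -0.5 * math.log(a * math.sqrt(b))


def insertion_time(K_ltr: float, params: Optional[AgeParams] = None) -> float:
    """Years since insertion from LTR-LTR divergence: T = K / (2 mu)."""
    params = params or AgeParams()
    if K_ltr < 0:
        raise ValueError("K_ltr must be >= 0")
    return K_ltr / (2.0 * params.mu)


def insertion_time_mya(K_ltr: float, params: Optional[AgeParams] = None) -> float:
    """Insertion age in million years, rounded to 3 decimals."""
    return round(insertion_time(K_ltr, params) / 1e6, 3)


def age_landscape(
    records: Iterable[DivergenceRecord], params: Optional[AgeParams] = None
) -> pd.DataFrame:
    """Divergence-binned aligned bp per superfamily (a repeat landscape).

    Rows are half-open divergence bins [i*w, (i+1)*w) with the last bin
    closed at max_divergence; records above max_divergence are dropped (they
    should already have been filtered on import). Total matrix mass equals
    the summed aligned_bp of the retained records.
    """
    params = params or AgeParams()
    w = params.bin_width
    n_bins = int(math.ceil(params.max_divergence / w))
    edges = [round(i * w, 10) for i in range(n_bins + 1)]
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins)]

    cells: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.divergence > params.max_divergence:
            continue
        i = min(int(rec.divergence / w), n_bins - 1)
        col = cells.setdefault(rec.superfamily, np.zeros(n_bins, dtype=np.int64))
        col[i] += rec.aligned_bp
    df = pd.DataFrame(cells, index=pd.Index(labels, name="divergence_bin"))
    return df.sort_index(axis=1)


def read_divergence_tsv(path) -> list[DivergenceRecord]:
    """TSV with columns te_id, superfamily, divergence, aligned_bp."""
    df = pd.read_csv(path, sep="\t")
    return [
        DivergenceRecord(str(r.te_id), str(r.superfamily),
                         float(r.divergence), int(r.aligned_bp))
        for r in df.itertuples(index=False)
    ]


def date_ltr_table(path, params: Optional[AgeParams] = None) -> pd.DataFrame:
    """Date intact LTR elements from a TSV of te_id, ltr_divergence."""
    params = params or AgeParams()
    df = pd.read_csv(path, sep="\t")
    df["years"] = [insertion_time(k, params) for k in df["ltr_divergence"]]
    df["mya"] = [round(y / 1e6, 3) for y in df["years"]]
    return df
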