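"""Virtual-screening performance measures on labelled ranked lists.

A ranked library is the outcome of a screen: T compounds ordered best-first
by docking score, of which P_T are positive controls (known ligands) and the
rest presumed-inactive decoys.  The enrichment factor at depth n is

    EF_n = P_n / (n * P_T / T)

where P_n counts positives among the top n — the observed hit count divided
by the count expected under random ordering.  EF_T is always 1; the maximum
attainable value is T / P_T.

Pose filtering is folded into a ranking by a stable partition: compounds
whose poses failed the filters move to the bottom of the list (positives and
decoys alike), survivors keep their relative order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class RankedEntry:
    compound_id: str
    score: float  # lower = better, docking-score convention
    is_positive: bool
    passed_filters: bool = True


@dataclass
class RankedLibrary:
    """Best-first ranking of a screened library.

    Construct with :meth:`from_entries` to sort by score (ties broken
    lexicographically by compound id, for reproducibility).
    """

    entries: list[RankedEntry] = field(default_factory=list)

    @classmethod
    def from_entries(cls, entries: list[RankedEntry]) -> "RankedLibrary":
        ordered = sorted(entries, key=lambda e: (e.score, e.compound_id))
        return cls(entries=ordered)

    @property
    def T(self) -> int:
        return len(self.entries)

    @property
    def P_T(self) -> int:
        return sum(e.is_positive for e in self.entries)

    @classmethod
    def from_table(cls, path: str | Path) -> "RankedLibrary":
        """Read (compound_id, score, label, passed) from TSV/CSV."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        entries = [
            RankedEntry(compound_id=str(r.compound_id), score=float(r.score),
                        is_positive=bool(r.label), passed_filters=bool(r.passed))
            for r in df.itertuples()
        ]
        return cls.from_entries(entries)


def top_n_hits(lib: RankedLibrary, n: int) -> int:
    """Number of positive controls among the top n ranked compounds."""
    if not (1 <= n <= lib.T):
        raise ValueError(f"n must be in [1, {lib.T}], got {n}")
    return sum(e.is_positive for e in lib.entries[:n])


def enrichment_factor(lib: RankedLibrary, n: int) -> float:
    """EF_n = P_n / (n * P_T / T)."""
    if not (1 <= n <= lib.T):
        raise ValueError(f"n must be in [1, {lib.T}], got {n}")
    if lib.P_T == 0:
        raise ValueError("library has no positive controls")
    p_n = top_n_hits(lib, n)
    return p_n / (n * lib.P_T / lib.T)


def apply_filter_to_ranking(lib: RankedLibrary) -> RankedLibrary:
    """Move every compound that failed the filters to the bottom of the list.

    Stable partition: survivors keep relative order at the top, non-passers
    keep relative order below them.  T and P_T are unchanged; the operation
    is idempotent.
    """
    passed = [e for e in lib.entries if e.passed_filters]
    failed = [e for e in lib.entries if not e.passed_filters]
    return RankedLibrary(entries=passed + failed)


def percentile_ranks(lib: RankedLibrary) -> dict[str, float]:
    """Percentile rank of every compound: 100 * r / T with 1-based rank r.

    The convention is "fraction of the library at or above this rank", so the
    best compound of 100 sits at the 1st percentile and a compound at the
    40th percentile is in the top 40%.
    """
    T = lib.T
    return {e.compound_id: 100.0 * r / T
            for r, e in enumerate(lib.entries, 1)}


def metrics_table(lib: RankedLibrary, depths: tuple[int, ...] = (10, 20, 40)) -> pd.DataFrame:
    """Hit counts and enrichment factors at the given depths, as a table."""
    rows = []
    for n in depths:
        if n > lib.T:
            continue
        rows.append({"n": n, "hits": top_n_hits(lib, n),
                     "P_T": lib.P_T, "T": lib.T,
                     "EF": enrichment_factor(lib, n)})
    return pd.DataFrame(rows)
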