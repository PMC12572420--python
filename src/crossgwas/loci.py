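"""LD clumping, known-locus database construction and novel-locus screening.

A *novel* locus is a significant meta-analysis SNP lying at least 500 kb from
every previously reported index variant on its chromosome. The known-locus
database is built by greedily clumping each contributing study's suggestive
hits (p < 5e-6 by default) into independent index variants (r^2 < 0.001
within a 10,000-kb window) and taking the union of positions over studies.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ClumpParams",
    "IndexVariant",
    "LdMatrix",
    "KnownLocusDB",
    "ld_clump",
    "build_known_db",
    "screen_novel",
]


@dataclass(frozen=True)
class ClumpParams:
    """Greedy-clumping thresholds: pairwise r^2, window size, p-value entry cut."""

    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    p_threshold: float = 5e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0 or self.p_threshold <= 0:
            raise ValueError("window_kb and p_threshold must be positive")


@dataclass(frozen=True)
class IndexVariant:
    snp_id: str
    chrom: str
    pos: int
    p: float


class LdMatrix:
    """Sparse symmetric pairwise r^2 store with unit diagonal.

    Absent pairs are treated as r^2 = 0 (unlinked), which matches how
    clumping consumes reference-panel LD exports that only list correlated
    pairs.
    """

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError("r2 must be in [0, 1]")
        if a != b:
            self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "LdMatrix":
        """Build from a long table with columns snp_a, snp_b, r2."""
        m = cls()
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
            m.set(str(a), str(b), float(r2))
        return m

    def to_table(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def ld_clump(
    records: pd.DataFrame, ld: LdMatrix, params: ClumpParams
) -> list[IndexVariant]:
    """Greedy p-value-ordered clumping into independent index variants.

    Only rows with p < ``params.p_threshold`` enter. Walking SNPs by
    ascending p, a candidate is accepted iff no already-accepted SNP on the
    same chromosome both lies within ``window_kb`` AND has r^2 >=
    ``r2_threshold`` with it — i.e. a SNP is clumped away only when it is
    simultaneously near and correlated with a better index.

    ``records`` needs columns snp, chrom, pos, p.
    """
    df = records.loc[records["p"] < params.p_threshold, ["snp", "chrom", "pos", "p"]]
    df = df.sort_values(["p", "snp"], kind="mergesort")
    window = params.window_kb * 1000.0
    accepted: list[IndexVariant] = []
    by_chrom: dict[str, tuple[list[int], list[str]]] = {}
    for snp, chrom, pos, p in df.itertuples(index=False):
        chrom = str(chrom)
        pos = int(pos)
        positions, names = by_chrom.setdefault(chrom, ([], []))
        lo = bisect.bisect_left(positions, pos - window)
        hi = bisect.bisect_right(positions, pos + window)
        clumped = any(
            ld.get(str(snp), names[i]) >= params.r2_threshold
            for i in range(lo, hi)
        )
        if clumped:
            continue
        i = bisect.bisect_left(positions, pos)
        positions.insert(i, pos)
        names.insert(i, str(snp))
        accepted.append(IndexVariant(str(snp), chrom, pos, float(p)))
    return accepted


@dataclass
class KnownLocusDB:
    """Chromosome -> sorted index-variant positions, with provenance rows."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "snp", "source_study"])
    )

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.entries.loc[self.entries["chrom"] == chrom, "pos"]
        return np.sort(sub.to_numpy(dtype=np.int64))

    def nearest_distance(self, chrom: str, pos: int) -> Optional[int]:
        """Distance in bp to the nearest known index on ``chrom``; None if empty."""
        arr = self.positions(chrom)
        if arr.size == 0:
            return None
        i = np.searchsorted(arr, pos)
        cands = []
        if i > 0:
            cands.append(abs(pos - int(arr[i - 1])))
        if i < arr.size:
            cands.append(abs(pos - int(arr[i])))
        return min(cands)

    def to_table(self) -> pd.DataFrame:
        return self.entries.sort_values(["chrom", "pos"]).reset_index(drop=True)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "KnownLocusDB":
        return cls(entries=df[["chrom", "pos", "snp", "source_study"]].copy())


def build_known_db(
    per_study_records: Mapping[str, pd.DataFrame],
    ld: LdMatrix,
    params: Optional[ClumpParams] = None,
) -> KnownLocusDB:
    """Clump each study's suggestive hits and union the index positions.

    Duplicate (chrom, pos) entries across studies collapse to one row; the
    provenance column keeps the comma-joined contributing studies.
    """
    params = params or ClumpParams()
    rows = []
    for study, df in per_study_records.items():
        for iv in ld_clump(df, ld, params):
            rows.append((iv.chrom, iv.pos, iv.snp_id, study))
    if not rows:
        return KnownLocusDB()
    ent = pd.DataFrame(rows, columns=["chrom", "pos", "snp", "source_study"])
    ent = (
        ent.groupby(["chrom", "pos"], as_index=False)
        .agg({"snp": "first", "source_study": lambda s: ",".join(sorted(set(s)))})
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return KnownLocusDB(entries=ent)


def screen_novel(
    meta_hits: pd.DataFrame,
    db: KnownLocusDB,
    min_dist_kb: float = 500.0,
    p_threshold: float = 5e-8,
) -> pd.DataFrame:
    """Return the subset of significant meta-analysis hits that are novel.

    A hit is novel iff its chromosome is absent from the database or the
    nearest known index variant lies at distance >= ``min_dist_kb`` kb
    (a hit exactly at the boundary counts as novel).
    """
    hits = meta_hits[meta_hits["p"] < p_threshold]
    min_dist = min_dist_kb * 1000.0
    keep = []
    for t in hits.itertuples():
        d = db.nearest_distance(str(t.chrom), int(t.pos))
        keep.append(d is None or d >= min_dist)
    return hits[np.asarray(keep, dtype=bool)].reset_index(drop=True)
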