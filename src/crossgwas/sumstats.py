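"""Reading, validation, harmonization and interconversion of GWAS summary statistics.

Summary statistics are the universal currency of the pipeline: per-SNP effect
size (beta, on the liability/log-odds scale), standard error, p-value,
effect-allele frequency and an effective-sample-size weight. Studies that
publish only Z-scores and weights are converted back to (beta, se) with the
standard sample-size-scheme formulas::

    se   = 1 / sqrt(2 * f * (1 - f) * (weight + z^2))
    beta = se * z

where ``f`` is the effect-allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SumStatRecord",
    "StudyMeta",
    "ReadResult",
    "EafDecision",
    "ColumnMappingError",
    "read_sumstats",
    "write_sumstats",
    "records_to_frame",
    "frame_to_records",
    "recover_beta_se",
    "align_to_reference",
    "filter_eaf_consistency",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the on-disk format
CANONICAL_COLUMNS = [
    "snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "weight", "z",
]


class ColumnMappingError(ValueError):
    """A required summary-statistics column could not be resolved."""


@dataclass(frozen=True)
class StudyMeta:
    """Identity and size of one contributing study."""

    study_id: str
    n_cases: int = 0
    n_controls: int = 0
    build: str = "hg38"

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("case/control counts must be non-negative")

    @property
    def n_effective(self) -> float:
        """Effective sample size 4 / (1/cases + 1/controls) of a case-control study."""
        if self.n_cases == 0 or self.n_controls == 0:
            return float(self.n_cases + self.n_controls)
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association summary in one study.

    ``beta`` is signed with respect to the effect allele ``ea``; ``z`` is
    optional and, when present alongside ``beta`` and ``se``, must equal
    ``beta / se``.
    """

    snp_id: str
    chrom: str
    pos: int
    ea: str
    oa: str
    eaf: Optional[float] = None
    beta: Optional[float] = None
    se: Optional[float] = None
    p: Optional[float] = None
    weight: Optional[float] = None
    z: Optional[float] = None

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if self.ea == self.oa:
            errs.append("effect and other allele are identical")
        if self.se is not None and not self.se > 0:
            errs.append("se must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            errs.append("eaf outside [0, 1]")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            errs.append("p outside (0, 1]")
        if self.weight is not None and self.weight < 0:
            errs.append("weight must be non-negative")
        if self.beta is not None and self.se is not None and self.z is not None:
            if abs(self.z - self.beta / self.se) > 1e-6 * max(1.0, abs(self.z)):
                errs.append("z inconsistent with beta/se")
        return errs


@dataclass
class ReadResult:
    """Outcome of reading a summary-statistics file: records plus a rejection report."""

    records: list[SumStatRecord]
    n_total: int
    rejects: list[tuple[int, str]]  # (1-based data line number, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejects, columns=["line", "reason"])


@dataclass(frozen=True)
class EafDecision:
    """Keep/drop decision of the cross-study allele-frequency consistency filter."""

    keep: bool
    eaf_min: float
    eaf_max: float
    status: str  # "checked" or "unchecked"


def recover_beta_se(z, eaf, weight):
    """Recover (beta, se) from a Z-score, effect-allele frequency and weight.

    Accepts scalars or numpy arrays (broadcast). ``se = 1/sqrt(2 f (1-f)
    (weight + z^2))`` and ``beta = se * z``; this inverts the sample-size
    weighting scheme so that ``beta / se`` round-trips ``z`` exactly.
    """
    z = np.asarray(z, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise ValueError("degenerate effect-allele frequency (must be in (0,1))")
    if np.any(weight <= 0.0):
        raise ValueError("weight must be positive")
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (weight + z * z))
    beta = se * z
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def _complement(allele: str) -> Optional[str]:
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None


def _flip(record: SumStatRecord) -> SumStatRecord:
    return replace(
        record,
        ea=record.oa,
        oa=record.ea,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
        beta=None if record.beta is None else -record.beta,
        z=None if record.z is None else -record.z,
    )


def align_to_reference(
    record: SumStatRecord, ref_ea: str, ref_oa: str
) -> tuple[Optional[SumStatRecord], str]:
    """Orient a record to a reference allele pair.

    Returns ``(aligned_record, status)`` with status one of ``unchanged``,
    ``flipped``, ``complement``, ``complement_flipped`` or ``excluded``
    (record is None). Strand-complement rescue is attempted only for
    non-palindromic allele pairs; palindromic mismatches are excluded since
    strand cannot be resolved from alleles alone.
    """
    ea, oa = record.ea.upper(), record.oa.upper()
    ref_ea, ref_oa = ref_ea.upper(), ref_oa.upper()
    if (ea, oa) == (ref_ea, ref_oa):
        return record, "unchanged"
    if (ea, oa) == (ref_oa, ref_ea):
        return _flip(record), "flipped"
    if not _is_palindromic(ea, oa):
        cea, coa = _complement(ea), _complement(oa)
        if cea is not None and coa is not None:
            if (cea, coa) == (ref_ea, ref_oa):
                return replace(record, ea=cea, oa=coa), "complement"
            if (cea, coa) == (ref_oa, ref_ea):
                return _flip(replace(record, ea=cea, oa=coa)), "complement_flipped"
    return None, "excluded"


def filter_eaf_consistency(
    eafs: Sequence[float], max_diff: float = 0.2
) -> EafDecision:
    """Cross-study effect-allele-frequency consistency check for one SNP.

    Drops the SNP iff max(eaf) - min(eaf) is strictly greater than
    ``max_diff`` (default 0.2). A single-study SNP cannot be checked and is
    kept with status ``unchecked``.
    """
    eafs = [e for e in eafs if e is not None and not math.isnan(e)]
    if len(eafs) < 2:
        v = eafs[0] if eafs else float("nan")
        return EafDecision(keep=True, eaf_min=v, eaf_max=v, status="unchecked")
    lo, hi = min(eafs), max(eafs)
    return EafDecision(keep=(hi - lo) <= max_diff, eaf_min=lo, eaf_max=hi,
                       status="checked")


_REQUIRED = ["snp", "chrom", "pos", "ea", "oa"]
_NUMERIC = ["eaf", "beta", "se", "p", "weight", "z"]


def read_sumstats(
    path, column_map: Optional[Mapping[str, str]] = None, sep: str = "\t"
) -> ReadResult:
    """Read a delimited summary-statistics file into validated records.

    ``column_map`` maps canonical names (``snp``, ``chrom``, ``pos``, ``ea``,
    ``oa``, ``eaf``, ``beta``, ``se``, ``p``, ``weight``, ``z``) to the file's
    column names; canonical names already present in the header need not be
    mapped. The file must resolve the five identity columns and at least one
    of {beta+se, z+weight+eaf, p+beta}. Malformed rows are rejected with a
    line-numbered reason, never silently dropped. Gzip input is transparent.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    colmap = dict(column_map or {})
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
    df = df.rename(columns=rename)
    for canon in _REQUIRED:
        if canon not in df.columns:
            raise ColumnMappingError(f"required column '{canon}' not found in header")
    have = set(df.columns)
    if not ({"beta", "se"} <= have or {"z", "weight", "eaf"} <= have
            or {"p", "beta"} <= have):
        raise ColumnMappingError(
            "need at least one of beta+se, z+weight+eaf, or p+beta column groups")

    records: list[SumStatRecord] = []
    rejects: list[tuple[int, str]] = []
    numeric_cols = [c for c in _NUMERIC if c in df.columns]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        vals: dict[str, Optional[float]] = {}
        bad = None
        for c in numeric_cols:
            raw = row[c]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                vals[c] = None
                continue
            try:
                vals[c] = float(raw)
            except (TypeError, ValueError):
                bad = f"unparseable numeric in column '{c}': {raw!r}"
                break
        if bad is None:
            try:
                pos = int(float(row["pos"]))
            except (TypeError, ValueError):
                bad = f"unparseable position: {row['pos']!r}"
        if bad is not None:
            rejects.append((i, bad))
            continue
        rec = SumStatRecord(
            snp_id=str(row["snp"]), chrom=str(row["chrom"]), pos=pos,
            ea=str(row["ea"]).upper(), oa=str(row["oa"]).upper(),
            **{k: vals.get(k) for k in _NUMERIC},
        )
        errs = rec.validation_errors()
        if errs:
            rejects.append((i, "; ".join(errs)))
        else:
            records.append(rec)
    return ReadResult(records=records, n_total=len(df), rejects=rejects)


def records_to_frame(records: Iterable[SumStatRecord]) -> pd.DataFrame:
    """Records -> canonical DataFrame (columns in on-disk order)."""
    rows = [
        (r.snp_id, r.chrom, r.pos, r.ea, r.oa, r.eaf, r.beta, r.se, r.p,
         r.weight, r.z)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SumStatRecord]:
    def opt(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return [
        SumStatRecord(
            snp_id=str(t.snp), chrom=str(t.chrom), pos=int(t.pos),
            ea=str(t.ea), oa=str(t.oa), eaf=opt(t.eaf), beta=opt(t.beta),
            se=opt(t.se), p=opt(t.p), weight=opt(t.weight), z=opt(t.z),
        )
        for t in df.itertuples(index=False)
    ]


def write_sumstats(records_or_frame, path, sep: str = "\t") -> None:
    """Write records (or a canonical frame) as delimited text with header."""
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
    else:
        df = records_to_frame(records_or_frame)
    df.to_csv(path, sep=sep, index=False)
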