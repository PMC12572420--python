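"""Multi-study meta-analysis of per-SNP effects.

Effects are pooled with inverse-variance fixed effects (weights
``w_i = 1/se_i^2``). Between-study heterogeneity is quantified with
Cochran's Q on k-1 degrees of freedom and the I^2 percentage
``max(0, (Q - (k-1))/Q) * 100``. When a SNP shows substantial
heterogeneity — Q-test p < 0.1 AND I^2 > 50%, both strict — the
DerSimonian–Laird random-effects estimate is reported instead, with the
method-of-moments between-study variance::

    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))

and restated weights ``w*_i = 1/(se_i^2 + tau^2)``.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FixedEffectsResult",
    "RandomEffectsResult",
    "fixed_effects",
    "heterogeneity",
    "random_effects_dl",
    "meta_pipeline",
    "two_sided_p",
]

#: output columns of the pooled table
META_COLUMNS = [
    "snp", "chrom", "pos", "ea", "oa", "eaf_pooled", "beta", "se", "z", "p",
    "mlog10p", "k", "q_stat", "q_p", "i2", "tau2", "model",
]


class FixedEffectsResult(NamedTuple):
    beta: float
    se: float
    z: float
    p: float


class RandomEffectsResult(NamedTuple):
    beta: float
    se: float
    tau2: float
    z: float
    p: float


def two_sided_p(z) -> np.ndarray | float:
    """Two-sided normal p-value, computed in log-space for extreme |z|.

    The result is floored at the smallest positive double (~5e-324) so it
    stays inside (0, 1]; use :func:`neglog10_p` when the magnitude matters.
    """
    z = np.asarray(z, dtype=float)
    p = np.exp(np.log(2.0) + stats.norm.logsf(np.abs(z)))
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    return float(p) if p.ndim == 0 else p


def neglog10_p(z) -> np.ndarray | float:
    """-log10 of the two-sided normal p-value, stable for any |z|."""
    z = np.asarray(z, dtype=float)
    m = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    return float(m) if m.ndim == 0 else m


def _check_inputs(betas, ses):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("meta-analysis needs at least one study")
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    return betas, ses


def fixed_effects(betas, ses) -> FixedEffectsResult:
    """Inverse-variance fixed-effects pooling of per-study (beta, se)."""
    betas, ses = _check_inputs(betas, ses)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return FixedEffectsResult(beta, se, z, two_sided_p(z))


def heterogeneity(betas, ses, beta_pooled: float):
    """Cochran's Q, its p-value on k-1 df, and I^2 in [0, 100].

    With a single study Q is undefined: returns ``(nan, nan, 0.0)``.
    """
    betas, ses = _check_inputs(betas, ses)
    k = betas.size
    if k < 2:
        return float("nan"), float("nan"), 0.0
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - beta_pooled) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, q_p, i2


def random_effects_dl(betas, ses) -> RandomEffectsResult:
    """DerSimonian–Laird random-effects pooling (k >= 2)."""
    betas, ses = _check_inputs(betas, ses)
    if betas.size < 2:
        raise ValueError("random-effects pooling needs at least two studies")
    w = 1.0 / ses**2
    sw = np.sum(w)
    beta_f = np.sum(w * betas) / sw
    q = np.sum(w * (betas - beta_f) ** 2)
    df = betas.size - 1
    c = sw - np.sum(w**2) / sw
    tau2 = max(0.0, float((q - df) / c)) if c > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = beta / se
    return RandomEffectsResult(beta, se, tau2, z, two_sided_p(z))


def _align_long(long: pd.DataFrame) -> pd.DataFrame:
    """Vectorized allele alignment of a concatenated per-study table.

    The first occurrence of each SNP (concatenation order) defines the
    reference orientation. Swapped-allele rows get beta negated and eaf
    complemented; rows that match in neither orientation (after an implicit
    strand complement for non-palindromic pairs) are dropped.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def comp_series(s: pd.Series) -> pd.Series:
        return s.map(lambda a: "".join(comp.get(b, "?") for b in a))

    ref = long.drop_duplicates("snp")[["snp", "ea", "oa"]].rename(
        columns={"ea": "ref_ea", "oa": "ref_oa"})
    df = long.merge(ref, on="snp", how="left")
    cea, coa = comp_series(df["ea"]), comp_series(df["oa"])
    same = (df["ea"] == df["ref_ea"]) & (df["oa"] == df["ref_oa"])
    swap = (df["ea"] == df["ref_oa"]) & (df["oa"] == df["ref_ea"])
    palin = cea == df["oa"]
    csame = ~palin & (cea == df["ref_ea"]) & (coa == df["ref_oa"])
    cswap = ~palin & (cea == df["ref_oa"]) & (coa == df["ref_ea"])
    keep = same | swap | csame | cswap
    neg = (swap | cswap) & ~same
    df = df[keep].copy()
    neg = neg[keep].to_numpy()
    df.loc[neg, "beta"] = -df.loc[neg, "beta"].to_numpy()
    if "eaf" in df.columns:
        df.loc[neg, "eaf"] = 1.0 - df.loc[neg, "eaf"].to_numpy()
    df["ea"] = df["ref_ea"]
    df["oa"] = df["ref_oa"]
    return df.drop(columns=["ref_ea", "ref_oa"])


def meta_pipeline(
    studies: Mapping[str, pd.DataFrame],
    eaf_max_diff: float = 0.2,
    fallback_q_p: float = 0.1,
    fallback_i2: float = 50.0,
    min_studies: int = 1,
) -> pd.DataFrame:
    """Align, frequency-filter and pool per-SNP effects across studies.

    Parameters
    ----------
    studies
        Mapping of study id to a canonical summary-statistics frame with at
        least columns snp, chrom, pos, ea, oa, beta, se (eaf and weight
        optional but needed for the frequency filter / pooled frequency).
    eaf_max_diff
        SNPs whose cross-study effect-allele-frequency range strictly exceeds
        this value are excluded (mirrors the AVERAGEFREQ/MINMAXFREQ guard).
    fallback_q_p, fallback_i2
        The random-effects fallback triggers iff q_p < fallback_q_p AND
        i2 > fallback_i2, both strict.

    Returns the pooled table (one row per SNP) with heterogeneity statistics
    and a ``model`` flag in {"fixed", "random"}.
    """
    frames = []
    for sid, df in studies.items():
        d = df.copy()
        d["study"] = sid
        frames.append(d)
    if not frames:
        raise ValueError("no studies supplied")
    long = pd.concat(frames, ignore_index=True)
    long = _align_long(long)

    if "eaf" in long.columns:
        grp = long.groupby("snp")["eaf"]
        rng = (grp.max() - grp.min()).fillna(0.0)
        nchecked = grp.count()
        bad = rng.index[(rng > eaf_max_diff) & (nchecked >= 2)]
        long = long[~long["snp"].isin(set(bad))]

    w = 1.0 / long["se"].to_numpy() ** 2
    long = long.assign(_w=w, _wb=w * long["beta"].to_numpy(),
                       _wb2=w * long["beta"].to_numpy() ** 2, _w2=w * w)
    if "weight" in long.columns and long["weight"].notna().any():
        fw = long["weight"].fillna(0.0).to_numpy()
    else:
        fw = w
    if "eaf" in long.columns:
        long = long.assign(_fw=fw, _fwf=fw * long["eaf"].to_numpy())

    agg_spec = {"_w": "sum", "_wb": "sum", "_wb2": "sum", "_w2": "sum",
                "study": "count"}
    if "_fw" in long.columns:
        agg_spec.update({"_fw": "sum", "_fwf": "sum"})
    first = long.groupby("snp", sort=False).first()[
        [c for c in ("chrom", "pos", "ea", "oa") if c in long.columns]]
    agg = long.groupby("snp", sort=False).agg(agg_spec)
    agg = agg.rename(columns={"study": "k"})
    if min_studies > 1:
        agg = agg[agg["k"] >= min_studies]

    sw, swb, swb2 = agg["_w"].to_numpy(), agg["_wb"].to_numpy(), agg["_wb2"].to_numpy()
    sw2, k = agg["_w2"].to_numpy(), agg["k"].to_numpy()
    beta_f = swb / sw
    se_f = 1.0 / np.sqrt(sw)
    q = np.maximum(swb2 - swb**2 / sw, 0.0)
    with np.errstate(invalid="ignore"):
        q_p = np.where(k >= 2, stats.chi2.sf(q, np.maximum(k - 1, 1)), np.nan)
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / np.where(q > 0, q, 1.0))
                      * 100.0, 0.0)
    i2 = np.where(k >= 2, i2, 0.0)

    fallback = (k >= 2) & (q_p < fallback_q_p) & (i2 > fallback_i2)
    tau2 = np.zeros_like(beta_f)
    beta, se = beta_f.copy(), se_f.copy()
    if fallback.any():
        c = sw - sw2 / sw
        t2 = np.where(c > 0, np.maximum(0.0, (q - (k - 1)) / np.where(c > 0, c, 1.0)),
                      0.0)
        tau2 = np.where(fallback, t2, 0.0)
        flagged = set(agg.index[fallback])
        sub = long[long["snp"].isin(flagged)].copy()
        t2map = pd.Series(tau2, index=agg.index)
        sub_t2 = sub["snp"].map(t2map).to_numpy()
        ws = 1.0 / (sub["se"].to_numpy() ** 2 + sub_t2)
        sub = sub.assign(_ws=ws, _wsb=ws * sub["beta"].to_numpy())
        ragg = sub.groupby("snp", sort=False).agg({"_ws": "sum", "_wsb": "sum"})
        ragg = ragg.reindex(agg.index[fallback])
        beta[fallback] = (ragg["_wsb"] / ragg["_ws"]).to_numpy()
        se[fallback] = 1.0 / np.sqrt(ragg["_ws"].to_numpy())

    z = beta / se
    out = first.reindex(agg.index).reset_index().rename(columns={"index": "snp"})
    out["eaf_pooled"] = (agg["_fwf"] / agg["_fw"]).to_numpy() if "_fw" in agg else np.nan
    out["beta"], out["se"], out["z"] = beta, se, z
    out["p"] = two_sided_p(z)
    out["mlog10p"] = neglog10_p(z)
    out["k"] = k
    out["q_stat"], out["q_p"], out["i2"], out["tau2"] = q, q_p, i2, tau2
    out["q_stat"] = np.where(k >= 2, out["q_stat"], np.nan)
    out["model"] = np.where(fallback, "random", "fixed")
    return out[[c for c in META_COLUMNS if c in out.columns]]
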