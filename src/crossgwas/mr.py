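"""Bidirectional two-sample Mendelian randomization with a sensitivity battery.

Instruments are genome-wide suggestive SNPs for the exposure, LD-clumped and
filtered to instrument strength F = (beta_exp/se_exp)^2 > 10, then harmonized
against the outcome summary statistics (palindromic SNPs with ambiguous
frequency are dropped). Per-instrument Wald ratios beta_out/beta_exp are
combined with:

* IVW — inverse-variance weighted mean of ratios; the SE is inflated
  multiplicatively by sqrt(Q/(n-1)) when Cochran's Q exceeds its degrees of
  freedom (overdispersion-aware fixed effects).
* MR-Egger — weighted regression of beta_out on beta_exp with a free
  intercept capturing directional pleiotropy; intercept p from a t
  distribution on n-2 df.
* Weighted median — robust to up to 50% invalid weight; SE by seeded
  parametric bootstrap.
* Simple and weighted mode — presumptive extras, mode of the kernel-smoothed
  ratio distribution.
* MR-PRESSO global test — parametric simulation of the leave-one-out
  residual sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .loci import ClumpParams, LdMatrix, ld_clump

__all__ = [
    "INSTRUMENT_COLUMNS",
    "MrEstimate",
    "MrReport",
    "DIRECTION_PARAMS",
    "select_instruments",
    "harmonize",
    "ivw",
    "egger",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
    "cochran_q",
    "leave_one_out",
    "presso_global",
    "run_bidirectional",
]

Z95 = 1.959964

INSTRUMENT_COLUMNS = [
    "snp", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out",
    "f_stat",
]

#: per-direction instrument selection thresholds
DIRECTION_PARAMS = {
    "forward": {"p_threshold": 1e-5, "r2": 0.1, "window_kb": 500.0, "f_min": 10.0},
    "reverse": {"p_threshold": 5e-6, "r2": 0.001, "window_kb": 10_000.0,
                "f_min": 10.0},
}


@dataclass(frozen=True)
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


@dataclass
class MrReport:
    exposure: str
    outcome: str
    direction: str
    n_snps: int
    estimates: list[MrEstimate] = field(default_factory=list)
    q_stat: Optional[float] = None
    q_p: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    presso_global_p: Optional[float] = None
    loo: Optional[pd.DataFrame] = None
    loo_pass: Optional[bool] = None
    skipped: Optional[str] = None

    def estimate(self, method: str) -> Optional[MrEstimate]:
        for e in self.estimates:
            if e.method == method:
                return e
        return None


def _ratios(instruments: pd.DataFrame):
    """Per-instrument Wald ratios and first-order SEs; beta_exp == 0 excluded."""
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    ok = bx != 0.0
    bx = bx[ok]
    by = instruments["beta_out"].to_numpy(dtype=float)[ok]
    sy = instruments["se_out"].to_numpy(dtype=float)[ok]
    return by / bx, sy / np.abs(bx), ok


def select_instruments(
    exposure: pd.DataFrame,
    ld: LdMatrix,
    direction: str = "forward",
    exclude: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Clumped, strength-filtered instrument candidates on the exposure side.

    ``exposure`` needs columns snp, chrom, pos, p, beta, se (eaf optional).
    In the reverse direction SNPs in ``exclude`` (the forward-analysis
    instruments) are removed before clumping so the two instrument sets are
    disjoint by construction.
    """
    if direction not in DIRECTION_PARAMS:
        raise ValueError(f"unknown direction {direction!r}")
    par = DIRECTION_PARAMS[direction]
    df = exposure
    if exclude:
        df = df[~df["snp"].isin(exclude)]
    params = ClumpParams(r2_threshold=par["r2"], window_kb=par["window_kb"],
                         p_threshold=par["p_threshold"])
    index = {iv.snp_id for iv in ld_clump(df, ld, params)}
    sel = df[df["snp"].isin(index)].copy()
    f = (sel["beta"] / sel["se"]) ** 2
    sel["f_stat"] = f
    return sel[f > par["f_min"]].reset_index(drop=True)


def harmonize(
    instruments: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Join exposure instruments with outcome effects, aligned to the
    exposure's effect allele.

    Outcome rows with swapped alleles get beta negated and eaf complemented;
    palindromic (A/T, C/G) SNPs whose frequency falls in the ambiguity window
    on either side are dropped, as are SNPs missing from the outcome or with
    irreconcilable alleles. Returns an instrument table with
    :data:`INSTRUMENT_COLUMNS`.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = outcome.drop_duplicates("snp").set_index("snp")
    lo, hi = palindromic_eaf_window
    rows = []
    for t in instruments.itertuples(index=False):
        snp = str(t.snp)
        if snp not in out.index:
            continue
        o = out.loc[snp]
        ea, oa = str(t.ea).upper(), str(t.oa).upper()
        oea, ooa = str(o["ea"]).upper(), str(o["oa"]).upper()
        palindromic = comp.get(ea) == oa
        beta_out, eaf_out = float(o["beta"]), float(o.get("eaf", np.nan))
        if (ea, oa) == (oea, ooa):
            pass
        elif (ea, oa) == (ooa, oea):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not np.isnan(eaf_out) else eaf_out
        elif not palindromic and (comp.get(ea, "?"), comp.get(oa, "?")) == (oea, ooa):
            pass
        elif not palindromic and (comp.get(ea, "?"), comp.get(oa, "?")) == (ooa, oea):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not np.isnan(eaf_out) else eaf_out
        else:
            continue
        eaf_exp = float(getattr(t, "eaf", np.nan))
        if palindromic:
            for f in (eaf_exp, eaf_out):
                if not np.isnan(f) and lo <= f <= hi:
                    beta_out = None
                    break
            if beta_out is None:
                continue
        f_stat = getattr(t, "f_stat", (t.beta / t.se) ** 2)
        rows.append((snp, float(t.beta), float(t.se), beta_out,
                     float(o["se"]), eaf_exp, eaf_out, float(f_stat)))
    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def ivw(instruments: pd.DataFrame) -> MrEstimate:
    """Inverse-variance-weighted causal estimate from Wald ratios."""
    b, s, _ = _ratios(instruments)
    if b.size == 0:
        raise ValueError("no usable instruments (all beta_exp zero or empty)")
    w = 1.0 / s**2
    est = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if b.size >= 2:
        q = float(np.sum(w * (b - est) ** 2))
        phi = q / (b.size - 1)
        if phi > 1.0:  # multiplicative random-effects inflation
            se *= math.sqrt(phi)
    z = est / se
    return MrEstimate("ivw", est, se, 2 * float(stats.norm.sf(abs(z))), int(b.size))


def egger(instruments: pd.DataFrame):
    """MR-Egger weighted regression with intercept.

    Returns ``(slope_estimate, intercept, intercept_se, intercept_p)``.
    All instruments are oriented so beta_exp >= 0 (joint sign flip) before
    the fit; weights are 1/se_out^2. SEs carry the weighted-least-squares
    residual scale RSS/(n-2); p-values from t on n-2 df.
    """
    n = len(instruments)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float).copy()
    by = instruments["beta_out"].to_numpy(dtype=float).copy()
    sy = instruments["se_out"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]
    w = 1.0 / sy**2
    sw, swx, swy = w.sum(), (w * bx).sum(), (w * by).sum()
    swxx, swxy = (w * bx * bx).sum(), (w * bx * by).sum()
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    icpt = (swy - slope * swx) / sw
    resid = by - icpt - slope * bx
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / (n - 2)  # free residual scale, as in weighted least squares
    se_slope = math.sqrt(sigma2 * sw / denom)
    se_icpt = math.sqrt(sigma2 * swxx / denom)
    p_slope = 2 * float(stats.t.sf(abs(slope / se_slope), n - 2))
    p_icpt = 2 * float(stats.t.sf(abs(icpt / se_icpt), n - 2))
    return (MrEstimate("egger", float(slope), se_slope, p_slope, n),
            float(icpt), se_icpt, p_icpt)


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b, w = b[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, b))


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of Wald ratios (weights 1/se_j^2), bootstrap SE."""
    b, s, _ = _ratios(instruments)
    if b.size < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    w = 1.0 / s**2
    est = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, s, size=(n_boot, b.size))
    boots = np.array([_weighted_median(d, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    z = est / se if se > 0 else np.inf
    return MrEstimate("weighted_median", est, se,
                      2 * float(stats.norm.sf(abs(z))), int(b.size))


def _mode_estimate(b: np.ndarray, s: np.ndarray, w: Optional[np.ndarray],
                   phi: float = 1.0) -> float:
    # mode of the normal-kernel density of ratio estimates (Hartwig-style)
    mad = np.median(np.abs(b - np.median(b))) / stats.norm.ppf(0.75)
    h = max(phi * 0.9 * min(np.std(b, ddof=1), mad if mad > 0 else np.inf)
            * b.size ** (-0.2), 1e-8)
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 512)
    wk = np.ones_like(b) if w is None else w / w.sum()
    dens = (wk[None, :] * stats.norm.pdf((grid[:, None] - b[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _mode(instruments: pd.DataFrame, weighted: bool, n_boot: int,
          seed: int) -> MrEstimate:
    b, s, _ = _ratios(instruments)
    if b.size < 3:
        raise ValueError("mode estimators need at least 3 instruments")
    w = 1.0 / s**2 if weighted else None
    est = _mode_estimate(b, s, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, s, size=(n_boot, b.size))
    boots = np.array([_mode_estimate(d, s, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    z = est / se if se > 0 else np.inf
    name = "weighted_mode" if weighted else "simple_mode"
    return MrEstimate(name, est, se, 2 * float(stats.norm.sf(abs(z))), int(b.size))


def simple_mode(instruments: pd.DataFrame, n_boot: int = 200,
                seed: int = 0) -> MrEstimate:
    """Presumptive extra: unweighted mode of the ratio distribution."""
    return _mode(instruments, weighted=False, n_boot=n_boot, seed=seed)


def weighted_mode(instruments: pd.DataFrame, n_boot: int = 200,
                  seed: int = 0) -> MrEstimate:
    """Presumptive extra: inverse-variance weighted mode of the ratios."""
    return _mode(instruments, weighted=True, n_boot=n_boot, seed=seed)


def cochran_q(instruments: pd.DataFrame, ivw_beta: float):
    """Cochran's Q of the ratio estimates around the IVW slope; p on n-1 df."""
    b, s, _ = _ratios(instruments)
    if b.size < 2:
        return None, None
    w = 1.0 / s**2
    q = float(np.sum(w * (b - ivw_beta) ** 2))
    return q, float(stats.chi2.sf(q, b.size - 1))


def _plain_ivw(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    w = 1.0 / s**2
    return float(np.sum(w * b) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def leave_one_out(instruments: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Per-SNP IVW estimates with that SNP removed, plus a sign-stability flag.

    The analysis "passes" when every leave-one-out confidence interval
    overlaps the sign of the full-sample IVW estimate.
    """
    b, s, ok = _ratios(instruments)
    if b.size < 2:
        raise ValueError("leave-one-out needs at least 2 usable instruments")
    snps = instruments.loc[ok, "snp"].to_numpy()
    full, _ = _plain_ivw(b, s)
    rows = []
    for j in range(b.size):
        mask = np.arange(b.size) != j
        est, se = _plain_ivw(b[mask], s[mask])
        rows.append((snps[j], est, se, est - Z95 * se, est + Z95 * se))
    loo = pd.DataFrame(rows, columns=["snp", "beta", "se", "ci_low", "ci_high"])
    if full >= 0:
        passed = bool((loo["ci_high"] > 0).all())
    else:
        passed = bool((loo["ci_low"] < 0).all())
    return loo, passed


def presso_global(
    instruments: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> float:
    """MR-PRESSO global pleiotropy test (simulation p for the observed RSS).

    The observed statistic is the outcome-weighted leave-one-out residual sum
    of squares RSS = sum_j w_j (beta_out_j - slope_{-j} beta_exp_j)^2 with
    w_j = 1/se_out_j^2; its null distribution is built by redrawing
    beta_out_j ~ Normal(slope_{-j} beta_exp_j, se_out_j) ``n_sim`` times.
    Returns (1 + #{sim RSS >= observed}) / (n_sim + 1).
    """
    if len(instruments) < 4:
        raise ValueError("MR-PRESSO global test needs at least 4 instruments")
    rb, rs, ok = _ratios(instruments)
    bx = instruments.loc[ok, "beta_exp"].to_numpy(dtype=float)
    by = instruments.loc[ok, "beta_out"].to_numpy(dtype=float)
    sy = instruments.loc[ok, "se_out"].to_numpy(dtype=float)
    n = rb.size
    w = 1.0 / rs**2
    # leave-one-out IVW slopes, vectorized
    sw, swb = w.sum(), (w * rb).sum()
    loo_slope = (swb - w * rb) / (sw - w)
    wy = 1.0 / sy**2
    expected = loo_slope * bx
    obs = float(np.sum(wy * (by - expected) ** 2))
    rng = np.random.default_rng(seed)
    sim_by = rng.normal(expected, sy, size=(n_sim, n))
    # recompute leave-one-out slopes inside each simulation
    sim_rb = sim_by / bx
    sim_w = np.broadcast_to(w, (n_sim, n))
    ssw = sim_w.sum(axis=1, keepdims=True)
    sswb = (sim_w * sim_rb).sum(axis=1, keepdims=True)
    sim_slope = (sswb - sim_w * sim_rb) / (ssw - sim_w)
    sim_rss = np.sum(wy * (sim_by - sim_slope * bx) ** 2, axis=1)
    return float((1 + np.sum(sim_rss >= obs)) / (n_sim + 1))


def analyse_pair(
    instruments: pd.DataFrame,
    exposure: str,
    outcome: str,
    direction: str,
    seed: int = 0,
    presso_n_sim: int = 1000,
    include_modes: bool = False,
) -> MrReport:
    """Full estimator battery for one harmonized exposure-outcome pair."""
    report = MrReport(exposure=exposure, outcome=outcome, direction=direction,
                      n_snps=len(instruments))
    if len(instruments) == 0:
        report.skipped = "no instruments after harmonization"
        return report
    est = ivw(instruments)
    report.estimates.append(est)
    report.q_stat, report.q_p = cochran_q(instruments, est.beta)
    if len(instruments) >= 3:
        slope, icpt, _icpt_se, icpt_p = egger(instruments)
        report.estimates.append(slope)
        report.egger_intercept, report.egger_intercept_p = icpt, icpt_p
        report.estimates.append(weighted_median(instruments, seed=seed))
        if include_modes:
            report.estimates.append(simple_mode(instruments, seed=seed))
            report.estimates.append(weighted_mode(instruments, seed=seed))
    if len(instruments) >= 2:
        report.loo, report.loo_pass = leave_one_out(instruments)
    if len(instruments) >= 4:
        report.presso_global_p = presso_global(instruments, n_sim=presso_n_sim,
                                               seed=seed)
    return report


def run_bidirectional(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LdMatrix,
    outcome_label: str = "outcome",
    reverse_exposure: Optional[pd.DataFrame] = None,
    reverse_outcomes: Optional[Mapping[str, pd.DataFrame]] = None,
    seed: int = 0,
    presso_n_sim: int = 1000,
    bh_alpha: float = 0.05,
) -> tuple[list[MrReport], pd.DataFrame]:
    """Forward (traits -> outcome) and reverse (outcome -> traits) MR panel.

    Forward instruments are pooled into an exclusion set so the reverse
    analysis never reuses them. IVW p-values are BH-adjusted across traits
    within each direction; the returned table flags traits significant at
    ``bh_alpha``. Per-trait failures (no instruments, too few SNPs) are
    isolated and recorded as skipped reports.
    """
    from .enrich import bh_adjust

    reports: list[MrReport] = []
    forward_snps: Set[str] = set()
    for trait, exp_df in exposures.items():
        try:
            cand = select_instruments(exp_df, ld, "forward")
            inst = harmonize(cand, outcome)
            rep = analyse_pair(inst, trait, outcome_label, "forward", seed=seed,
                               presso_n_sim=presso_n_sim)
        except ValueError as exc:
            rep = MrReport(exposure=trait, outcome=outcome_label,
                           direction="forward", n_snps=0, skipped=str(exc))
        if rep.n_snps and not rep.skipped:
            forward_snps.update(inst["snp"])
        reports.append(rep)

    if reverse_exposure is not None and reverse_outcomes:
        rev_cand = select_instruments(reverse_exposure, ld, "reverse",
                                      exclude=forward_snps)
        for trait, out_df in reverse_outcomes.items():
            try:
                inst = harmonize(rev_cand, out_df)
                rep = analyse_pair(inst, outcome_label, trait, "reverse",
                                   seed=seed, presso_n_sim=presso_n_sim)
            except ValueError as exc:
                rep = MrReport(exposure=outcome_label, outcome=trait,
                               direction="reverse", n_snps=0, skipped=str(exc))
            reports.append(rep)

    rows = []
    for rep in reports:
        e = rep.estimate("ivw")
        rows.append((
            rep.direction,
            rep.exposure if rep.direction == "forward" else rep.outcome,
            rep.n_snps,
            None if e is None else e.beta,
            None if e is None else e.or_,
            None if e is None else e.ci_low,
            None if e is None else e.ci_high,
            None if e is None else e.p,
            rep.q_p, rep.egger_intercept_p, rep.presso_global_p,
            rep.skipped or "",
        ))
    table = pd.DataFrame(rows, columns=[
        "direction", "trait", "n_snp", "ivw_beta", "or", "ci_low", "ci_high",
        "mr_p", "q_stat_p", "egger_intercept_p", "presso_p", "skipped"])
    table["mr_p_bh"] = np.nan
    table["significant"] = False
    for direction in table["direction"].unique():
        mask = (table["direction"] == direction) & table["mr_p"].notna()
        if mask.any():
            adj = bh_adjust(table.loc[mask, "mr_p"].to_numpy())
            table.loc[mask, "mr_p_bh"] = adj
            table.loc[mask, "significant"] = adj < bh_alpha
    return reports, table
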