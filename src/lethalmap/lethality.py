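"""Mating-type analysis of insemination failure under a recessive lethal.

With a fully penetrant recessive embryonic lethal at frequency p, only
matings in which both the service sire and the dam carry the deletion can
produce homozygous conceptuses. Sorting inseminations by the deletion
status of the sire and of the maternal grand-sire (MGS; the only genotyped
ancestor on the dam side) gives four mating types with known expected
homozygote fractions:

    I   NC sire x daughter of NC MGS : 0
    II  NC sire x daughter of C MGS  : 0
    III C sire x daughter of NC MGS  : 0.25 p
    IV  C sire x daughter of C MGS   : 0.25 * P(dam carrier)

where for type IV the dam inherits the deletion from her carrier MGS with
probability 1/2 or from the ungenotyped maternal grand-dam with probability
p; conditioning on the dam being alive (dams cannot be homozygous) gives
P(dam carrier) = 0.5 / (1 - 0.5 p). If a fraction delta(d) of homozygous
conceptuses has died by d days after insemination, the extra failure beyond
the background rate f_d is delta(d) * (1 - f_d) * E[homozygote fraction], so
the stage-specific death fraction is estimated as observed/expected extra.

Failure rates per mating type are adjusted for parity and month-year fixed
effects and an MGS random effect with a linear mixed model on the 0/1
non-return outcome, the MGS variance ratio being REML-profiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simpop import ArrayDataset, InseminationRecords

__all__ = [
    "ELEstimate",
    "FailureRateTable",
    "MATING_TYPES",
    "absence_of_homozygotes_summary",
    "adjusted_failure_rates",
    "classify_matings",
    "death_fraction_curve",
    "estimate_death_fraction",
    "expected_extra_failure",
    "expected_homozygote_fraction",
    "lethal_equivalents",
    "rescale_equivalents",
]

MATING_TYPES = ("I", "II", "III", "IV")


@dataclass
class FailureRateTable:
    """Adjusted failure rates per mating type and day.

    ``table`` columns: day, mating_type, adjusted_rate, se, n_records,
    background (f_d, the record-weighted mean of adjusted types I and II)
    and extra_rate (adjusted - background).
    """

    table: pd.DataFrame


@dataclass
class ELEstimate:
    day: int
    mating_type: str
    observed_extra: float
    expected_extra: float  # under delta = 1
    death_fraction: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    exceeds_one: bool = False


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def expected_homozygote_fraction(mating_type: str, p: float,
                                 conditioned: bool = True) -> float:
    """Expected fraction of deletion-homozygous conceptuses per mating type.

    With ``conditioned`` (default) the type-IV dam-carrier probability is
    conditioned on dam viability, 0.5/(1 - 0.5p); without it, 0.5.
    """
    if not (0.0 <= p <= 0.5):
        raise ValueError("p must lie in [0, 0.5]")
    if mating_type in ("I", "II"):
        return 0.0
    if mating_type == "III":
        return 0.25 * p
    if mating_type == "IV":
        p_dam = 0.5 / (1.0 - 0.5 * p) if conditioned else 0.5
        return 0.25 * p_dam
    raise ValueError(f"unknown mating type {mating_type!r}")


def expected_extra_failure(mating_type: str, p: float, f_d: float,
                           delta_d: float = 1.0,
                           conditioned: bool = True) -> float:
    """Expected extra failure rate: delta * (1 - f) * homozygote fraction."""
    if not (0.0 <= f_d < 1.0):
        raise ValueError("background failure must lie in [0, 1)")
    if not (0.0 <= delta_d <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    return delta_d * (1.0 - f_d) * expected_homozygote_fraction(
        mating_type, p, conditioned)


def estimate_death_fraction(
    observed_extra: float,
    mating_type: str,
    p: float,
    f_d: float,
    day: int = 0,
    conditioned: bool = True,
) -> ELEstimate:
    """Stage-specific death fraction: observed / expected extra failure.

    The expectation assumes full lethality by the stage (delta = 1); an
    estimate above 1 is flagged, not truncated.
    """
    expected = expected_extra_failure(mating_type, p, f_d, 1.0, conditioned)
    if expected <= 0:
        raise ValueError("expected extra failure is zero for this mating type")
    delta = max(0.0, observed_extra / expected)
    return ELEstimate(day=day, mating_type=mating_type,
                      observed_extra=observed_extra, expected_extra=expected,
                      death_fraction=delta, exceeds_one=delta > 1.0)


def lethal_equivalents(extra_failure_budget: float, q: float) -> float:
    """Number of independent recessive lethal loci at frequency q explaining
    a given homozygous-conceptus burden under random mating: n = X / q^2."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if extra_failure_budget < 0:
        raise ValueError("budget must be >= 0")
    return extra_failure_budget / (q * q)


def rescale_equivalents(n1: float, q1: float, q2: float) -> float:
    """Equivalent locus count at a different allele frequency:
    n2 = n1 (q1/q2)^2 keeps n q^2 (the expected burden) constant."""
    if not (0.0 < q1 < 1.0 and 0.0 < q2 < 1.0):
        raise ValueError("frequencies must lie in (0, 1)")
    return n1 * (q1 / q2) ** 2


# ---------------------------------------------------------------------------
# mating classification
# ---------------------------------------------------------------------------


def classify_matings(records: InseminationRecords,
                     carrier_status: dict) -> tuple:
    """Annotate records with mating type from sire and MGS carrier status.

    ``carrier_status`` maps animal id -> truthy carrier flag. Records whose
    sire or MGS status cannot be resolved are excluded and counted.

    Returns ``(annotated_table, counts)`` where counts includes the excluded
    records under ``"unresolved"``.
    """
    t = records.table.copy()
    sire_c = t["sire_id"].map(lambda a: carrier_status.get(a))
    mgs_c = t["mgs_id"].map(lambda a: carrier_status.get(a))
    resolved = sire_c.notna() & mgs_c.notna()
    sc = sire_c[resolved].astype(bool)
    mc = mgs_c[resolved].astype(bool)
    mt = np.where(~sc & ~mc, "I",
                  np.where(~sc & mc, "II", np.where(sc & ~mc, "III", "IV")))
    out = t[resolved].copy()
    out["mating_type"] = mt
    counts = {k: int((mt == k).sum()) for k in MATING_TYPES}
    counts["unresolved"] = int((~resolved).sum())
    return out, counts


# ---------------------------------------------------------------------------
# adjusted failure rates (LMM with MGS random effect)
# ---------------------------------------------------------------------------


def _design(annotated: pd.DataFrame):
    """Indicator design: 4 type columns, parity and month (first level
    dropped), MGS grouping. Returns column structures for fast suff-stats."""
    mt = pd.Categorical(annotated["mating_type"], categories=MATING_TYPES)
    type_idx = mt.codes.astype(np.int64)
    par = pd.Categorical(annotated["parity"])
    mon = pd.Categorical(annotated["month_year"])
    mgs = pd.Categorical(annotated["mgs_id"])
    p_par = max(len(par.categories) - 1, 0)
    p_mon = max(len(mon.categories) - 1, 0)
    p = 4 + p_par + p_mon
    n = len(annotated)
    cols = [type_idx]
    offs = [0]
    # covariate column index per record (or -1 when at the dropped level)
    par_col = par.codes.astype(np.int64) - 1
    mon_col = mon.codes.astype(np.int64) - 1
    return {
        "n": n, "p": p, "p_par": p_par, "p_mon": p_mon,
        "type_idx": type_idx, "par_col": par_col, "mon_col": mon_col,
        "mgs_idx": mgs.codes.astype(np.int64), "q": len(mgs.categories),
    }


def _dense_rows(d) -> np.ndarray:
    """Materialise the fixed-effect design as a dense float32 matrix."""
    n, p = d["n"], d["p"]
    X = np.zeros((n, p), dtype=np.float64)
    X[np.arange(n), d["type_idx"]] = 1.0
    m = d["par_col"] >= 0
    X[np.where(m)[0], 4 + d["par_col"][m]] = 1.0
    m = d["mon_col"] >= 0
    X[np.where(m)[0], 4 + d["p_par"] + d["mon_col"][m]] = 1.0
    return X


def _mgs_reml(X, y, mgs_idx, q):
    """Profile the MGS variance ratio lambda for V = I + lambda Z Z'.

    Uses the grouped Woodbury identity, so each likelihood evaluation costs
    O(p^2 q) on precomputed sufficient statistics.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ng = np.bincount(mgs_idx, minlength=q).astype(float)
    ZtX = np.zeros((q, p))
    np.add.at(ZtX, mgs_idx, X)
    Zty = np.bincount(mgs_idx, weights=y, minlength=q)

    def reml(lam):
        dgf = lam / (1.0 + lam * ng)
        XtViX = XtX - ZtX.T @ (ZtX * dgf[:, None])
        XtViy = Xty - ZtX.T @ (Zty * dgf)
        yViy = yty - float(Zty @ (Zty * dgf))
        beta, *_ = np.linalg.lstsq(XtViX, XtViy, rcond=None)
        rss = yViy - float(beta @ XtViy)
        rank = np.linalg.matrix_rank(XtViX)
        sigma2 = rss / (n - rank)
        sgn, ld_xx = np.linalg.slogdet(XtViX + 1e-10 * np.eye(p))
        ld_v = float(np.log1p(lam * ng).sum())
        ll = -0.5 * ((n - rank) * (np.log(2 * np.pi * sigma2) + 1.0) + ld_v + ld_xx)
        return ll, beta, sigma2, XtViX

    res = optimize.minimize_scalar(lambda lg: -reml(np.exp(lg))[0],
                                   bounds=(np.log(1e-8), np.log(10.0)),
                                   method="bounded", options={"xatol": 1e-4})
    lam = float(np.exp(res.x))
    ll, beta, sigma2, XtViX = reml(lam)
    return lam, beta, sigma2, XtViX, ll


def _mgs_fixed_lambda(X, y, mgs_idx, q, lam):
    """GLS fit at a fixed MGS variance ratio (lam = 0 is ordinary LS)."""
    n, p = X.shape
    ng = np.bincount(mgs_idx, minlength=q).astype(float)
    ZtX = np.zeros((q, p))
    np.add.at(ZtX, mgs_idx, X)
    Zty = np.bincount(mgs_idx, weights=y, minlength=q)
    dgf = lam / (1.0 + lam * ng)
    XtViX = X.T @ X - ZtX.T @ (ZtX * dgf[:, None])
    XtViy = X.T @ y - ZtX.T @ (Zty * dgf)
    beta, *_ = np.linalg.lstsq(XtViX, XtViy, rcond=None)
    yViy = float(y @ y) - float(Zty @ (Zty * dgf))
    rank = np.linalg.matrix_rank(XtViX)
    sigma2 = (yViy - float(beta @ XtViy)) / (n - rank)
    return lam, beta, sigma2, XtViX


def _cluster_suffstats(d: dict, X: np.ndarray, y: np.ndarray, lam: float) -> dict:
    """Per-MGS-cluster GLS sufficient statistics at a fixed variance ratio.

    For cluster g with n_g records, V_g^-1 = I - dgf_g 1 1' with
    dgf_g = lam/(1 + lam n_g); a cluster bootstrap with multiplicities w then
    refits the mixed model from C(w) = sum_g w_g C_g and b(w) = sum_g w_g b_g,
    reproducing the point estimator exactly (lambda held at the full fit).

    Exploits the all-indicator design: each record activates at most three
    columns, so X'X per cluster accumulates in O(records x 9).
    """
    n, p = X.shape
    q = d["q"]
    mgs = d["mgs_idx"]
    # active columns per record (p = padding column for dropped levels)
    a0 = d["type_idx"]
    a1 = np.where(d["par_col"] >= 0, 4 + d["par_col"], p)
    a2 = np.where(d["mon_col"] >= 0, 4 + d["p_par"] + d["mon_col"], p)
    cols = np.stack([a0, a1, a2], axis=1)  # (n, 3)
    P = p + 1
    xtx = np.zeros(q * P * P)
    for i in range(3):
        for j in range(3):
            keys = (mgs * P + cols[:, i]) * P + cols[:, j]
            np.add.at(xtx, keys, 1.0)
    xtx = xtx.reshape(q, P, P)[:, :p, :p]
    xty = np.zeros(q * P)
    for i in range(3):
        np.add.at(xty, mgs * P + cols[:, i], y)
    xty = xty.reshape(q, P)[:, :p]
    ztx = np.zeros((q, P))
    for i in range(3):
        np.add.at(ztx, (mgs, cols[:, i]), 1.0)
    ztx = ztx[:, :p]
    zty = np.bincount(mgs, weights=y, minlength=q)
    ng = np.bincount(mgs, minlength=q).astype(float)
    dgf = lam / (1.0 + lam * ng)
    C = xtx - dgf[:, None, None] * (ztx[:, :, None] * ztx[:, None, :])
    b = xty - dgf[:, None] * ztx * zty[:, None]
    n_type = np.zeros((q, 4))
    np.add.at(n_type, (mgs, d["type_idx"]), 1.0)
    return {"C": C, "b": b, "n_type": n_type}


def adjusted_failure_rates(
    annotated: pd.DataFrame,
    day: int,
    mgs_variance_fallback: float = 0.05,
    mgs_lambda: float | None = None,
) -> pd.DataFrame:
    """Mixed-model adjusted failure rates per mating type at one day.

    Fits failure ~ mating_type + parity + month_year + (1 | MGS) with the
    MGS variance ratio REML-profiled (or fixed via ``mgs_lambda``).
    Adjusted rates are population-averaged (evaluated at the observed
    covariate mix); the background f_d is the record-weighted mean of
    adjusted types I and II. Rank-deficient fixed effects are handled by
    least squares on estimable contrasts.
    """
    if annotated["mating_type"].nunique() < 2:
        raise ValueError("need at least two mating types")
    d = _design(annotated)
    X = _dense_rows(d)
    y = annotated[f"failure_{day}"].to_numpy(dtype=float)
    try:
        if mgs_lambda is not None:
            lam, beta, sigma2, XtViX = _mgs_fixed_lambda(
                X, y, d["mgs_idx"], d["q"], mgs_lambda)
        else:
            lam, beta, sigma2, XtViX = _mgs_reml(X, y, d["mgs_idx"], d["q"])[:4]
    except np.linalg.LinAlgError:
        lam = mgs_variance_fallback
        XtViX = X.T @ X
        beta, *_ = np.linalg.lstsq(XtViX, X.T @ y, rcond=None)
        sigma2 = float(np.mean((y - X @ beta) ** 2))
    cov = np.linalg.pinv(XtViX) * sigma2
    xbar_cov = X[:, 4:].mean(axis=0)

    rows = []
    for k, mt in enumerate(MATING_TYPES):
        nk = int((d["type_idx"] == k).sum())
        if nk == 0:
            continue
        c = np.zeros(d["p"])
        c[k] = 1.0
        c[4:] = xbar_cov
        rate = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        rows.append({"day": day, "mating_type": mt, "adjusted_rate": rate,
                     "se": se, "n_records": nk})
    out = pd.DataFrame(rows)
    base = out[out["mating_type"].isin(["I", "II"])]
    f_d = float(np.average(base["adjusted_rate"], weights=base["n_records"]))
    out["background"] = f_d
    out["extra_rate"] = out["adjusted_rate"] - f_d
    return out


def death_fraction_curve(
    annotated: pd.DataFrame,
    p: float,
    days=(35, 56, 100, 150),
    mating_type: str = "IV",
    conditioned: bool = True,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> tuple:
    """Adjusted rates and death-fraction estimates with bootstrap CIs.

    For every day the mixed model supplies adjusted per-type rates; the
    death fraction is observed/expected extra failure in ``mating_type``.
    The CI is a percentile cluster bootstrap over maternal-grand-sire
    families: nuisance effects (parity, month, MGS) are held at their
    full-data estimates, MGS clusters are resampled with replacement, and
    the per-type adjusted means are recomputed. Clustering at the MGS level
    preserves the within-cow correlation (a cow's records share her
    deletion genotype) that a record-level bootstrap would miss.
    """
    rng = np.random.default_rng(seed)
    d = _design(annotated)
    X = _dense_rows(d)
    mt_i = MATING_TYPES.index(mating_type)
    tables = []
    estimates = []
    for day in days:
        adj = adjusted_failure_rates(annotated, day)
        tables.append(adj)
        row = adj[adj["mating_type"] == mating_type].iloc[0]
        f_d = float(row["background"])
        est = estimate_death_fraction(float(row["extra_rate"]), mating_type,
                                      p, f_d, day=day, conditioned=conditioned)
        if n_bootstrap:
            y = annotated[f"failure_{day}"].to_numpy(dtype=float)
            lam = _mgs_reml(X, y, d["mgs_idx"], d["q"])[0]
            stats_g = _cluster_suffstats(d, X, y, lam)
            xbar_cov = X[:, 4:].mean(axis=0)
            q = d["q"]
            C_tot = stats_g["C"].sum(axis=0)
            b_tot = stats_g["b"].sum(axis=0)
            n_tot = stats_g["n_type"].sum(axis=0)

            def delta_from(C, bb, cnts):
                if cnts[:2].sum() == 0 or cnts[mt_i] == 0:
                    return np.nan
                beta_b, *_ = np.linalg.lstsq(C, bb, rcond=None)
                means = beta_b[:4] + xbar_cov @ beta_b[4:]
                fb = float(np.average(means[:2], weights=cnts[:2]))
                exp_b = expected_extra_failure(mating_type, p, fb, 1.0, conditioned)
                return (means[mt_i] - fb) / exp_b if exp_b > 0 else np.nan

            theta_hat = delta_from(C_tot, b_tot, n_tot)
            boot = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                w = np.bincount(rng.integers(0, q, size=q),
                                minlength=q).astype(float)
                boot[b] = delta_from(np.tensordot(w, stats_g["C"], axes=1),
                                     w @ stats_g["b"], w @ stats_g["n_type"])
            boot = boot[np.isfinite(boot)]
            # BCa interval: bias correction from the bootstrap distribution,
            # acceleration from the delete-one-cluster jackknife
            jack = np.array([
                delta_from(C_tot - stats_g["C"][g], b_tot - stats_g["b"][g],
                           n_tot - stats_g["n_type"][g])
                for g in range(q)])
            jack = jack[np.isfinite(jack)]
            jm = jack.mean()
            num = ((jm - jack) ** 3).sum()
            den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
            a = num / den if den > 0 else 0.0
            prop = np.clip(np.mean(boot < theta_hat), 1e-4, 1 - 1e-4)
            z0 = stats.norm.ppf(prop)
            lo, hi = [], []
            for zalpha, store in ((stats.norm.ppf(0.025), lo),
                                  (stats.norm.ppf(0.975), hi)):
                zz = z0 + (z0 + zalpha) / (1 - a * (z0 + zalpha))
                store.append(float(np.percentile(
                    boot, 100 * stats.norm.cdf(zz))))
            est.ci_low, est.ci_high = lo[0], hi[0]
        estimates.append(est)
    return FailureRateTable(pd.concat(tables, ignore_index=True)), estimates


# ---------------------------------------------------------------------------
# absence of homozygotes
# ---------------------------------------------------------------------------


def absence_of_homozygotes_summary(
    dataset: ArrayDataset,
    region: tuple,
    one_copy_mean: float = -0.66,
    zero_copy_mean: float = -5.0,
) -> dict:
    """Summarise per-sample mean LRR in a region against copy-number regimes.

    The minimum mean LRR across samples is classified as one-copy
    (heterozygous-deletion) or zero-copy regime by the midpoint between the
    regime means; a minimum inside the one-copy regime supports the absence
    of live homozygotes.
    """
    chrom, start, end = region
    mask = (dataset.markers.in_interval(start, end)
            & (dataset.markers.table["chromosome"] == chrom).to_numpy())
    if not mask.any():
        raise ValueError("region contains no markers")
    means = dataset.lrr[:, mask].mean(axis=1)
    i_min = int(np.argmin(means))
    boundary = 0.5 * (one_copy_mean + zero_copy_mean)
    regime = "one-copy" if means[i_min] > boundary else "zero-copy"
    return {
        "per_sample_mean_lrr": means,
        "min_mean_lrr": float(means[i_min]),
        "min_sample_id": int(dataset.animal_ids[i_min]),
        "regime_boundary": boundary,
        "minimum_regime": regime,
        "homozygote_free": regime == "one-copy",
    }
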