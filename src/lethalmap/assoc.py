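"""Mixed-model association mapping with pedigree kinship and ancestral haplotypes.

Two mapping layers are provided. The genome-scan layer fits, SNP by SNP,

    y = mu + X b + P c + m s + Z u + e,   u ~ N(0, A_s sigma_u^2),

where y are breeding-value proofs, P holds the top principal components
(population stratification), m is the additive SNP dosage and A_s the
pedigree numerator-relationship matrix among sires; s is tested with a
t-test. The fine-mapping layer clusters phased haplotypes into K ancestral
haplotype states with a hidden Markov model, then tests each position with

    y = mu + P c + H h + Z u + e,  h ~ N(0, I sigma_h^2),  u ~ N(0, A sigma_u^2),

with residual variance scaled by reliability-derived weights (W);
the haplotype variance component is tested with a likelihood-ratio test
referred to chi-square with 1 df. REML uses an eigendecomposition of the
kinship for the one-ratio SNP model (single decomposition reused across
markers) and Nelder-Mead over the two log variance ratios for the haplotype
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simpop import Pedigree, UNKNOWN

__all__ = [
    "AncestralHaplotypeModel",
    "KinshipMatrix",
    "MixedModelFit",
    "bonferroni_threshold",
    "fit_ancestral_hmm",
    "haplotype_lrt",
    "kinship_matrix",
    "pca_covariates",
    "reliability_weights",
    "snp_mixed_gwas",
    "duo_phase",
]


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    subject_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("kinship matrix must be symmetric")
        if np.any(np.diag(v) < 1 - 1e-9):
            raise ValueError("numerator relationship diagonal must be >= 1")
        w = np.linalg.eigvalsh(v)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("kinship matrix not PSD within tolerance")


def kinship_matrix(pedigree: Pedigree, subjects=None) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    a_ij = 0.5 (a_i,sire(j) + a_i,dam(j)), a_jj = 1 + 0.5 a_sire(j),dam(j);
    unknown parents contribute zero. Computed over the whole pedigree, then
    restricted to ``subjects`` (default: all animals).
    """
    t = pedigree.table.sort_values("generation", kind="stable")
    ids = t["animal_id"].to_numpy()
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = t["sire_id"].to_numpy()
    dams = t["dam_id"].to_numpy()
    for j in range(n):
        si = index.get(sires[j]) if sires[j] != UNKNOWN else None
        di = index.get(dams[j]) if dams[j] != UNKNOWN else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[j, :j] = row[:j]
        A[:j, j] = row[:j]
        A[j, j] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    if subjects is None:
        return KinshipMatrix(ids, A)
    try:
        sel = [index[s] for s in subjects]
    except KeyError as exc:
        raise ValueError(f"subject {exc.args[0]} absent from pedigree") from None
    sel = np.asarray(sel)
    return KinshipMatrix(np.asarray(subjects), A[np.ix_(sel, sel)])


# ---------------------------------------------------------------------------
# PCA covariates
# ---------------------------------------------------------------------------


def pca_covariates(genotypes: np.ndarray, k: int = 4) -> np.ndarray:
    """Top-k principal-component scores from allele-frequency-standardised
    genotypes (samples x markers, additive 0/1/2 coding).

    Constant markers are dropped (logged); returns an (n, k) score matrix.
    """
    import logging

    g = np.asarray(genotypes, dtype=float)
    if k == 0:
        return np.empty((g.shape[0], 0))
    if g.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    p = g.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        logging.getLogger(__name__).info(
            "pca_covariates: dropped %d constant markers", int((~keep).sum()))
    g = g[:, keep]
    p = p[keep]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z -= z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :k] * s[:k]


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    beta: np.ndarray
    beta_names: list
    sigma2_u: float
    sigma2_e: float
    loglik: float
    sigma2_h: float = 0.0
    statistic: float = float("nan")
    p_value: float = float("nan")
    se: float = float("nan")
    state_effects: np.ndarray | None = None
    state_frequencies: np.ndarray | None = None


def _reml_ll_rotated(delta: float, yr: np.ndarray, Xr: np.ndarray,
                     s: np.ndarray) -> tuple:
    """Restricted log-likelihood for V = sigma_e^2 (delta * diag(s) + I)."""
    v = delta * s + 1.0
    w = 1.0 / v
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r * w))
    n, p = len(yr), Xr.shape[1]
    sigma2 = rss / (n - p)
    _, ld_xx = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                 + np.log(v).sum() + ld_xx)
    return ll, beta, sigma2, XtWX


def snp_mixed_gwas(
    y: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Single-SNP mixed-model scan with a random polygenic (sire) effect.

    The kinship eigendecomposition is computed once and reused for every
    marker; the variance ratio delta = sigma_u^2/sigma_e^2 is profiled per
    marker on a log grid with golden refinement, and the SNP substitution
    effect is tested with a t-test (df = n - p). Markers below the MAF
    threshold are skipped (NaN rows).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if len(y) != n:
        raise ValueError("response / genotype dimension mismatch")
    X0 = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X0 = np.column_stack([X0, covariates])
    s, U = np.linalg.eigh(kinship.values)
    if s.min() < -1e-8:
        raise ValueError("kinship not PSD")
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    X0r = U.T @ X0
    gr = U.T @ g

    freq = g.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)

    grid = np.concatenate([[0.0], np.logspace(-3, 3, 25)])
    out = []
    for j in range(m):
        if maf[j] < min_maf:
            out.append((np.nan,) * 7)
            continue
        Xr = np.column_stack([X0r, gr[:, j]])

        def nll(log_delta):
            return -_reml_ll_rotated(np.exp(log_delta), yr, Xr, s)[0]

        lls = [_reml_ll_rotated(d, yr, Xr, s)[0] for d in grid]
        best = int(np.argmax(lls))
        delta = grid[best]
        if 0 < best < len(grid) - 1 and delta > 0:
            res = optimize.minimize_scalar(
                nll, bracket=(np.log(grid[max(best - 1, 1)]),
                              np.log(grid[best]), np.log(grid[best + 1])),
                method="brent", options={"xtol": 1e-4})
            delta = float(np.exp(res.x))
        ll, beta, sigma2, XtWX = _reml_ll_rotated(delta, yr, Xr, s)
        cov = np.linalg.inv(XtWX) * sigma2
        se = float(np.sqrt(cov[-1, -1]))
        tstat = float(beta[-1] / se)
        df = n - Xr.shape[1]
        p = float(2 * stats.t.sf(abs(tstat), df))
        out.append((beta[-1], se, tstat, p, delta * sigma2, sigma2, ll))
    return pd.DataFrame(out, columns=["beta", "se", "t", "p",
                                      "sigma2_u", "sigma2_e", "loglik"])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def reliability_weights(r2: np.ndarray) -> np.ndarray:
    """De-regression weights w = r2 / (1 - r2) from proof reliabilities."""
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 <= 0) | (r2 >= 1)):
        raise ValueError("reliabilities must lie in (0, 1)")
    return r2 / (1.0 - r2)


# ---------------------------------------------------------------------------
# ancestral haplotype HMM
# ---------------------------------------------------------------------------


@dataclass
class AncestralHaplotypeModel:
    """K-state HMM over markers: one hidden ancestral state per haplotype
    per marker, Bernoulli allele emissions per (state, marker), homogeneous
    switch rate per bp (jump destination uniform over states)."""

    positions: np.ndarray
    emissions: np.ndarray  # (K, m) P(allele = 1 | state)
    switch_rate: float  # per bp
    loglik: float
    haplotypes: np.ndarray  # (H, m) training data, kept for decoding
    hap_owner: np.ndarray  # (H,) animal index of each haplotype

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    def _rho(self) -> np.ndarray:
        gaps = np.diff(self.positions)
        return 1.0 - np.exp(-self.switch_rate * gaps)

    def _forward_backward(self) -> tuple:
        e1 = self.emissions
        H, m = self.haplotypes.shape
        K = self.n_states
        obs = self.haplotypes
        rho = self._rho()
        em = np.where(obs[:, :, None] == 1, e1.T[None, :, :], 1.0 - e1.T[None, :, :])
        em = np.clip(em, 1e-12, None)
        alpha = np.empty((m, H, K))
        cnorm = np.empty((m, H))
        a = em[:, 0, :] / K
        cnorm[0] = a.sum(axis=1)
        alpha[0] = a / cnorm[0][:, None]
        for j in range(1, m):
            prev = alpha[j - 1]
            a = ((1 - rho[j - 1]) * prev + rho[j - 1] / K) * em[:, j, :]
            cnorm[j] = a.sum(axis=1)
            alpha[j] = a / cnorm[j][:, None]
        beta = np.empty((m, H, K))
        beta[m - 1] = 1.0
        for j in range(m - 2, -1, -1):
            nxt = beta[j + 1] * em[:, j + 1, :]
            beta[j] = ((1 - rho[j]) * nxt + rho[j] * nxt.mean(axis=1, keepdims=True)) \
                / cnorm[j + 1][:, None]
        ll = float(np.log(cnorm).sum())
        return alpha, beta, cnorm, em, ll

    def posteriors(self, marker_index: int | None = None) -> np.ndarray:
        """Posterior state probabilities; (H, K) at one marker or (m, H, K)."""
        alpha, beta, _, _, _ = self._forward_backward()
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        if marker_index is None:
            return np.transpose(gamma, (0, 1, 2))
        return gamma[marker_index]

    def posterior_mean(self, marker_indices) -> np.ndarray:
        """Posterior state probabilities averaged over markers, (H, K).

        Averaging across the markers of a region stabilises state
        assignment relative to a single-marker decode."""
        alpha, beta, _, _, _ = self._forward_backward()
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        return gamma[np.asarray(marker_indices)].mean(axis=0)

    def state_dosages(self, marker_index: int, n_animals: int) -> np.ndarray:
        """Per-animal expected ancestral-state dosages (n, K) at a marker."""
        post = self.posteriors(marker_index)
        D = np.zeros((n_animals, self.n_states))
        np.add.at(D, self.hap_owner, post)
        return D


def fit_ancestral_hmm(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    K: int = 40,
    n_starts: int = 2,
    seed: int = 0,
    n_iter: int = 30,
    tol: float = 1e-4,
    hap_owner: np.ndarray | None = None,
) -> AncestralHaplotypeModel:
    """Baum-Welch clustering of phased haplotypes into K ancestral states.

    Emissions and the (single, homogeneous) per-bp switch rate are EM
    updated; the best of ``n_starts`` random initialisations by final
    log-likelihood is returned. The switch-rate M-step maximises the
    expected complete-data likelihood for the jump-augmented chain, so the
    marginal log-likelihood is non-decreasing across iterations.
    """
    haps = np.asarray(haplotypes, dtype=np.int8)
    H, m = haps.shape
    if hap_owner is None:
        hap_owner = np.repeat(np.arange(H // 2), 2) if H % 2 == 0 else np.arange(H)
    if K > H:
        import warnings

        warnings.warn(f"K={K} exceeds the number of haplotypes ({H}); proceeding")
    rng = np.random.default_rng(seed)
    gaps = np.diff(positions).astype(float)
    best_model = None
    for _ in range(max(1, n_starts)):
        # k-means++-style seeding: greedily pick haplotypes far (in Hamming
        # distance) from those already chosen, so minority backgrounds get
        # their own starting state
        sub = rng.choice(H, size=min(H, 2000), replace=False)
        pool = haps[sub].astype(np.int16)
        chosen = [int(rng.integers(0, len(pool)))]
        dmin = np.abs(pool - pool[chosen[0]]).mean(axis=1)
        while len(chosen) < min(K, len(pool)):
            probs = dmin ** 2
            tot = probs.sum()
            if tot <= 0:
                nxt = int(rng.integers(0, len(pool)))
            else:
                nxt = int(rng.choice(len(pool), p=probs / tot))
            chosen.append(nxt)
            dmin = np.minimum(dmin, np.abs(pool - pool[nxt]).mean(axis=1))
        rows = sub[chosen]
        if len(rows) < K:
            rows = np.concatenate([rows, rng.choice(H, size=K - len(rows))])
        e1 = np.clip(haps[rows].astype(float), 0.05, 0.95)
        e1 += rng.uniform(-0.04, 0.04, size=e1.shape)
        rate = 1e-7  # ~1 switch per 10 Mb to start
        model = AncestralHaplotypeModel(positions=np.asarray(positions),
                                        emissions=e1, switch_rate=rate,
                                        loglik=-np.inf, haplotypes=haps,
                                        hap_owner=np.asarray(hap_owner))
        prev_ll = -np.inf
        for _it in range(n_iter):
            alpha, beta, cnorm, em, ll = model._forward_backward()
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            # emission update
            occ = gamma.sum(axis=1)  # (m, K)
            ones = (gamma * (haps.T[:, :, None] == 1)).sum(axis=1)
            model.emissions = np.clip((ones / np.clip(occ, 1e-12, None)).T,
                                      1e-3, 1 - 1e-3)
            # expected jumps per interval: P(jump at j) = 1 - P(stay expressed)
            rho = model._rho()
            stay = np.empty((m - 1, H))
            for j in range(1, m):
                num = (alpha[j - 1] * (1 - rho[j - 1]) * em[:, j, :]
                       * beta[j]).sum(axis=1)
                stay[j - 1] = num / cnorm[j]
            e_jump = np.clip(1.0 - stay, 0.0, 1.0).sum(axis=1)  # per interval

            def neg_q(log_r):
                r = np.exp(log_r)
                pj = np.clip(1.0 - np.exp(-r * gaps), 1e-12, 1 - 1e-12)
                return -(e_jump * np.log(pj)
                         + (H - e_jump) * np.log1p(-pj)).sum()

            res = optimize.minimize_scalar(neg_q, bounds=(np.log(1e-12), np.log(1e-4)),
                                           method="bounded")
            model.switch_rate = float(np.exp(res.x))
            model.loglik = ll
            if ll - prev_ll < tol and _it > 2:
                break
            prev_ll = ll
        _, _, _, _, final_ll = model._forward_backward()
        model.loglik = final_ll
        if best_model is None or model.loglik > best_model.loglik:
            best_model = model
    return best_model


# ---------------------------------------------------------------------------
# haplotype-based weighted mixed model with LRT
# ---------------------------------------------------------------------------


class _TwoComponentREML:
    """REML engine for V = sigma_e^2 (g_h D D' + g_u A + W^-1).

    Works in the W^(1/2)-transformed, kinship-eigenrotated basis, so each
    likelihood evaluation costs O(n K) plus a K-dimensional Woodbury solve
    (K = number of haplotype states) instead of a dense n^3 factorisation.
    The constant Jacobian of the W^(1/2) transform is omitted; it cancels
    from every likelihood difference (and from the LRT).
    """

    def __init__(self, y, X, D, A, weights):
        n = len(y)
        sw = np.sqrt(weights) if weights is not None else np.ones(n)
        At = A * np.outer(sw, sw)
        s, U = np.linalg.eigh(At)
        self.s = np.clip(s, 0.0, None)
        self.yr = U.T @ (sw * y)
        self.Xr = U.T @ (sw[:, None] * X)
        self.Dr = U.T @ (sw[:, None] * D)
        self.n, self.p = X.shape
        self.K = D.shape[1]

    def loglik(self, g_h: float, g_u: float) -> tuple:
        m = g_u * self.s + 1.0
        mi = 1.0 / m
        B = np.column_stack([self.yr, self.Xr])
        MiB = B * mi[:, None]
        ld_v = float(np.log(m).sum())
        if g_h > 0:
            MiD = self.Dr * mi[:, None]
            core = np.eye(self.K) / g_h + self.Dr.T @ MiD
            sgn, ld_core = np.linalg.slogdet(core)
            ld_v += ld_core + self.K * np.log(g_h)
            ViB = MiB - MiD @ np.linalg.solve(core, self.Dr.T @ MiB)
        else:
            ViB = MiB
        Viy, ViX = ViB[:, 0], ViB[:, 1:]
        XtViX = self.Xr.T @ ViX
        beta = np.linalg.solve(XtViX, self.Xr.T @ Viy)
        rss = float(self.yr @ Viy - beta @ (self.Xr.T @ Viy))
        df = self.n - self.p
        sigma2 = max(rss / df, 1e-12)
        _, ld_xx = np.linalg.slogdet(XtViX)
        ll = -0.5 * (df * (np.log(2 * np.pi * sigma2) + 1.0) + ld_v + ld_xx)
        return ll, beta, sigma2

    def h_blup(self, g_h: float, g_u: float, beta: np.ndarray) -> np.ndarray:
        m = g_u * self.s + 1.0
        mi = 1.0 / m
        r = self.yr - self.Xr @ beta
        if g_h <= 0:
            return np.zeros(self.K)
        MiD = self.Dr * mi[:, None]
        core = np.eye(self.K) / g_h + self.Dr.T @ MiD
        Vir = r * mi - MiD @ np.linalg.solve(core, self.Dr.T @ (r * mi))
        return g_h * (self.Dr.T @ Vir)


def haplotype_lrt(
    y: np.ndarray,
    state_dosages: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    weights: np.ndarray | None = None,
    mixture_null: bool = False,
) -> MixedModelFit:
    """Test a QTL at one position via the ancestral-haplotype variance
    component.

    Fits y = mu + Pc + Hh + Zu + e with h ~ N(0, I sigma_h^2),
    u ~ N(0, A sigma_u^2) and e ~ N(0, W^-1 sigma_e^2); the LRT compares the
    restricted likelihoods with and without the haplotype component and is
    referred to chi-square 1 df (the boundary-corrected 50:50 mixture is
    available with ``mixture_null``). Per-state BLUP effects and dosage
    frequencies are returned for effect/frequency plots.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(state_dosages, dtype=float)
    n, K = D.shape
    used = D.sum(axis=0) > 1e-8
    if not used.all():
        import logging

        logging.getLogger(__name__).info(
            "haplotype_lrt: dropped %d empty state columns", int((~used).sum()))
    Du = D[:, used]
    X = np.ones((n, 1))
    names = ["mu"]
    if covariates is not None and np.size(covariates):
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([X, covariates])
        names += [f"c{i+1}" for i in range(covariates.shape[1])]
    engine = _TwoComponentREML(y, X, Du, kinship.values, weights)

    res0 = optimize.minimize_scalar(
        lambda lg: -engine.loglik(0.0, np.exp(lg))[0],
        bounds=(-10, 6), method="bounded", options={"xatol": 1e-6})
    ll0 = -res0.fun
    gu0 = float(np.exp(res0.x))
    best = None
    for init in ([-2.0, res0.x], [0.5, res0.x], [-5.0, res0.x]):
        r = optimize.minimize(
            lambda v: -engine.loglik(np.exp(v[0]), np.exp(v[1]))[0],
            init, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 300})
        if best is None or r.fun < best.fun:
            best = r
    ll1 = -best.fun
    gh, gu = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    # allow the boundary solution sigma_h^2 = 0
    if ll0 > ll1:
        ll1, gh, gu = ll0, 0.0, gu0
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    if mixture_null:
        p = 0.5 * float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    else:
        p = float(stats.chi2.sf(lrt, 1))

    ll, beta, sigma2 = engine.loglik(gh, gu)
    h_blup = np.zeros(K)
    h_blup[used] = engine.h_blup(gh, gu, beta)
    freqs = D.sum(axis=0) / (2.0 * n)
    return MixedModelFit(
        beta=beta, beta_names=names,
        sigma2_u=gu * sigma2, sigma2_e=sigma2, sigma2_h=gh * sigma2,
        loglik=ll1, statistic=lrt, p_value=p,
        state_effects=h_blup, state_frequencies=freqs,
    )


# ---------------------------------------------------------------------------
# duo phasing utility (real-data entry)
# ---------------------------------------------------------------------------


def duo_phase(child_calls: np.ndarray, sire_calls: np.ndarray) -> np.ndarray:
    """Phase a child's genotypes against its sire where Mendel determines it.

    Returns (2, m) alleles with -1 where phase is undetermined (haplotype 0
    paternal). Homozygous child markers are trivially phased; heterozygous
    markers phase only when the sire is homozygous.
    """
    c = np.asarray(child_calls)
    s = np.asarray(sire_calls)
    out = np.full((2, len(c)), -1, dtype=np.int8)
    hom = (c == 0) | (c == 2)
    out[0, hom] = out[1, hom] = (c[hom] // 2).astype(np.int8)
    het = c == 1
    pat_known = het & ((s == 0) | (s == 2))
    out[0, pat_known] = (s[pat_known] // 2).astype(np.int8)
    out[1, pat_known] = 1 - out[0, pat_known]
    return out
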