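"""Marker/sample QC and the clustered-anomaly scan that first flags a deletion.

A hemizygous deletion leaves two array-level fingerprints before anyone looks
at intensities: the in-deletion SNPs show a gross excess of homozygotes
(carriers are miscalled as homozygous), and parent-offspring Mendelian
conflicts pile up at the same markers (a hemizygous ``A-`` sire called AA can
produce a hemizygous ``B-`` child called BB). This module computes per-marker
QC metrics, an exact conditional Hardy-Weinberg test, duo/trio conflict
counts, and scans for runs of co-localised anomalies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import ArrayDataset, MarkerMap, Pedigree, UNKNOWN

__all__ = [
    "MarkerQCReport",
    "QCThresholds",
    "ScanConfig",
    "anomaly_scan",
    "count_mendelian_conflicts",
    "hwe_exact",
    "hwe_exact_vector",
    "qc_filter",
]

log = logging.getLogger(__name__)

EXCESS_HOM = "excess-hom"
EXCESS_HET = "excess-het"
NONE = "none"


@dataclass
class QCThresholds:
    """Default cutoffs follow common array-QC practice for bull cohorts."""

    min_sample_call_rate: float = 0.90
    min_marker_call_rate: float = 0.95
    min_maf: float = 0.05
    min_call_quality: float = 0.60
    min_sample_mean_quality: float = 0.65
    max_parentage_conflicts: int = 10

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_marker_call_rate", "min_maf",
                     "min_call_quality", "min_sample_mean_quality"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.max_parentage_conflicts < 0:
            raise ValueError("conflict cap must be >= 0")


@dataclass
class MarkerQCReport:
    """Per-marker QC metrics with per-rule pass flags."""

    table: pd.DataFrame


@dataclass
class ScanConfig:
    min_run_length: int = 3
    alpha: float = 1e-6
    conflict_cap: int = 10
    min_maf: float = 0.05  # rare-allele markers produce HWE artifacts


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def _het_distribution(n: int, n_a: int) -> tuple:
    """Conditional distribution of the heterozygote count given allele counts.

    Returns ``(het_values, probabilities)``. Computed with the stable ratio
    recurrence outward from a central heterozygote count, then normalised.
    """
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    # the heterozygote count shares the parity of the rare-allele count
    ks = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(ks), dtype=np.float64)
    mid_i = len(ks) // 2
    probs[mid_i] = 1.0
    # P(k+2)/P(k) = 4 * hom_rare(k) * hom_common(k) / ((k+2)(k+1))
    for i in range(mid_i, len(ks) - 1):
        k = int(ks[i])
        hom_r = (rare - k) // 2
        hom_c = (2 * n - rare - k) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((k + 2.0) * (k + 1.0))
    for i in range(mid_i, 0, -1):
        k = int(ks[i])
        hom_r = (rare - k) // 2
        hom_c = (2 * n - rare - k) // 2
        probs[i - 1] = probs[i] * (k * (k - 1.0)) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    return ks, probs


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> tuple:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    The p-value sums the probabilities of all heterozygote counts (given the
    allele counts) whose conditional probability does not exceed that of the
    observed count. Direction compares the observed heterozygote count with
    its conditional expectation: fewer than expected is ``excess-hom``, more
    is ``excess-het``, ties are ``none``. No mid-p correction is applied.

    Returns ``(p_value, direction)``.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype counts")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_ab
    ks, probs = _het_distribution(n, n_a)
    obs_i = int(np.searchsorted(ks, n_ab))
    p_obs = probs[obs_i]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    p = min(p, 1.0)
    expected = float((ks * probs).sum())
    if abs(n_ab - expected) < 1e-9:
        direction = NONE
    elif n_ab < expected:
        direction = EXCESS_HOM
    else:
        direction = EXCESS_HET
    return p, direction


def hwe_exact_vector(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray) -> tuple:
    """Vector form of :func:`hwe_exact` over markers.

    Returns ``(p_values, directions)``; empty tables get p = 1, ``none``.
    """
    m = len(n_aa)
    ps = np.ones(m)
    dirs = np.array([NONE] * m, dtype=object)
    for j in range(m):
        if n_aa[j] + n_ab[j] + n_bb[j] == 0:
            continue
        ps[j], dirs[j] = hwe_exact(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
    return ps, dirs


# ---------------------------------------------------------------------------
# Mendelian conflicts
# ---------------------------------------------------------------------------

# trio validity lookup over genotype codes 0=AA, 1=AB, 2=BB
_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}
_TRIO_VALID = np.zeros((3, 3, 3), dtype=bool)
for _s in range(3):
    for _d in range(3):
        for _c in range(3):
            _TRIO_VALID[_s, _d, _c] = any(
                a + b == _c for a in _GAMETES[_s] for b in _GAMETES[_d])


def _duo_conflict(parent: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Duo-rule conflicts (no shared allele); missing (-1) never conflicts."""
    return ((parent == 0) & (child == 2)) | ((parent == 2) & (child == 0))


def count_mendelian_conflicts(
    dataset: ArrayDataset,
    pedigree: Pedigree,
    use_trios: bool = False,
) -> np.ndarray:
    """Per-marker count of parent-offspring genotype incompatibilities.

    A duo conflict is a (marker, parent-offspring pair) whose called
    genotypes share no allele; with ``use_trios`` a child genotype impossible
    given both genotyped parents also counts (pairs fall back to the duo rule
    at markers where one parent is untyped). Missing calls never conflict.
    Animals whose parents are not in the dataset are skipped with a log entry.
    """
    ids = {a: i for i, a in enumerate(dataset.animal_ids)}
    calls = dataset.calls
    m = calls.shape[1]
    conflicts = np.zeros(m, dtype=np.int64)
    t = pedigree.table
    skipped = 0
    duos: list = []
    trios: list = []
    for child, sire, dam in zip(t["animal_id"], t["sire_id"], t["dam_id"]):
        if child not in ids:
            continue
        si = ids.get(sire) if sire != UNKNOWN else None
        di = ids.get(dam) if dam != UNKNOWN else None
        skipped += (sire != UNKNOWN and si is None) + (dam != UNKNOWN and di is None)
        if use_trios and si is not None and di is not None:
            trios.append((si, di, ids[child]))
        else:
            duos.extend((pi, ids[child]) for pi in (si, di) if pi is not None)
    if skipped:
        log.info("count_mendelian_conflicts: %d parent links not genotyped", skipped)
    if duos:
        p = calls[[a for a, _ in duos]]
        c = calls[[b for _, b in duos]]
        conflicts += _duo_conflict(p, c).sum(axis=0)
    if trios:
        s = calls[[a for a, _, _ in trios]]
        d = calls[[b for _, b, _ in trios]]
        c = calls[[x for _, _, x in trios]]
        typed = (s >= 0) & (d >= 0) & (c >= 0)
        bad = np.zeros_like(c, dtype=bool)
        bad[typed] = ~_TRIO_VALID[s[typed], d[typed], c[typed]]
        bad |= (_duo_conflict(s, c) | _duo_conflict(d, c)) & ~typed
        conflicts += bad.sum(axis=0)
    return conflicts


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _marker_stats(calls: np.ndarray) -> tuple:
    called = calls >= 0
    call_rate = called.mean(axis=0) if calls.shape[0] else np.zeros(calls.shape[1])
    n_aa = (calls == 0).sum(axis=0)
    n_ab = (calls == 1).sum(axis=0)
    n_bb = (calls == 2).sum(axis=0)
    tot = np.maximum(n_aa + n_ab + n_bb, 1)
    p_b = (2 * n_bb + n_ab) / (2 * tot)
    maf = np.minimum(p_b, 1 - p_b)
    return call_rate, maf, n_aa, n_ab, n_bb


def qc_filter(
    dataset: ArrayDataset,
    thresholds: QCThresholds | None = None,
    pedigree: Pedigree | None = None,
    compute_hwe: bool = True,
) -> tuple:
    """Apply sample- then marker-level QC, returning a per-rule audit trail.

    Filtering order: sample mean quality -> sample call rate -> marker call
    rate -> MAF -> Mendelian-conflict cap (the last only when a pedigree is
    supplied). Individual calls below the per-call quality threshold are set
    missing before any rate is computed.

    Returns ``(filtered_dataset, MarkerQCReport, sample_report)``.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if dataset.calls.size == 0:
        raise ValueError("empty dataset")
    th = thresholds
    calls = dataset.calls.copy()
    calls[(dataset.quality < th.min_call_quality) & (calls >= 0)] = -1

    mean_q = dataset.quality.mean(axis=1)
    ok_quality = mean_q >= th.min_sample_mean_quality
    sample_call_rate = (calls >= 0).mean(axis=1)
    ok_callrate = sample_call_rate >= th.min_sample_call_rate
    keep_samples = ok_quality & ok_callrate
    sample_report = pd.DataFrame({
        "animal_id": dataset.animal_ids,
        "mean_quality": mean_q,
        "call_rate": sample_call_rate,
        "pass_quality": ok_quality,
        "pass_call_rate": ok_callrate,
        "kept": keep_samples,
    })

    sub_calls = calls[keep_samples]
    call_rate, maf, n_aa, n_ab, n_bb = _marker_stats(sub_calls)
    pass_cr = call_rate >= th.min_marker_call_rate
    pass_maf = maf >= th.min_maf

    if pedigree is not None:
        sub = ArrayDataset(dataset.animal_ids[keep_samples], dataset.markers,
                           sub_calls, dataset.lrr[keep_samples],
                           dataset.quality[keep_samples])
        conflicts = count_mendelian_conflicts(sub, pedigree)
    else:
        conflicts = np.zeros(calls.shape[1], dtype=np.int64)
    pass_conf = conflicts <= th.max_parentage_conflicts

    if compute_hwe:
        hwe_p, hwe_dir = hwe_exact_vector(n_aa, n_ab, n_bb)
    else:
        hwe_p = np.ones(calls.shape[1])
        hwe_dir = np.array([NONE] * calls.shape[1], dtype=object)

    mt = dataset.markers.table
    report = MarkerQCReport(pd.DataFrame({
        "marker_id": mt["marker_id"].to_numpy(),
        "chromosome": mt["chromosome"].to_numpy(),
        "position": mt["position"].to_numpy(),
        "call_rate": call_rate,
        "maf": maf,
        "hwe_p": hwe_p,
        "hwe_direction": hwe_dir,
        "conflicts": conflicts,
        "pass_call_rate": pass_cr,
        "pass_maf": pass_maf,
        "pass_conflicts": pass_conf,
        "kept": pass_cr & pass_maf & pass_conf,
    }))
    keep_markers = report.table["kept"].to_numpy()
    filtered = ArrayDataset(
        dataset.animal_ids[keep_samples],
        MarkerMap(dataset.markers.table[keep_markers].reset_index(drop=True)),
        sub_calls[:, keep_markers],
        dataset.lrr[np.ix_(keep_samples, keep_markers)],
        dataset.quality[np.ix_(keep_samples, keep_markers)],
    )
    return filtered, report, sample_report


# ---------------------------------------------------------------------------
# anomaly scan
# ---------------------------------------------------------------------------


def anomaly_scan(report: MarkerQCReport, config: ScanConfig | None = None) -> pd.DataFrame:
    """Find runs of consecutive anomalous markers suggesting a deletion.

    A marker is anomalous when its exact HWE p-value falls below ``alpha``
    with excess homozygosity, or its Mendelian-conflict count exceeds the
    cap. Maximal runs of at least ``min_run_length`` consecutive anomalous
    markers become candidate intervals (1-based closed, first to last marker
    position) with supporting marker ids.
    """
    if config is None:
        config = ScanConfig()
    t = report.table
    out_rows = []
    for chrom, sub in t.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        flag = (((sub["hwe_p"].to_numpy() < config.alpha)
                 & (sub["hwe_direction"].to_numpy() == EXCESS_HOM))
                | (sub["conflicts"].to_numpy() > config.conflict_cap))
        flag &= sub["maf"].to_numpy() >= config.min_maf
        if not flag.any():
            continue
        padded = np.concatenate([[False], flag, [False]])
        starts = np.where(~padded[:-1] & padded[1:])[0]
        ends = np.where(padded[:-1] & ~padded[1:])[0]
        for a, b in zip(starts, ends):
            if b - a >= config.min_run_length:
                chunk = sub.iloc[a:b]
                out_rows.append({
                    "chromosome": chrom,
                    "start": int(chunk["position"].iloc[0]),
                    "end": int(chunk["position"].iloc[-1]),
                    "n_markers": int(b - a),
                    "marker_ids": list(chunk["marker_id"]),
                })
    return pd.DataFrame(out_rows, columns=["chromosome", "start", "end",
                                           "n_markers", "marker_ids"])
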