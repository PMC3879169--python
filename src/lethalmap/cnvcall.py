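"""Deletion discovery from array signals and combined-evidence carrier calling.

A heterozygous deletion makes a sample hemizygous across the interval: every
in-deletion SNP is called homozygous (there is only one allele to see) and
the total fluorescence intensity (Log R Ratio) drops to the one-copy regime.
This module detects such runs per sample, genotypes samples for the deletion
by combining four lines of evidence (low LRR, obligate homozygosity,
Mendelian-conflict involvement, tag-haplotype carriage), measures linkage
disequilibrium between the deletion and a tag haplotype, and tests for
depletion of tag-haplotype homozygotes (the population signature of a
recessive lethal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simpop import ArrayDataset, Pedigree

__all__ = [
    "CarrierCallParams",
    "DeletionCall",
    "HemizygousRun",
    "LDResult",
    "RunParams",
    "call_deletion_carriers",
    "detect_hemizygous_runs",
    "estimate_deletion_frequency",
    "homozygote_depletion_test",
    "ld_r2",
]


@dataclass
class HemizygousRun:
    sample_id: int
    start_bp: int  # 1-based closed interval, first to last marker in the run
    end_bp: int
    n_markers: int
    mean_lrr: float
    het_calls: int = 0  # zero by construction

    def __post_init__(self) -> None:
        if self.het_calls != 0:
            raise ValueError("a hemizygous run cannot contain a heterozygous call")


@dataclass
class DeletionCall:
    sample_id: int
    status: str  # carrier / non-carrier / ambiguous
    low_lrr: bool
    obligate_hom: bool
    conflict_implicated: bool
    tag_haplotype: bool
    score: float  # evidence-weighted score in [0, 1]
    mean_lrr: float


@dataclass
class LDResult:
    r2: float
    freq_x: float
    freq_y: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 outside [0, 1]")


@dataclass
class RunParams:
    """Run-mean LRR threshold and minimum called-marker count per panel."""

    lrr_threshold: float = -0.3
    min_markers: int = 20  # HD-scale default; use 3 for 50K-density data
    edge_trim_lrr: float = 0.0  # trim clearly two-copy markers at run edges


@dataclass
class CarrierCallParams:
    lrr_threshold: float = -0.3
    score_weights: dict = field(default_factory=lambda: {
        "low_lrr": 0.45, "obligate_hom": 0.35,
        "conflict_implicated": 0.10, "tag_haplotype": 0.10})


# ---------------------------------------------------------------------------
# hemizygous-run detection
# ---------------------------------------------------------------------------


def detect_hemizygous_runs(
    dataset: ArrayDataset,
    params: RunParams | None = None,
) -> list:
    """Per-sample maximal runs of het-free markers with depressed mean LRR.

    Runs are defined on called markers only: a heterozygous call breaks a
    run; missing calls neither break a run nor count toward the minimum
    length. A het-free stretch is reported when it contains at least
    ``min_markers`` called markers and its mean LRR (over called markers)
    falls below the threshold. Stretch edges are trimmed of markers with
    clearly two-copy intensity (LRR above ``edge_trim_lrr``) so reported
    intervals hug the deleted segment.
    """
    if params is None:
        params = RunParams()
    runs: list = []
    if dataset.calls.size == 0:
        return runs
    pos = dataset.markers.positions
    for i in range(dataset.n_samples):
        calls = dataset.calls[i]
        lrr = dataset.lrr[i]
        het = calls == 1
        called = calls >= 0
        # boundaries at het calls
        breakpoints = np.concatenate([[-1], np.where(het)[0], [len(calls)]])
        for a, b in zip(breakpoints[:-1], breakpoints[1:]):
            lo, hi = a + 1, b  # candidate stretch [lo, hi)
            idx = np.where(called[lo:hi])[0] + lo
            if len(idx) < params.min_markers:
                continue
            # trim clearly diploid-intensity markers at the edges
            while len(idx) and lrr[idx[0]] > params.edge_trim_lrr:
                idx = idx[1:]
            while len(idx) and lrr[idx[-1]] > params.edge_trim_lrr:
                idx = idx[:-1]
            if len(idx) < params.min_markers:
                continue
            mean_lrr = float(lrr[idx].mean())
            if mean_lrr < params.lrr_threshold:
                runs.append(HemizygousRun(
                    sample_id=int(dataset.animal_ids[i]),
                    start_bp=int(pos[idx[0]]),
                    end_bp=int(pos[idx[-1]]),
                    n_markers=int(len(idx)),
                    mean_lrr=mean_lrr,
                ))
    return runs


# ---------------------------------------------------------------------------
# combined-evidence carrier calling
# ---------------------------------------------------------------------------


def call_deletion_carriers(
    dataset: ArrayDataset,
    region: tuple,
    pedigree: Pedigree | None = None,
    tag_assignments: dict | None = None,
    params: CarrierCallParams | None = None,
) -> list:
    """Genotype every sample for a deletion in ``region`` (chrom, start, end).

    Evidence flags per sample: mean in-region LRR below the one-copy
    threshold; no heterozygous call in the region (obligate homozygosity);
    involvement in at least one Mendelian conflict at an in-region marker;
    carriage of the tag haplotype (when assignments are supplied).

    Decision rule: carrier iff (low-LRR AND obligate-homozygosity) OR
    (tag-haplotype AND at least one other flag). A sample with depressed LRR
    but a heterozygous call in the region is ambiguous (contradictory
    evidence); everything else is a non-carrier.
    """
    if params is None:
        params = CarrierCallParams()
    chrom, start, end = region
    mask = (dataset.markers.in_interval(start, end)
            & (dataset.markers.table["chromosome"] == chrom).to_numpy())
    if not mask.any():
        raise ValueError("region contains no markers")
    calls = dataset.calls[:, mask]
    lrr = dataset.lrr[:, mask]
    called = calls >= 0
    with np.errstate(invalid="ignore"):
        mean_lrr = np.where(called.any(axis=1),
                            np.where(called, lrr, np.nan).mean(axis=1,
                                                               where=called),
                            0.0)
    low_lrr = mean_lrr < params.lrr_threshold
    oblig = ~(calls == 1).any(axis=1)

    conflict = np.zeros(dataset.n_samples, dtype=bool)
    if pedigree is not None:
        ids = {a: i for i, a in enumerate(dataset.animal_ids)}
        t = pedigree.table
        from .arrayqc import _duo_conflict

        for child, sire, dam in zip(t["animal_id"], t["sire_id"], t["dam_id"]):
            ci = ids.get(child)
            if ci is None:
                continue
            for parent in (sire, dam):
                pi = ids.get(parent)
                if pi is None:
                    continue
                if _duo_conflict(calls[pi], calls[ci]).any():
                    conflict[pi] = conflict[ci] = True

    tags = np.zeros(dataset.n_samples, dtype=bool)
    if tag_assignments is not None:
        tags = np.array([bool(tag_assignments.get(a, False))
                         for a in dataset.animal_ids])

    w = params.score_weights
    score = (w["low_lrr"] * low_lrr + w["obligate_hom"] * oblig
             + w["conflict_implicated"] * conflict + w["tag_haplotype"] * tags)
    out = []
    for i in range(dataset.n_samples):
        n_other = int(low_lrr[i]) + int(oblig[i]) + int(conflict[i])
        if (low_lrr[i] and oblig[i]) or (tags[i] and n_other >= 1):
            status = "carrier"
        elif low_lrr[i] and not oblig[i]:
            status = "ambiguous"
        else:
            status = "non-carrier"
        out.append(DeletionCall(
            sample_id=int(dataset.animal_ids[i]),
            status=status,
            low_lrr=bool(low_lrr[i]),
            obligate_hom=bool(oblig[i]),
            conflict_implicated=bool(conflict[i]),
            tag_haplotype=bool(tags[i]),
            score=float(score[i]),
            mean_lrr=float(mean_lrr[i]),
        ))
    return out


def calls_to_frame(calls: list) -> pd.DataFrame:
    """Deletion calls as a tidy evidence table."""
    return pd.DataFrame([c.__dict__ for c in calls])


def estimate_deletion_frequency(carrier_status: np.ndarray,
                                gamete_pool: bool = True) -> float:
    """Deletion allele frequency from live-animal carrier calls.

    Among live animals no homozygote exists for a fully lethal deletion, so
    the naive estimate carrier_count / 2n underestimates the gamete-pool
    frequency: a live-animal allele frequency of p/(1+p) corresponds to a
    gamete-pool frequency p. With ``gamete_pool`` (default) the estimate is
    corrected back to the gamete pool: p = c / (2 - c) for carrier fraction c.
    """
    c = float(np.mean(np.asarray(carrier_status) == 1))
    if gamete_pool:
        return c / (2.0 - c)
    return c / 2.0


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(x: np.ndarray, y: np.ndarray) -> LDResult:
    """Squared correlation between deletion dosage and tag-haplotype dosage.

    Accepts haplotype-level 0/1 indicator vectors (giving the classical
    r^2 = D^2 / (p(1-p)q(1-q))) or diploid dosages; either way the statistic
    is the squared Pearson correlation, which the haplotype form reduces to.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("monomorphic input: r2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return LDResult(r2=float(r * r),
                    freq_x=float(x.mean() / max(x.max(), 1)),
                    freq_y=float(y.mean() / max(y.max(), 1)),
                    n=len(x))


# ---------------------------------------------------------------------------
# homozygote depletion
# ---------------------------------------------------------------------------


def homozygote_depletion_test(n: int, q: float, k: int) -> float:
    """One-sided binomial test for too few tag-haplotype homozygotes.

    Under random mating a haplotype at frequency q yields homozygous
    diplotypes at rate q^2; observing k homozygotes among n diplotypes gives
    the tail p-value P(K <= k) with K ~ Binomial(n, q^2). For the
    absence-of-homozygotes case k = 0 this is (1 - q^2)^n.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if k < 0 or k > n:
        raise ValueError("k must lie in [0, n]")
    return float(stats.binom.cdf(k, n, q * q))
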