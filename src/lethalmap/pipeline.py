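"""End-to-end scenario runner: rediscover the planted deletion from scratch.

``run_scenario`` chains the full narrative on synthetic data: simulate a
cohort segregating the lethal deletion; QC the 50K array calls and scan for
clustered anomalies; genotype samples for the deletion from combined array
evidence; cluster haplotypes into ancestral states and measure how well the
best state tags the deletion (and map the fertility/milk QTL); resolve the
breakpoint at base-pair precision from simulated short reads; and estimate
stage-specific death fractions of homozygous conceptuses from the
insemination records. Every artifact is written under a run directory with
a manifest (config hash, seed, package version) that reproduces the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrayqc, assoc, cnvcall, formats, lethality, simpop, svreads

__all__ = ["PipelineConfig", "run_scenario", "demo_config"]


@dataclass
class SVStageConfig:
    reference_length: int = 3_000_000
    coverage: float = 20.0
    read_len: int = 91
    microhomology: int = 2
    insertion: str = "C"


@dataclass
class HapscanConfig:
    enabled: bool = True
    K: int = 20
    window_bp: int = 4_000_000  # centred on the candidate region
    n_iter: int = 25
    n_starts: int = 3


@dataclass
class PipelineConfig:
    name: str = "default"
    seed: int = 1
    out_dir: str = "runs"
    population: simpop.PopulationConfig = field(default_factory=simpop.PopulationConfig)
    sv: SVStageConfig = field(default_factory=SVStageConfig)
    hapscan: HapscanConfig = field(default_factory=HapscanConfig)
    run_gwas: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls()
        for k, v in raw.items():
            if k == "population":
                for kk, vv in v.items():
                    setattr(cfg.population, kk, vv)
            elif k == "sv":
                for kk, vv in v.items():
                    setattr(cfg.sv, kk, vv)
            elif k == "hapscan":
                for kk, vv in v.items():
                    setattr(cfg.hapscan, kk, vv)
            else:
                setattr(cfg, k, v)
        return cfg


def demo_config(seed: int = 1) -> PipelineConfig:
    """Desk-scale scenario: ~2,000 live animals, one chromosome, 2x10^5
    insemination records, 3 Mb sequence fixture at 20x."""
    pop = simpop.PopulationConfig()
    pop.repro.n_records = 200_000
    cfg = PipelineConfig(name="demo", seed=seed, population=pop)
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_scenario(config: PipelineConfig) -> Path:
    """Execute the full scenario; returns the run directory.

    Any stage failure leaves the artifacts written so far in place and
    re-raises (non-zero exit under the CLI).
    """
    run_dir = Path(config.out_dir) / f"{config.name}_seed{config.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "package": "lethalmap",
        "version": __import__("lethalmap").__version__,
    }
    (run_dir / "config.yaml").write_text(cfg_yaml)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report: dict = {"scenario": config.name, "seed": config.seed}
    root = np.random.default_rng(config.seed)
    s_pop, s_sv1, s_sv2, s_hmm = (int(x) for x in root.integers(0, 2**31 - 1, 4))

    # --- stage 1: simulate ---
    cohort = simpop.simulate_cohort_full(config.population, s_pop)
    truth = cohort.deletion
    report["truth"] = {"start_bp": truth.start_bp, "end_bp": truth.end_bp,
                       "length_bp": truth.length_bp}
    mask_50k = (cohort.markers.table["panel"] == "50K").to_numpy()
    arr50 = cohort.array.subset_markers(mask_50k)
    formats.write_signal_report(arr50, run_dir / "signal_report_50k.tsv")
    cohort.inseminations.table.to_csv(run_dir / "inseminations.tsv", sep="\t", index=False)
    cohort.traits.table.to_csv(run_dir / "trait_proofs.tsv", sep="\t", index=False)

    # --- stage 2: QC + anomaly scan ---
    filtered, marker_report, sample_report = arrayqc.qc_filter(
        arr50, pedigree=cohort.pedigree)
    marker_report.table.drop(columns=["marker_ids"], errors="ignore").to_csv(
        run_dir / "marker_qc.tsv", sep="\t", index=False)
    regions = arrayqc.anomaly_scan(marker_report)
    if len(regions):
        formats.write_bed(regions, run_dir / "anomaly_regions.bed")
    truth_iv = (truth.start_bp, truth.end_bp)
    overlap = 0.0
    if len(regions):
        r = regions.iloc[0]
        inter = max(0, min(r["end"], truth_iv[1]) - max(r["start"], truth_iv[0]))
        overlap = inter / max(truth_iv[1] - truth_iv[0],
                              r["end"] - r["start"], 1)
    report["anomaly_scan"] = {
        "n_regions": int(len(regions)),
        "regions": regions.drop(columns=["marker_ids"]).to_dict("records")
        if len(regions) else [],
        "reciprocal_overlap_with_truth": overlap,
    }

    # --- stage 3: carrier calling ---
    region = (truth.chromosome,
              int(regions.iloc[0]["start"]) if len(regions) else truth.start_bp,
              int(regions.iloc[0]["end"]) if len(regions) else truth.end_bp)
    calls = cnvcall.call_deletion_carriers(arr50, region, pedigree=cohort.pedigree)
    call_df = cnvcall.calls_to_frame(calls)
    call_df.to_csv(run_dir / "deletion_calls.tsv", sep="\t", index=False)
    carrier = {c.sample_id: c.status == "carrier" for c in calls}
    truth_status = dict(zip(cohort.phased.animal_ids,
                            cohort.phased.deletion_copies))
    agree = np.mean([carrier[a] == (truth_status[a] >= 1) for a in carrier])
    p_hat = cnvcall.estimate_deletion_frequency(
        np.array([1 if carrier[a] else 0 for a in carrier]))
    report["carrier_calling"] = {"concordance": float(agree),
                                 "estimated_p": float(p_hat)}
    formats.write_deletion_vcf(
        run_dir / "deletion_array.vcf", truth.chromosome, region[1], region[2] + 1,
        samples={a: (1 if carrier[a] else 0) for a in list(carrier)[:50]})

    # --- stage 4: haplotype clustering + tag LD (+ optional LRT) ---
    if config.hapscan.enabled:
        pos = cohort.markers.positions
        centre = (truth.start_bp + truth.end_bp) // 2
        win = (pos >= centre - config.hapscan.window_bp // 2) \
            & (pos <= centre + config.hapscan.window_bp // 2) & mask_50k
        haps = cohort.phased.haplotypes[:, :, win].reshape(
            cohort.phased.n_animals * 2, -1)
        owners = np.repeat(np.arange(cohort.phased.n_animals), 2)
        model = assoc.fit_ancestral_hmm(
            haps, pos[win], K=config.hapscan.K, seed=s_hmm,
            n_iter=config.hapscan.n_iter, n_starts=config.hapscan.n_starts,
            hap_owner=owners)
        wpos = pos[win]
        in_del = np.where((wpos >= truth.start_bp) & (wpos <= truth.end_bp))[0]
        if len(in_del) == 0:
            in_del = [min(int(np.searchsorted(wpos, centre)), win.sum() - 1)]
        post = model.posterior_mean(in_del)
        assign = post.argmax(axis=1)
        del_flags = cohort.phased.del_flags.reshape(-1)
        tag_state = int(np.bincount(assign[del_flags],
                                    minlength=model.n_states).argmax()) \
            if del_flags.any() else -1
        if tag_state >= 0:
            tag_vec = (assign == tag_state).astype(int)
            ld = cnvcall.ld_r2(del_flags.astype(int), tag_vec)
            report["hapscan"] = {"tag_state": tag_state, "ld_r2": ld.r2,
                                 "tag_freq": float(tag_vec.mean())}
        else:
            report["hapscan"] = {"tag_state": None, "ld_r2": None}

    # --- stage 5: GWAS on the fertility index ---
    if config.run_gwas:
        ped = cohort.pedigree.table
        bulls = ped[(ped["sex"] == "M") & (ped["generation"] > 0)]["animal_id"].to_numpy()
        tr = cohort.traits.trait("fertility_index").set_index("animal_id")
        bulls = np.array([b for b in bulls if b in tr.index])
        y = tr.loc[bulls, "value"].to_numpy()
        idx = {a: i for i, a in enumerate(cohort.phased.animal_ids)}
        rows = [idx[b] for b in bulls]
        geno = cohort.phased.genotype_dosage()[rows][:, mask_50k]
        pcs = assoc.pca_covariates(geno, k=4)
        kin = assoc.kinship_matrix(cohort.pedigree, subjects=bulls)
        gwas = assoc.snp_mixed_gwas(y, geno, pcs, kin)
        gwas["position"] = cohort.markers.positions[mask_50k]
        gwas.to_csv(run_dir / "gwas_fertility_index.tsv", sep="\t", index=False)
        thr = assoc.bonferroni_threshold(0.05, 50_000)
        sig = gwas[gwas["p"] < thr]
        peak = gwas.loc[gwas["p"].idxmin()] if gwas["p"].notna().any() else None
        report["gwas"] = {
            "threshold": thr,
            "n_significant": int(len(sig)),
            "qtl_detected": bool(len(sig)),
            "peak_position": int(peak["position"]) if peak is not None else None,
            "peak_p": float(peak["p"]) if peak is not None else None,
        }
        if not len(sig):
            report["gwas"]["note"] = "no QTL detected at the genome-wide threshold"

    # --- stage 6: sequence-level breakpoint resolution ---
    svc = config.sv
    margin = (svc.reference_length - truth.length_bp) // 2
    origin = max(1, truth.start_bp - margin)
    dele = svreads.PlantedDeletion(proximal_end=truth.start_bp - 1,
                                   length=truth.length_bp,
                                   microhomology=svc.microhomology,
                                   insertion=svc.insertion)
    ref = svreads.make_reference(length=svc.reference_length, deletion=dele,
                                 origin=origin, seed=s_sv1)
    carrier_seq = svreads.build_carrier_allele(ref, dele)
    reads = svreads.simulate_reads(
        [("wt", ref.codes, 0.5), ("carrier", carrier_seq, 0.5)],
        coverage=svc.coverage, read_len=svc.read_len, seed=s_sv2)
    aln = svreads.align_reads(reads, ref)
    sv_call = svreads.call_deletion_sv(aln, ref)
    formats.write_fasta({ref.name: ref.sequence}, run_dir / "reference.fasta")
    formats.write_sam_like(aln.table, run_dir / "alignments.tsv")
    report["sv"] = {
        "planted": {"size": dele.length, "microhomology": dele.microhomology,
                    "insertion": dele.insertion},
        "called": None if sv_call is None else {
            "size": sv_call.size, "microhomology": sv_call.microhomology,
            "insertion": sv_call.insertion,
            "proximal_end": sv_call.proximal_end,
            "distal_start": sv_call.distal_start,
            "n_split_reads": sv_call.n_split_reads,
            "n_discordant_pairs": sv_call.n_discordant_pairs,
            "depth_ratio": sv_call.depth_ratio,
        },
    }
    if sv_call is not None:
        formats.write_deletion_vcf(
            run_dir / "deletion_sv.vcf", truth.chromosome,
            sv_call.proximal_end, sv_call.distal_start,
            microhomology=sv_call.microhomology, insertion=sv_call.insertion)

    # --- stage 7: lethality analysis ---
    annotated, counts = lethality.classify_matings(
        cohort.inseminations, {a: truth_status[a] >= 1 for a in truth_status})
    if annotated["mating_type"].nunique() >= 2 and p_hat > 0:
        table, estimates = lethality.death_fraction_curve(
            annotated, p=p_hat, seed=config.seed, n_bootstrap=50)
        table.table.to_csv(run_dir / "failure_rates.tsv", sep="\t", index=False)
        report["lethality"] = {
            "mating_counts": counts,
            "death_fractions": [{
                "day": e.day, "estimate": e.death_fraction,
                "ci": [e.ci_low, e.ci_high]} for e in estimates],
            "true_schedule": {str(k): v for k, v in truth.lethality.items()},
        }
    else:
        report["lethality"] = {
            "mating_counts": counts,
            "note": "no carrier matings observed; lethality analysis skipped",
        }

    # --- stage 8: antagonistic trait effects ---
    effects = {}
    for trait in ("fertility_index", "milk"):
        tt = cohort.traits.trait(trait)
        cop = np.array([truth_status[a] for a in tt["animal_id"]], dtype=float)
        v = tt["value"].to_numpy()
        X = np.column_stack([np.ones_like(cop), cop])
        b, *_ = np.linalg.lstsq(X, v, rcond=None)
        effects[trait] = float(b[1])
    report["trait_effects_per_copy"] = effects

    (run_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    _write_summary(report, run_dir / "summary.txt")
    return run_dir


def _write_summary(report: dict, path: Path) -> None:
    lines = [f"scenario {report['scenario']} (seed {report['seed']})"]
    t = report.get("truth", {})
    lines.append(f"planted deletion: {t.get('start_bp')}-{t.get('end_bp')} "
                 f"({t.get('length_bp')} bp)")
    a = report.get("anomaly_scan", {})
    lines.append(f"anomaly scan: {a.get('n_regions')} region(s), reciprocal "
                 f"overlap with truth {a.get('reciprocal_overlap_with_truth'):.3f}")
    c = report.get("carrier_calling", {})
    lines.append(f"carrier calling: concordance {c.get('concordance'):.4f}, "
                 f"estimated p {c.get('estimated_p'):.4f}")
    h = report.get("hapscan")
    if h:
        r2 = h.get("ld_r2")
        lines.append(f"tag haplotype: state {h.get('tag_state')}, "
                     f"LD r2 with deletion {r2 if r2 is None else round(r2, 4)}")
    g = report.get("gwas")
    if g:
        lines.append(f"gwas: {'QTL detected' if g['qtl_detected'] else 'no QTL detected'}"
                     f" (peak p {g.get('peak_p')})")
    s = report.get("sv", {}).get("called")
    if s:
        lines.append(f"sv call: size {s['size']} bp, microhomology "
                     f"{s['microhomology']}, insertion '{s['insertion']}', "
                     f"depth ratio {s['depth_ratio']:.3f}")
    for e in report.get("lethality", {}).get("death_fractions", []):
        lines.append(f"death fraction by day {e['day']}: {e['estimate']:.3f} "
                     f"[{e['ci'][0]:.3f}, {e['ci'][1]:.3f}]")
    eff = report.get("trait_effects_per_copy", {})
    if eff:
        lines.append("per-copy effects: "
                     + ", ".join(f"{k} {v:+.3f}" for k, v in eff.items()))
    path.write_text("\n".join(lines) + "\n")
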