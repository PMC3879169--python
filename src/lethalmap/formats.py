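"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 1-based closed intervals everywhere; BED files on
disk are 0-based half-open and converted on the way in/out. Genotype tables
round-trip through PLINK-style .ped/.map text and VCF 4.2; deletion calls
are written as VCF symbolic ``<DEL>`` records with END/SVLEN/HOMLEN/HOMSEQ
and an untemplated-insertion INFO field; alignments use a documented
SAM-like TSV with an optional converter to real SAM (via pysam).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simpop import ArrayDataset, MarkerMap, Pedigree

__all__ = [
    "bed_to_internal",
    "internal_to_bed",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_plink",
    "write_plink",
    "read_genotype_vcf",
    "write_genotype_vcf",
    "write_deletion_vcf",
    "read_deletion_vcf",
    "write_signal_report",
    "read_signal_report",
    "write_sam_like",
    "sam_like_to_sam",
]


# ---------------------------------------------------------------------------
# interval conventions
# ---------------------------------------------------------------------------


def internal_to_bed(start: int, end: int) -> tuple:
    """1-based closed [start, end] -> 0-based half-open [start-1, end)."""
    return start - 1, end


def bed_to_internal(start: int, end: int) -> tuple:
    """0-based half-open [start, end) -> 1-based closed [start+1, end]."""
    return start + 1, end


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write chromosome/start/end (internal 1-based closed) as BED."""
    with open(path, "w") as f:
        for _, r in intervals.iterrows():
            s, e = internal_to_bed(int(r["start"]), int(r["end"]))
            name = r.get("name", ".")
            f.write(f"{r['chromosome']}\t{s}\t{e}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            s, e = bed_to_internal(int(parts[1]), int(parts[2]))
            rows.append({"chromosome": parts[0], "start": s, "end": e,
                         "name": parts[3] if len(parts) > 3 else "."})
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(records: dict, path, width: int = 70) -> None:
    with open(path, "w") as f:
        for name, seq in records.items():
            f.write(f">{name}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i: i + width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# PLINK-style text
# ---------------------------------------------------------------------------

_CALL_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), -1: ("0", "0")}
_ALLELES_TO_CALL = {v: k for k, v in _CALL_TO_ALLELES.items()}
_ALLELES_TO_CALL[("B", "A")] = 1


def write_plink(dataset: ArrayDataset, prefix, pedigree: Pedigree | None = None) -> None:
    """Write calls as .ped/.map text (alleles A/B, missing 0)."""
    prefix = Path(prefix)
    mt = dataset.markers.table
    with open(prefix.with_suffix(".map"), "w") as f:
        for _, r in mt.iterrows():
            f.write(f"{r['chromosome']}\t{r['marker_id']}\t0\t{r['position']}\n")
    parents = {}
    sexes = {}
    if pedigree is not None:
        t = pedigree.table
        parents = {a: (s, d) for a, s, d in zip(t["animal_id"], t["sire_id"], t["dam_id"])}
        sexes = dict(zip(t["animal_id"], t["sex"]))
    with open(prefix.with_suffix(".ped"), "w") as f:
        for i, aid in enumerate(dataset.animal_ids):
            sire, dam = parents.get(aid, (0, 0))
            sex = {"M": 1, "F": 2}.get(sexes.get(aid), 0)
            fields = ["FAM", str(aid), str(sire), str(dam), str(sex), "-9"]
            for c in dataset.calls[i]:
                a, b = _CALL_TO_ALLELES[int(c)]
                fields += [a, b]
            f.write(" ".join(fields) + "\n")


def read_plink(prefix) -> tuple:
    """Read .ped/.map text back into (animal_ids, calls, MarkerMap)."""
    prefix = Path(prefix)
    rows = []
    with open(prefix.with_suffix(".map")) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{prefix}.map:{ln}: malformed map line")
            rows.append({"marker_id": parts[1], "chromosome": parts[0],
                         "position": int(parts[3]), "panel": "NA",
                         "allele_a": "A", "allele_b": "B"})
    markers = MarkerMap(pd.DataFrame(rows))
    ids, calls = [], []
    with open(prefix.with_suffix(".ped")) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            geno = parts[6:]
            if len(geno) != 2 * len(markers):
                raise ValueError(f"{prefix}.ped:{ln}: wrong genotype count")
            ids.append(int(parts[1]))
            calls.append([_ALLELES_TO_CALL.get((geno[2 * j], geno[2 * j + 1]), -1)
                          for j in range(len(markers))])
    return np.asarray(ids), np.asarray(calls, dtype=np.int8), markers


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_genotype_vcf(dataset: ArrayDataset, path,
                       contig_length: int | None = None) -> None:
    """Biallelic SNP calls as VCF 4.2 (REF=A, ALT=B placeholder alleles)."""
    mt = dataset.markers.table
    chroms = mt["chromosome"].unique()
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            ln = contig_length or int(mt["position"].max()) + 1
            f.write(f"##contig=<ID={c},length={ln}>\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(a) for a in dataset.animal_ids)
        f.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(len(mt)):
            r = mt.iloc[j]
            gts = "\t".join(_VCF_GT[int(c)] for c in dataset.calls[:, j])
            f.write(f"{r['chromosome']}\t{r['position']}\t{r['marker_id']}"
                    f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotype_vcf(path) -> tuple:
    """Read a biallelic VCF into (animal_ids, calls, MarkerMap) via pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    ids = [int(s) if str(s).isdigit() else s for s in vf.header.samples]
    rows, calls = [], []
    for rec in vf:
        rows.append({"marker_id": rec.id or f"{rec.chrom}_{rec.pos}",
                     "chromosome": rec.chrom, "position": rec.pos,
                     "panel": "NA", "allele_a": "A", "allele_b": "B"})
        row = []
        for s in vf.header.samples:
            gt = rec.samples[s]["GT"]
            row.append(-1 if gt is None or None in gt else int(sum(gt)))
        calls.append(row)
    vf.close()
    return (np.asarray(ids), np.asarray(calls, dtype=np.int8).T,
            MarkerMap(pd.DataFrame(rows)))


def write_deletion_vcf(path, chrom: str, proximal_end: int, distal_start: int,
                       microhomology: int = 0, homology_seq: str = "",
                       insertion: str = "", samples: dict | None = None,
                       contig_length: int | None = None) -> None:
    """Symbolic <DEL> record; POS is the last retained base, END the last
    deleted base (VCF convention), SVLEN negative deleted length."""
    size = distal_start - proximal_end - 1
    end = distal_start - 1
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={chrom},length={contig_length or end + 10_000_000}>\n")
        f.write('##ALT=<ID=DEL,Description="Deletion">\n')
        f.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        f.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        f.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        f.write('##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">\n')
        f.write('##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology sequence">\n')
        f.write('##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Untemplated insertion">\n')
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        info = f"SVTYPE=DEL;END={end};SVLEN={-size};HOMLEN={microhomology}"
        if homology_seq:
            info += f";HOMSEQ={homology_seq}"
        if insertion:
            info += f";INSSEQ={insertion}"
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            header += "\tFORMAT\t" + "\t".join(str(s) for s in samples)
        f.write(header + "\n")
        line = f"{chrom}\t{proximal_end}\tDEL1\tN\t<DEL>\t.\tPASS\t{info}"
        if samples:
            line += "\tGT\t" + "\t".join(_VCF_GT[int(v)] for v in samples.values())
        f.write(line + "\n")


def read_deletion_vcf(path) -> dict:
    """Read the first symbolic <DEL> record back (via pysam)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    for rec in vf:
        if rec.alts and rec.alts[0] == "<DEL>":
            info = dict(rec.info)
            svlen = info.get("SVLEN", 0)
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            out = {
                "chromosome": rec.chrom,
                "proximal_end": rec.pos,
                "end": rec.stop,
                "size": -int(svlen),
                "microhomology": int(info.get("HOMLEN", 0)),
                "insertion": str(info.get("INSSEQ", "")),
                "genotypes": {s: (-1 if None in rec.samples[s]["GT"] else
                                  sum(rec.samples[s]["GT"]))
                              for s in vf.header.samples} if vf.header.samples else {},
            }
            vf.close()
            return out
    vf.close()
    raise ValueError("no <DEL> record found")


# ---------------------------------------------------------------------------
# signal report and tabular outputs
# ---------------------------------------------------------------------------

_CALL_STR = {0: "AA", 1: "AB", 2: "BB", -1: "--"}
_STR_CALL = {v: k for k, v in _CALL_STR.items()}


def write_signal_report(dataset: ArrayDataset, path) -> None:
    """Long-format tab-separated intensity report (sample, marker, call,
    LRR, quality), the shape array-scanner software exports."""
    mids = dataset.markers.table["marker_id"].to_numpy()
    with open(path, "w") as f:
        f.write("sample_id\tmarker_id\tcall\tlrr\tquality\n")
        for i, aid in enumerate(dataset.animal_ids):
            for j, mid in enumerate(mids):
                f.write(f"{aid}\t{mid}\t{_CALL_STR[int(dataset.calls[i, j])]}"
                        f"\t{dataset.lrr[i, j]:.4f}\t{dataset.quality[i, j]:.4f}\n")


def read_signal_report(path, markers: MarkerMap) -> ArrayDataset:
    df = pd.read_csv(path, sep="\t")
    ids = df["sample_id"].unique()
    mid_index = {m: j for j, m in enumerate(markers.table["marker_id"])}
    n, m = len(ids), len(markers)
    calls = np.full((n, m), -1, dtype=np.int8)
    lrr = np.zeros((n, m))
    qual = np.zeros((n, m))
    id_index = {a: i for i, a in enumerate(ids)}
    ii = df["sample_id"].map(id_index).to_numpy()
    jj = df["marker_id"].map(mid_index).to_numpy()
    calls[ii, jj] = df["call"].map(_STR_CALL).to_numpy(dtype=np.int8)
    lrr[ii, jj] = df["lrr"].to_numpy()
    qual[ii, jj] = df["quality"].to_numpy()
    return ArrayDataset(np.asarray(ids), markers, calls, lrr, qual)


# ---------------------------------------------------------------------------
# SAM-like alignments
# ---------------------------------------------------------------------------

SAM_LIKE_COLUMNS = [
    "pair", "mate", "aligned", "split", "strand", "pos", "mismatches",
    "block1_start", "block1_end", "block2_start", "block2_end",
    "gap_seq", "mate_distance",
]


def write_sam_like(table: pd.DataFrame, path) -> None:
    table[SAM_LIKE_COLUMNS].to_csv(path, sep="\t", index=False)


def sam_like_to_sam(table: pd.DataFrame, reference_name: str,
                    reference_length: int, read_len: int, path) -> None:
    """Convert the alignment table to a minimal valid SAM (checked by pysam).

    Sequences/qualities are not retained in the table, so SEQ/QUAL are '*';
    split reads are emitted as two lines with soft-clipped CIGARs.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": reference_name, "LN": int(reference_length)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, r in table.iterrows():
            if not r["aligned"]:
                continue
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"pair{int(r['pair'])}"
            a.flag = (16 if r["strand"] == "-" else 0) | (1 | (64 if r["mate"] == 1 else 128))
            a.reference_id = 0
            a.reference_start = int(r["pos"]) - 1
            a.mapping_quality = 60
            if r["split"] and r["block1_start"] >= 0:
                b1 = int(r["block1_end"]) - int(r["block1_start"]) + 1
                a.cigarstring = f"{b1}M{read_len - b1}S"
            else:
                a.cigarstring = f"{read_len}M"
            out.write(a)
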