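"""Short-read simulation and breakpoint resolution for a large deletion.

The deletion leaves three sequence-level signatures in a heterozygous
carrier: halved read depth across the interval, read pairs whose mates map
much further apart than the library insert, and split reads that straddle
the junction and resolve it to the base pair. Junctions of non-homologous
end joining typically show a few bases of microhomology between the two
flanks, sometimes with a short untemplated insertion; both are modelled and
recovered here.

Coordinate conventions (documented once, used everywhere):

* reference positions are 1-based; ``origin`` lets a simulated segment
  represent an arbitrary genomic window;
* a planted deletion is ``(proximal_end, length, microhomology, insertion)``
  where ``proximal_end`` is the last retained base before the junction;
* the carrier allele is ``ref[1..proximal_end] + insertion +
  ref[proximal_end+length+1 .. end]``;
* reported deletion size is the number of reference bases absent from the
  carrier allele (unambiguous under microhomology);
* microhomology is assigned to the proximal side: it is the longest h for
  which the h retained bases ending at ``proximal_end`` equal the h deleted
  bases immediately preceding the distal retained flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentSet",
    "BreakpointCall",
    "PlantedDeletion",
    "ReadSet",
    "SyntheticReference",
    "align_reads",
    "build_carrier_allele",
    "call_deletion_sv",
    "make_reference",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def encode(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode()
    codes = _CODE[np.frombuffer(seq, dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


# ---------------------------------------------------------------------------
# reference and planted deletion
# ---------------------------------------------------------------------------


@dataclass
class PlantedDeletion:
    proximal_end: int  # 1-based last retained base (in origin coordinates)
    length: int
    microhomology: int = 0
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("deleted length must be positive")
        if self.microhomology < 0:
            raise ValueError("microhomology must be >= 0")

    @property
    def distal_start(self) -> int:
        """First retained base after the junction (1-based)."""
        return self.proximal_end + self.length + 1


@dataclass
class SyntheticReference:
    name: str
    codes: np.ndarray  # uint8 base codes
    origin: int = 1  # genomic coordinate of the first base
    repeats: pd.DataFrame | None = None  # LINE-like annotations at breakpoints

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def local(self, pos_1based: int) -> int:
        """Origin coordinate -> 0-based index into ``codes``."""
        return pos_1based - self.origin


def make_reference(
    length: int = 3_000_000,
    deletion: PlantedDeletion | None = None,
    origin: int = 1,
    seed: int = 0,
    name: str = "chr12_segment",
) -> SyntheticReference:
    """Random reference with junction content pinned for exact recovery.

    The bases around the planted junction are edited so that (i) the stated
    microhomology holds exactly and is maximal, and (ii) neither the
    insertion nor the distal flank accidentally extends an alignment across
    the junction. This makes breakpoint recovery a well-posed round trip.
    LINE-like repeat annotations are recorded at both breakpoints to mirror
    the repeat context such deletions typically arise in.
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    repeats = None
    if deletion is not None:
        d = deletion
        p = d.proximal_end - origin  # 0-based index of last retained base
        dist = d.distal_start - origin  # 0-based index of first distal retained base
        if p - d.microhomology < 0 or dist > length:
            raise ValueError("deletion does not fit inside the reference")
        h = d.microhomology
        ins = encode(d.insertion) if d.insertion else np.empty(0, dtype=np.uint8)
        # the base just before the distal flank must not match the last
        # junction character of the carrier allele (insertion end, or the
        # last proximal base when there is no insertion), or the suffix
        # block would extend across the junction; with microhomology that
        # base is a copy of codes[p], so edit codes[p] first
        if len(ins) and codes[p] == ins[-1]:
            codes[p] = (ins[-1] + 1) % 4
        # plant the microhomology: last h retained proximal bases equal the
        # h deleted bases just before the distal flank
        if h:
            codes[dist - h: dist] = codes[p - h + 1: p + 1]
        # cap it so the stated h is maximal
        codes[dist - h - 1] = (codes[p - h] + 1) % 4
        if len(ins):
            if h == 0:
                # codes[dist-1] must differ from both codes[p] (cap, already
                # enforced above) and the insertion end
                if codes[dist - 1] == ins[-1]:
                    forbidden = {int(codes[p]), int(ins[-1])}
                    codes[dist - 1] = next(b for b in range(4) if b not in forbidden)
            # the proximal flank must not extend into the insertion
            if ins[0] == codes[p + 1]:
                codes[p + 1] = (ins[0] + 1) % 4
        else:
            # no insertion: the proximal flank must stop exactly at p
            if codes[p + 1] == codes[dist]:
                codes[p + 1] = (codes[dist] + 1) % 4
        repeats = pd.DataFrame({
            "name": ["L1ME1-like", "L1BT-like"],
            "start": [d.proximal_end - 700, d.distal_start - 1],
            "end": [d.proximal_end + 35, d.distal_start + 5252],
        })
    return SyntheticReference(name=name, codes=codes, origin=origin, repeats=repeats)


def build_carrier_allele(reference: SyntheticReference,
                         deletion: PlantedDeletion) -> np.ndarray:
    """Carrier chromosome: excise the deleted segment, place the insertion.

    Verifies that the stated microhomology is consistent with the reference
    content (forced by :func:`make_reference`).
    """
    p = reference.local(deletion.proximal_end)
    dist = reference.local(deletion.distal_start)
    if p < 0 or dist > len(reference.codes):
        raise ValueError("deletion outside the reference")
    h = deletion.microhomology
    if h and not np.array_equal(reference.codes[p - h + 1: p + 1],
                                reference.codes[dist - h: dist]):
        raise ValueError("stated microhomology inconsistent with reference content")
    ins = encode(deletion.insertion) if deletion.insertion else np.empty(0, dtype=np.uint8)
    return np.concatenate([reference.codes[: p + 1], ins, reference.codes[dist:]])


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Paired-end reads; ``truth`` records provenance for test oracles only."""

    r1: np.ndarray  # (n, read_len) uint8, forward strand of the fragment
    r2: np.ndarray  # (n, read_len) uint8, as sequenced (reverse complement)
    read_len: int
    truth: pd.DataFrame | None = None

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def to_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@pair{i}/1\n{decode(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@pair{i}/2\n{decode(self.r2[i])}\n+\n{qual}\n")


@dataclass
class InsertMix:
    """Two-component fragment-length mixture (gel-purified libraries)."""

    means: tuple = (300.0, 800.0)
    sds: tuple = (30.0, 80.0)
    weights: tuple = (0.5, 0.5)


def simulate_reads(
    alleles: list,
    coverage: float,
    read_len: int = 91,
    insert_mix: InsertMix | None = None,
    base_error: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Uniform shotgun paired-end reads from weighted allele sequences.

    ``alleles`` is a list of ``(name, codes, weight)`` where the weight is
    the molar (per-chromosome) proportion; a heterozygous carrier is the
    50/50 two-allele mixture. Fragments are sampled per molecule, so an
    allele's read share is proportional to weight x length and each allele
    receives per-base depth ``coverage * weight`` -- a heterozygous deletion
    therefore shows half depth inside the interval. The pair count is
    ``n_pairs = coverage * weighted_mean_length / (2 * read_len)``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mix is None:
        insert_mix = InsertMix()
    rng = np.random.default_rng(seed)
    names = [a[0] for a in alleles]
    seqs = [np.asarray(a[1], dtype=np.uint8) for a in alleles]
    w = np.array([a[2] for a in alleles], dtype=float)
    w = w / w.sum()
    lens = np.array([len(s) for s in seqs], dtype=float)
    mean_len = float(np.dot(w, lens))
    n_pairs = int(round(coverage * mean_len / (2.0 * read_len)))
    if n_pairs == 0:
        return ReadSet(np.empty((0, read_len), np.uint8),
                       np.empty((0, read_len), np.uint8), read_len,
                       truth=pd.DataFrame(columns=["allele", "start", "insert"]))

    molar = w * lens / np.dot(w, lens)
    allele_of = rng.choice(len(seqs), size=n_pairs, p=molar)
    comp = rng.choice(len(insert_mix.means), size=n_pairs,
                      p=np.asarray(insert_mix.weights) / np.sum(insert_mix.weights))
    ins = rng.normal(np.asarray(insert_mix.means)[comp],
                     np.asarray(insert_mix.sds)[comp])
    ins = np.maximum(np.round(ins).astype(np.int64), 2 * read_len)

    r1 = np.empty((n_pairs, read_len), dtype=np.uint8)
    r2 = np.empty((n_pairs, read_len), dtype=np.uint8)
    starts = np.empty(n_pairs, dtype=np.int64)
    offs = np.arange(read_len)
    for ai, seq in enumerate(seqs):
        m = allele_of == ai
        if not m.any():
            continue
        L = len(seq)
        ins[m] = np.minimum(ins[m], L)
        s = rng.integers(0, np.maximum(L - ins[m] + 1, 1))
        starts[m] = s
        r1[m] = seq[s[:, None] + offs]
        ends = s + ins[m]
        r2[m] = 3 - seq[ends[:, None] - 1 - offs]  # reverse complement
    # sequencing errors: substitute with one of the three other bases
    for mat in (r1, r2):
        err = rng.random(mat.shape) < base_error
        if err.any():
            mat[err] = (mat[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
    truth = pd.DataFrame({"allele": np.array(names)[allele_of],
                          "start": starts, "insert": ins})
    return ReadSet(r1, r2, read_len, truth=truth)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSet:
    """SAM-like alignment table plus raw reads for junction analysis.

    ``table`` columns: pair, mate, aligned, split, strand (+/-), pos
    (1-based origin coordinate of the leftmost aligned base), mismatches,
    and for split reads the two block coordinates and the unaligned junction
    residue (``gap_seq``). ``mate_distance`` is the outer distance of the
    pair when both mates align linearly.
    """

    table: pd.DataFrame
    reference: SyntheticReference
    read_len: int


class _KmerIndex:
    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        n = len(codes) - k + 1
        pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        # rolling keys via strided matmul in chunks to bound memory
        keys = np.zeros(n, dtype=np.uint64)
        chunk = 1 << 20
        for a in range(0, n, chunk):
            b = min(a + chunk, n)
            win = np.lib.stride_tricks.sliding_window_view(codes[a: b + k - 1], k)
            keys[a:b] = (win.astype(np.uint64) * pow4).sum(axis=1)
        order = np.argsort(keys, kind="stable")
        self.keys = keys[order]
        self.pos = order.astype(np.int64)
        self.pow4 = pow4

    def lookup(self, query_keys: np.ndarray) -> np.ndarray:
        """First reference position of each key, or -1."""
        i = np.searchsorted(self.keys, query_keys)
        ok = (i < len(self.keys)) & (self.keys[np.minimum(i, len(self.keys) - 1)]
                                     == query_keys)
        out = np.where(ok, self.pos[np.minimum(i, len(self.keys) - 1)], -1)
        return out


def _seed_keys(reads: np.ndarray, off: int, k: int, pow4: np.ndarray) -> np.ndarray:
    return (reads[:, off: off + k].astype(np.uint64) * pow4).sum(axis=1)


def _extend_forward(ref: np.ndarray, read: np.ndarray, ref_start: int) -> int:
    """Length of the maximal exact match of ``read`` at ``ref_start``."""
    n = min(len(read), len(ref) - ref_start)
    if n <= 0:
        return 0
    cmp = ref[ref_start: ref_start + n] != read[:n]
    hit = np.argmax(cmp) if cmp.any() else n
    return int(hit)


def _extend_backward(ref: np.ndarray, read: np.ndarray, ref_end: int) -> int:
    """Maximal exact suffix match of ``read`` ending at ref index ref_end-1."""
    n = min(len(read), ref_end)
    if n <= 0:
        return 0
    cmp = ref[ref_end - n: ref_end][::-1] != read[::-1][:n]
    hit = np.argmax(cmp) if cmp.any() else n
    return int(hit)


def align_reads(readset: ReadSet, reference: SyntheticReference,
                k: int = 31, max_mismatches: int = 6) -> AlignmentSet:
    """Exact-seed + extension alignment of paired reads to the reference.

    Reads are seeded with k-mers at several offsets on both strands; a seed
    hit is verified by full-length comparison. Reads that fail every linear
    placement are tested for a split alignment: a maximal exact prefix block
    and a maximal exact suffix block anchored by the terminal seeds. A split
    is reported when both blocks are at least 15 bases and their placements
    are discontiguous on the reference; the junction residue between the
    blocks (possibly empty) is recorded. Unalignable reads are flagged, not
    dropped.
    """
    ref = reference.codes
    rl = readset.read_len
    index = _KmerIndex(ref, k)
    pow4 = index.pow4
    n = readset.n_pairs

    reads = np.concatenate([readset.r1, readset.r2], axis=0)
    pair_ids = np.concatenate([np.arange(n), np.arange(n)])
    mates = np.concatenate([np.ones(n, np.int8), np.full(n, 2, np.int8)])
    N = len(reads)
    rc = (3 - reads)[:, ::-1]

    pos = np.full(N, -1, dtype=np.int64)
    strand = np.full(N, "+", dtype=object)
    mism = np.full(N, -1, dtype=np.int64)
    unresolved = np.ones(N, dtype=bool)

    offsets = [0, rl - k, (rl - k) // 2]

    def try_linear(mat, which_strand):
        for off in offsets:
            idx = np.where(unresolved)[0]
            if len(idx) == 0:
                return
            keys = _seed_keys(mat[idx], off, k, pow4)
            hit = index.lookup(keys)
            cand = hit - off
            ok = (hit >= 0) & (cand >= 0) & (cand + rl <= len(ref))
            sub = idx[ok]
            if len(sub) == 0:
                continue
            cpos = cand[ok]
            mm = (ref[cpos[:, None] + np.arange(rl)] != mat[sub]).sum(axis=1)
            good = mm <= max_mismatches
            accept = sub[good]
            pos[accept] = cpos[good]
            strand[accept] = which_strand
            mism[accept] = mm[good]
            unresolved[accept] = False

    try_linear(reads, "+")
    try_linear(rc, "-")

    # split / unaligned resolution, per read
    split = np.zeros(N, dtype=bool)
    b1s = np.full(N, -1, dtype=np.int64)
    b1e = np.full(N, -1, dtype=np.int64)
    b2s = np.full(N, -1, dtype=np.int64)
    b2e = np.full(N, -1, dtype=np.int64)
    gap_seq = np.full(N, "", dtype=object)
    min_block = 15

    # short fallback seeds let junction blocks between min_block and k bases
    # anchor; collisions are filtered by the extension and by junction voting
    k2 = min(17, k)
    index2 = _KmerIndex(ref, k2) if unresolved.any() and k2 < k else None

    for i in np.where(unresolved)[0]:
        best = None
        for mat, sname in ((reads, "+"), (rc, "-")):
            read = mat[i]
            p_hit = index.lookup(_seed_keys(read[None, :], 0, k, pow4))[0]
            s_hit = index.lookup(_seed_keys(read[None, :], rl - k, k, pow4))[0]
            if index2 is not None:
                if p_hit < 0:
                    p_hit = index2.lookup(
                        _seed_keys(read[None, :], 0, k2, index2.pow4))[0]
                if s_hit < 0:
                    h2 = index2.lookup(
                        _seed_keys(read[None, :], rl - k2, k2, index2.pow4))[0]
                    s_hit = h2 + k2 - k if h2 >= 0 else -1
            if p_hit < 0 or s_hit < 0:
                continue
            pre = _extend_forward(ref, read, p_hit)
            suf = _extend_backward(ref, read, s_hit + k)
            if pre < min_block or suf < min_block:
                continue
            suf_start_ref = s_hit + k - suf  # 0-based
            suf_start_read = rl - suf
            if suf_start_ref - suf_start_read == p_hit:
                continue  # actually contiguous; an error read, leave unaligned
            cand = (pre + suf, sname, p_hit, pre, suf_start_ref, suf_start_read, suf)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            continue
        _, sname, p_hit, pre, suf_start_ref, suf_start_read, suf = best
        read = reads[i] if sname == "+" else rc[i]
        split[i] = True
        strand[i] = sname
        pos[i] = p_hit
        b1s[i] = p_hit
        b1e[i] = p_hit + pre - 1
        b2s[i] = suf_start_ref
        b2e[i] = suf_start_ref + suf - 1
        if suf_start_read > pre:
            gap_seq[i] = decode(read[pre:suf_start_read])
        unresolved[i] = False

    aligned = pos >= 0

    # outer mate distance for linearly aligned pairs
    mate_distance = np.full(N, -1, dtype=np.int64)
    lin = aligned & ~split
    m1 = lin[:n] & lin[n:]
    left = np.minimum(pos[:n], pos[n:])
    right = np.maximum(pos[:n], pos[n:]) + rl
    md = right - left
    mate_distance[:n][m1] = md[m1]
    mate_distance[n:][m1] = md[m1]

    org = reference.origin
    table = pd.DataFrame({
        "pair": pair_ids,
        "mate": mates,
        "aligned": aligned,
        "split": split,
        "strand": strand,
        "pos": np.where(aligned, pos + org, -1),
        "mismatches": mism,
        "block1_start": np.where(b1s >= 0, b1s + org, -1),
        "block1_end": np.where(b1e >= 0, b1e + org, -1),
        "block2_start": np.where(b2s >= 0, b2s + org, -1),
        "block2_end": np.where(b2e >= 0, b2e + org, -1),
        "gap_seq": gap_seq,
        "mate_distance": mate_distance,
    })
    return AlignmentSet(table=table, reference=reference, read_len=rl)


# ---------------------------------------------------------------------------
# SV calling
# ---------------------------------------------------------------------------


@dataclass
class BreakpointCall:
    proximal_end: int  # last retained reference base (1-based)
    distal_start: int  # first retained reference base after the junction
    size: int  # reference bases absent from the carrier allele
    microhomology: int
    insertion: str
    n_split_reads: int
    n_discordant_pairs: int
    depth_ratio: float
    ambiguous: bool = False
    candidates: list = field(default_factory=list)


def _microhomology_from_reference(ref: np.ndarray, p0: int, d0: int,
                                  max_h: int = 50) -> int:
    """Longest h with ref[p0-h+1..p0] == ref[d0-h..d0-1] (0-based indices)."""
    h = 0
    while (h < max_h and p0 - h >= 0 and d0 - 1 - h >= 0
           and ref[p0 - h] == ref[d0 - 1 - h]):
        h += 1
    return h


def call_deletion_sv(
    alignments: AlignmentSet,
    reference: SyntheticReference,
    insert_mix: InsertMix | None = None,
    depth_window: int = 1000,
    min_split_support: int = 2,
) -> BreakpointCall | None:
    """Resolve a deletion from depth, discordant pairs and split reads.

    Split reads vote on a canonical junction ``(proximal_end, distal_start,
    insertion)``: the prefix block's maximal extension fixes the proximal
    side, any overlap between prefix and suffix blocks (the microhomology
    expressed in the read) is assigned to the proximal side, and unaligned
    junction residue becomes the untemplated insertion. Size is the number
    of reference bases absent from the carrier allele; microhomology is
    recomputed from the reference flanks at the voted junction, so it is
    reported once and never double-counted in the size. Returns ``None``
    when there is no discordant-pair or split-read support; more than two
    well-supported distinct junctions yield an ambiguous call listing all.
    """
    if insert_mix is None:
        insert_mix = InsertMix()
    t = alignments.table
    ref = reference.codes
    org = reference.origin
    rl = alignments.read_len

    # discordant pairs: outer distance beyond the widest library component
    disc_threshold = max(m + 4 * s for m, s in zip(insert_mix.means, insert_mix.sds))
    pairs = t[(t["mate"] == 1) & (t["mate_distance"] > 0)]
    disc = pairs[pairs["mate_distance"] > disc_threshold]
    n_disc = len(disc)

    # split-read junction voting
    sp = t[t["split"]]
    votes: dict = {}
    for _, row in sp.iterrows():
        a = int(row["block1_end"]) - org  # 0-based last prefix base
        b = int(row["block2_start"]) - org  # 0-based first suffix base
        gap = str(row["gap_seq"])
        # overlap between blocks in read coordinates = expressed homology
        pre_len = int(row["block1_end"]) - int(row["block1_start"]) + 1
        read_suf_start = rl - (int(row["block2_end"]) - int(row["block2_start"]) + 1)
        overlap = pre_len - read_suf_start if not gap else 0
        p0 = a
        d0 = b + max(overlap, 0)
        if d0 <= p0:
            continue
        key = (p0, d0, gap)
        votes[key] = votes.get(key, 0) + 1
    if not votes and n_disc == 0:
        return None

    call_p0 = call_d0 = None
    insertion = ""
    ambiguous = False
    candidates: list = []
    n_split = 0
    if votes:
        max_sup = max(votes.values())
        strong = {kk: v for kk, v in votes.items()
                  if v >= min(min_split_support, max_sup) and v >= max_sup / 4}
        candidates = [{"proximal_end": kk[0] + org, "distal_start": kk[1] + org,
                       "insertion": kk[2], "support": v}
                      for kk, v in sorted(strong.items(), key=lambda x: -x[1])]
        if len(strong) > 2:
            ambiguous = True
        best = max(strong.items(), key=lambda x: x[1])
        (call_p0, call_d0, insertion), n_split = best
    elif n_disc:
        # interval estimate only: innermost discordant footprint
        mates2 = t[(t["mate"] == 2) & (t["mate_distance"] > disc_threshold)]
        left = int(disc["pos"].max()) - org + rl - 1
        right = int(mates2["pos"].min()) - org if len(mates2) else left + 1
        call_p0, call_d0 = left, max(right, left + 2)
        insertion = ""

    size = call_d0 - call_p0 - 1
    h = _microhomology_from_reference(ref, call_p0, call_d0)

    # depth ratio inside the called interval vs the flanks
    lin = t[t["aligned"] & ~t["split"]]
    starts = lin["pos"].to_numpy() - org
    cover = np.zeros(len(ref) // depth_window + 1)
    np.add.at(cover, starts // depth_window, 1.0)
    inside = cover[(call_p0 // depth_window) + 1: call_d0 // depth_window]
    outside = np.concatenate([cover[1: call_p0 // depth_window - 1],
                              cover[call_d0 // depth_window + 2: -2]])
    depth_ratio = float(inside.mean() / outside.mean()) if len(inside) and outside.mean() > 0 else float("nan")

    return BreakpointCall(
        proximal_end=call_p0 + org,
        distal_start=call_d0 + org,
        size=int(size),
        microhomology=int(h),
        insertion=insertion,
        n_split_reads=int(n_split),
        n_discordant_pairs=int(n_disc),
        depth_ratio=depth_ratio,
        ambiguous=ambiguous,
        candidates=candidates,
    )
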