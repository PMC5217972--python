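"""Read-origin classification against the host and phage frames.

Reads are assigned one of six origin classes — ``phage``, ``host``,
``hybrid-left``, ``hybrid-right``, ``ambiguous``, ``unmapped`` — by exact
k-mer seeding against both reference frames followed by ungapped
verification on the seed diagonal.  A hybrid (attP/B junction) read anchors
with at least ``min_anchor`` matched bases in *both* frames outside the att
core; the core itself is identical in every frame and carries no
information, so anchors always exclude it.

The mapper is an idealisation for error-free or low-error reads; SAM input
from a production aligner can be substituted via :func:`alignments_from_sam`
with the junction logic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import AttSite, ReplicatedGenome, revcomp

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

CLASS_LABELS = ("phage", "host", "hybrid-left", "hybrid-right",
                "ambiguous", "unmapped")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward 2-bit k-mer codes and a validity mask (no ambiguous bases)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    valid_base = arr < 4
    a = np.where(valid_base, arr, 0).astype(np.uint64)
    codes = np.zeros(n, np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : j + n]
    ok = np.ones(n, bool)
    bad = np.nonzero(~valid_base)[0]
    for b in bad:
        ok[max(0, b - k + 1) : b + 1] = False
    return codes, ok


def _canonical(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical codes, forward-is-canonical flags, validity mask."""
    fwd, ok = _kmer_codes(arr, k)
    rc_arr = _COMP[np.clip(arr[::-1], 0, 3)]
    rc_arr = np.where(arr[::-1] < 4, rc_arr, 4).astype(np.uint8)
    rcodes, _ = _kmer_codes(rc_arr, k)
    # rc code of the k-mer starting at i is the rc-sequence k-mer at n-k-i
    rc = rcodes[::-1]
    canon = np.minimum(fwd, rc)
    fwd_is_canon = fwd <= rc
    return canon, fwd_is_canon, ok


@dataclass(slots=True)
class Alignment:
    """One ungapped placement of a read in a reference frame."""

    read_id: str
    frame: str
    ref_start: int
    ref_end: int
    strand: str
    matched_bases: int
    read_len: int
    matches_left_of_core: int
    matches_in_core: int
    matches_right_of_core: int
    read_match_start: int
    read_match_end: int
    left_tail_in_core: bool = False   # matches stop inside/at core, read continues left
    right_tail_in_core: bool = False

    @property
    def anchor(self) -> int:
        """Matched bases outside the att core (the informative signal)."""
        return self.matches_left_of_core + self.matches_right_of_core


@dataclass(slots=True)
class JunctionCall:
    """A hybrid attP/B read: anchors on both sides of the core."""

    read_id: str
    side: str  # attL | attR
    host_anchor: int
    phage_anchor: int
    junction_pos_host: int


class KmerIndex:
    """Sorted canonical k-mer index over the host and phage frames."""

    def __init__(self, references: dict[str, ReplicatedGenome], k: int = 31):
        if k < 11:
            raise ValueError("k < 11 gives too many spurious matches")
        self.k = k
        self.frames = dict(references)
        self.frame_names = list(references)
        codes_l, frames_l, pos_l, strand_l = [], [], [], []
        for fi, (name, g) in enumerate(references.items()):
            if k > g.length:
                raise ValueError(f"k exceeds length of frame {name!r}")
            seq = g.sequence + (g.sequence[: k - 1] if g.topology == "circular" else "")
            arr = _encode(seq)
            canon, fwd_can, ok = _canonical(arr, k)
            idx = np.nonzero(ok)[0]
            codes_l.append(canon[idx])
            frames_l.append(np.full(idx.size, fi, np.uint8))
            pos_l.append((idx % g.length).astype(np.uint32))
            strand_l.append(fwd_can[idx])
        codes = np.concatenate(codes_l)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.frame_id = np.concatenate(frames_l)[order]
        self.pos = np.concatenate(pos_l)[order]
        self.fwd_canon = np.concatenate(strand_l)[order]

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        left = np.searchsorted(self.codes, query_codes, side="left")
        right = np.searchsorted(self.codes, query_codes, side="right")
        return left, right


def build_kmer_index(references: dict[str, ReplicatedGenome], k: int = 31) -> KmerIndex:
    return KmerIndex(references, k)


_MAX_HITS_PER_KMER = 64
_MIN_RUN = 8  # matches in runs shorter than this are treated as chance


def _solid_runs(mask: np.ndarray, min_run: int = _MIN_RUN) -> np.ndarray:
    """Keep only matches lying in runs of at least ``min_run``.

    A random 25%-identity background produces runs this long with
    probability ~4**-min_run per position, so the filtered mask isolates
    the genuinely homologous part of an alignment.
    """
    if not mask.any():
        return mask
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], mask.astype(np.int8), [0]))))
    keep = np.zeros_like(mask)
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_run:
            keep[s:e] = True
    return keep


def _verify_candidate(read_id: str, seq: str, index: KmerIndex, fi: int,
                      minus: bool, diag: int,
                      min_matched: int | None) -> Alignment | None:
    """Project the whole read on the reference at one (frame, strand,
    diagonal) and count matching positions."""
    n = len(seq)
    k = index.k
    g = index.frames[index.frame_names[fi]]
    L = g.length
    ref_start = diag - (n - k) if minus else diag
    if g.topology == "linear":
        if ref_start < 0 or ref_start + n > L:
            return None
        ref_seq = g.sequence[ref_start : ref_start + n]
    else:
        ref_start %= L
        ref_seq = g.fetch(ref_start, n)
    cmp_read = revcomp(seq) if minus else seq
    m = np.frombuffer(ref_seq.encode(), np.uint8) == np.frombuffer(
        cmp_read.encode(), np.uint8)
    matched = int(m.sum())
    m = _solid_runs(m)
    solid = int(m.sum())
    if solid == 0 or (min_matched is not None and solid < min_matched):
        return None
    where = np.nonzero(m)[0]
    # matched read positions, read coordinates
    if minus:
        r0, r1 = n - 1 - int(where[-1]), n - int(where[0])
    else:
        r0, r1 = int(where[0]), int(where[-1]) + 1
    aln = Alignment(
        read_id=read_id,
        frame=index.frame_names[fi],
        ref_start=ref_start,
        ref_end=(ref_start + n - 1) % L + 1 if g.topology == "circular" else ref_start + n,
        strand="-" if minus else "+",
        matched_bases=matched,
        read_len=n,
        matches_left_of_core=0,
        matches_in_core=0,
        matches_right_of_core=0,
        read_match_start=r0,
        read_match_end=r1,
    )
    _annotate_core(aln, m, L, index, fi)
    return aln


def _alignments_from_seeds(read_id: str, seq: str, index: KmerIndex,
                           qoff: np.ndarray, hit: np.ndarray,
                           q_fwd_canon: np.ndarray,
                           min_matched: int | None) -> list[Alignment]:
    """Chain seed hits per (frame, strand, diagonal) and verify each chain."""
    frames = index.frame_id[hit]
    pos = index.pos[hit].astype(np.int64)
    same = index.fwd_canon[hit] == q_fwd_canon
    # '+' alignment: ref = diag + read_offset; '-': ref + read_offset = diag
    diag = np.where(same, pos - qoff, pos + qoff)
    strand_bit = (~same).astype(np.int64)
    key = (frames.astype(np.int64) << 40) | (strand_bit << 39) | (diag & ((1 << 39) - 1))
    uniq, cnt = np.unique(key, return_counts=True)
    alns: list[Alignment] = []
    for gi in np.argsort(-cnt):
        fi = int(uniq[gi] >> 40)
        minus = bool((uniq[gi] >> 39) & 1)
        d = int(np.int64(uniq[gi]) & ((1 << 39) - 1))
        # sign-extend the 39-bit diagonal
        if d >= 1 << 38:
            d -= 1 << 39
        a = _verify_candidate(read_id, seq, index, fi, minus, d, min_matched)
        if a is not None:
            alns.append(a)
    alns.sort(key=lambda a: -a.matched_bases)
    return _dedupe(alns)


def map_read(read_id: str, seq: str, index: KmerIndex,
             min_matched: int | None = None) -> list[Alignment]:
    """Seed, chain per (frame, strand, diagonal), verify ungapped.

    Returns alignments sorted by matched bases, best first; an empty list
    means unmapped.
    """
    k = index.k
    arr = _encode(seq)
    n = len(seq)
    if n < k:
        return []
    canon, fwd_can, ok = _canonical(arr, k)
    left, right = index.lookup(canon)
    counts = np.minimum(right - left, _MAX_HITS_PER_KMER) * ok
    total = int(counts.sum())
    if total == 0:
        return []
    qoff = np.repeat(np.arange(counts.size), counts)
    starts = np.repeat(left, counts)
    csum = np.concatenate(([0], np.cumsum(counts)))
    ranks = np.arange(total) - np.repeat(csum[:-1], counts)
    hit = starts + ranks
    return _alignments_from_seeds(read_id, seq, index, qoff, hit,
                                  fwd_can[qoff], min_matched)


def map_reads_batch(reads: list[tuple[str, str]], index: KmerIndex,
                    min_matched: int | None = None,
                    stride: int = 4) -> list[list[Alignment]]:
    """Vectorised variant of :func:`map_read` over many same-length reads.

    Seeding (k-mer encoding, canonicalisation, index lookup) runs as a
    handful of whole-batch numpy operations, querying every ``stride``-th
    k-mer; any anchor of at least ``stride + k - 1`` consecutive matching
    bases still produces a seed, so stride 4 is lossless down to 20-base
    anchors next to a 17-bp core with k=31.  Queries are sorted before the
    index lookup for memory locality.  Only chain verification (which uses
    every base of the read regardless of stride) is per-read.
    """
    k = index.k
    results: list[list[Alignment] | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for i, (_, s) in enumerate(reads):
        by_len.setdefault(len(s), []).append(i)
    # bound the working set: the seeding matrices are O(chunk x read_len)
    chunk = 200_000
    for n, all_idxs in by_len.items():
        for c0 in range(0, len(all_idxs), chunk):
            _map_chunk(reads, index, min_matched, stride, n,
                       all_idxs[c0:c0 + chunk], results)
    return results  # type: ignore[return-value]


def _map_chunk(reads, index, min_matched, stride, n, idxs, results) -> None:
    """Seed and verify one same-length chunk of reads (see map_reads_batch)."""
    k = index.k
    if n < k:
        for i in idxs:
            results[i] = []
        return
    if len(idxs) < 8:
        for i in idxs:
            results[i] = map_read(reads[i][0], reads[i][1], index, min_matched)
        return
    N = len(idxs)
    mat = np.empty((N, n), np.uint8)
    for row, i in enumerate(idxs):
        mat[row] = _ENC[np.frombuffer(reads[i][1].encode(), np.uint8)]
    nk = n - k + 1
    qpos = np.arange(0, nk, stride)
    if qpos[-1] != nk - 1:  # always seed the final k-mer too
        qpos = np.append(qpos, nk - 1)
    valid = mat < 4
    a = np.where(valid, mat, 0).astype(np.uint64)
    fwd = np.zeros((N, nk), np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a[:, j : j + nk]
    rc_mat = np.where(valid[:, ::-1], _COMP[np.clip(mat[:, ::-1], 0, 3)], 0
                      ).astype(np.uint64)
    rcc = np.zeros((N, nk), np.uint64)
    for j in range(k):
        rcc = (rcc << np.uint64(2)) | rc_mat[:, j : j + nk]
    rc = rcc[:, ::-1]
    canon = np.minimum(fwd, rc)[:, qpos]
    fwd_can = (fwd <= rc)[:, qpos]
    ok = np.ones((N, nk), bool)
    bad_r, bad_c = np.nonzero(~valid)
    for r, c in zip(bad_r, bad_c):
        ok[r, max(0, c - k + 1) : c + 1] = False
    ok = ok[:, qpos]
    nq = qpos.size
    flat = canon.ravel()
    order = np.argsort(flat, kind="stable")
    sl = np.searchsorted(index.codes, flat[order])
    sr = np.searchsorted(index.codes, flat[order], side="right")
    left = np.empty_like(sl)
    right = np.empty_like(sr)
    left[order] = sl
    right[order] = sr
    counts = (np.minimum(right - left, _MAX_HITS_PER_KMER)
              * ok.ravel()).astype(np.int64)
    total = int(counts.sum())
    if total:
        starts = np.repeat(left, counts)
        csum = np.concatenate(([0], np.cumsum(counts)))
        ranks = np.arange(total) - np.repeat(csum[:-1], counts)
        hit_all = starts + ranks
    per_read = counts.reshape(N, nq).sum(axis=1)
    offsets = np.concatenate(([0], np.cumsum(per_read)))
    qoff_all = np.repeat(np.tile(qpos, N), counts)
    fc_flat = fwd_can.ravel()
    qfc_all = np.repeat(fc_flat, counts)
    for row, i in enumerate(idxs):
        lo, hi = offsets[row], offsets[row + 1]
        if lo == hi:
            results[i] = []
            continue
        results[i] = _alignments_from_seeds(
            reads[i][0], reads[i][1], index,
            qoff_all[lo:hi], hit_all[lo:hi], qfc_all[lo:hi], min_matched)


def _dedupe(alns: list[Alignment]) -> list[Alignment]:
    seen = set()
    out = []
    for a in alns:
        key = (a.frame, a.strand, a.ref_start)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


def _annotate_core(aln: Alignment, match_mask: np.ndarray, L: int,
                   index: KmerIndex, frame_idx: int) -> None:
    core = getattr(index, "core_pos", None)
    if core is None:
        aln.matches_left_of_core = aln.matched_bases
        return
    cpos, clen = core[index.frame_names[frame_idx]]
    n = match_mask.size
    refpos = (aln.ref_start + np.arange(n)) % L
    rel = ((refpos - cpos + L // 2) % L) - L // 2
    in_core = (rel >= 0) & (rel < clen)
    left = rel < 0
    right = rel >= clen
    aln.matches_left_of_core = int(match_mask[left].sum())
    aln.matches_in_core = int(match_mask[in_core].sum())
    aln.matches_right_of_core = int(match_mask[right].sum())
    # does the matched region stop at/inside the core while the read goes on?
    where = np.nonzero(match_mask)[0]
    lo, hi = int(where[0]), int(where[-1])
    aln.left_tail_in_core = lo > 0 and bool(in_core[lo] or (rel[lo] >= 0 and rel[lo] < clen + 2))
    aln.right_tail_in_core = hi < n - 1 and bool(in_core[hi] or (0 <= rel[hi] < clen + 2))


_TAIL_TOL = 6  # unmatched end bases tolerated before a junction is suspected


def classify_read(alignments: list[Alignment], att: AttSite,
                  min_anchor: int = 20) -> tuple[str, Alignment | None, JunctionCall | None]:
    """Origin call for one read from its alignments.

    Returns ``(label, primary alignment, junction call or None)``.
    """
    if not alignments:
        return "unmapped", None, None
    best: dict[str, Alignment] = {}
    for a in alignments:
        if a.frame not in best or a.anchor > best[a.frame].anchor:
            best[a.frame] = a
    host = best.get("host")
    phage = best.get("phage")
    ho = host is not None and host.anchor >= min_anchor
    ph = phage is not None and phage.anchor >= min_anchor
    if ho and ph:
        # genuine junction reads overlap only within the core
        o0 = max(host.read_match_start, phage.read_match_start)
        o1 = min(host.read_match_end, phage.read_match_end)
        if o1 - o0 > att.core_len + 10:
            return "ambiguous", host if host.anchor >= phage.anchor else phage, None
        side = ("attL" if host.matches_left_of_core >= host.matches_right_of_core
                else "attR")
        label = "hybrid-left" if side == "attL" else "hybrid-right"
        jc = JunctionCall(
            read_id=host.read_id, side=side,
            host_anchor=host.anchor, phage_anchor=phage.anchor,
            junction_pos_host=att.attB_pos if side == "attL"
            else att.attB_pos + att.core_len,
        )
        return label, host, jc
    single = phage if ph else host if ho else None
    if single is not None:
        # a junction whose second anchor is sub-threshold is not a clean
        # single-frame read: matches stop at the core and the read goes on
        n = single.read_len
        left_tail = single.read_match_start
        right_tail = n - single.read_match_end
        suspicious = (
            (left_tail > _TAIL_TOL and (single.left_tail_in_core if single.strand == "+" else single.right_tail_in_core))
            or (right_tail > _TAIL_TOL and (single.right_tail_in_core if single.strand == "+" else single.left_tail_in_core))
        )
        if suspicious:
            return "ambiguous", single, None
        return ("phage" if single is phage else "host"), single, None
    return "ambiguous", alignments[0], None


def summarize_classes(labels) -> dict:
    """Counts per class plus percentages rounded to one decimal."""
    counts = {c: 0 for c in CLASS_LABELS}
    n = 0
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
        n += 1
    out = {"total": n, "counts": counts}
    if n == 0:
        out["fractions_pct"] = None
        out["flag"] = "empty input: fractions undefined"
    else:
        out["fractions_pct"] = {c: round(100.0 * v / n, 1) for c, v in counts.items()}
    return out


class ReadOriginClassifier(BaseEstimator):
    """Assigns sequencing reads a phage/host/hybrid origin.

    Parameters
    ----------
    k : int
        Seed k-mer size; 31-mers are effectively unique at the genome sizes
        modelled here.
    min_anchor : int
        Minimum matched bases outside the att core required for an anchor;
        the default 20 exceeds the 17-bp core so anchors are informative.
    min_matched : int or None
        Discard alignments with fewer matched bases (default: ``k``).

    After :meth:`fit`, the estimator exposes ``index_`` (the k-mer index),
    ``att_`` and ``frames_``.  :meth:`predict` returns per-read labels;
    :meth:`classify` returns the full per-read table.
    """

    def __init__(self, k: int = 31, min_anchor: int = 20,
                 min_matched: int | None = None):
        self.k = k
        self.min_anchor = min_anchor
        self.min_matched = min_matched

    def fit(self, references: dict[str, ReplicatedGenome], att: AttSite = None):
        """Build the k-mer index over ``{'host': ..., 'phage': ...}``."""
        if att is None:
            raise ValueError("an AttSite is required to locate the core")
        if set(references) != {"host", "phage"}:
            raise ValueError("references must be {'host': ..., 'phage': ...}")
        att.validate(references["host"], references["phage"])
        idx = KmerIndex(references, k=self.k)
        # the core occupies [attP, attP+c) in native phage coordinates for
        # either orientation (a reverse-strand occurrence spans the same interval)
        idx.core_pos = {
            "host": (att.attB_pos, att.core_len),
            "phage": (att.attP_pos, att.core_len),
        }
        self.index_ = idx
        self.att_ = att
        self.frames_ = dict(references)
        return self

    def map(self, read_id: str, seq: str) -> list[Alignment]:
        mm = self.min_matched if self.min_matched is not None else self.k
        return map_read(read_id, seq, self.index_, min_matched=mm)

    def classify(self, reads) -> pd.DataFrame:
        """Classify an iterable of ``(read_id, sequence)`` pairs.

        Returns a DataFrame with one row per read: read_id, label, frame,
        pos, strand, matched_bases, host_anchor, phage_anchor, side.
        """
        reads = list(reads)
        mm = self.min_matched if self.min_matched is not None else self.k
        all_alns = map_reads_batch(reads, self.index_, min_matched=mm)
        rows = []
        for (rid, seq), alns in zip(reads, all_alns):
            label, primary, jc = classify_read(alns, self.att_, self.min_anchor)
            host_a = max((a.anchor for a in alns if a.frame == "host"), default=0)
            phage_a = max((a.anchor for a in alns if a.frame == "phage"), default=0)
            rows.append((
                rid, label,
                primary.frame if primary else None,
                primary.ref_start if primary else -1,
                primary.ref_end if primary else -1,
                primary.strand if primary else None,
                primary.matched_bases if primary else 0,
                host_a, phage_a,
                jc.side if jc else None,
            ))
        return pd.DataFrame(rows, columns=[
            "read_id", "label", "frame", "pos", "pos_end", "strand",
            "matched_bases", "host_anchor", "phage_anchor", "side"])

    def predict(self, reads) -> np.ndarray:
        """Class labels only, in input order."""
        return self.classify(reads)["label"].to_numpy()


def alignments_from_sam(path: str, frame_of_ref: dict[str, str],
                        references: dict[str, ReplicatedGenome],
                        core_pos: dict[str, tuple[int, int]]) -> dict[str, list[Alignment]]:
    """Read pre-computed alignments (SAM, mandatory fields) per read.

    Aligned bases are taken as matches (M/=/X consumed, S clipped; other
    CIGAR operations are rejected).  This lets a production aligner replace
    the internal mapper on real data; junction logic downstream is
    unchanged.
    """
    import pysam

    out: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in frame_of_ref:
                continue
            for op, _ in rec.cigartuples or []:
                if op not in (0, 4, 7, 8):  # M, S, =, X
                    raise ValueError(
                        f"unsupported CIGAR operation {op} in read {rec.query_name}")
            frame = frame_of_ref[rec.reference_name]
            L = references[frame].length
            cpos, clen = core_pos[frame]
            n = rec.query_length or len(rec.query_sequence or "")
            matched = sum(e - s for s, e in rec.get_blocks())
            left = inc = right = 0
            for s, e in rec.get_blocks():
                rel0 = ((s - cpos + L // 2) % L) - L // 2
                for p in range(s, e):
                    rel = ((p - cpos + L // 2) % L) - L // 2
                    if rel < 0:
                        left += 1
                    elif rel < clen:
                        inc += 1
                    else:
                        right += 1
            qs = rec.query_alignment_start
            qe = rec.query_alignment_end
            aln = Alignment(
                read_id=rec.query_name, frame=frame,
                ref_start=rec.reference_start, ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                matched_bases=matched, read_len=n,
                matches_left_of_core=left, matches_in_core=inc,
                matches_right_of_core=right,
                read_match_start=qs, read_match_end=qe,
            )
            out.setdefault(rec.query_name, []).append(aln)
    return out
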