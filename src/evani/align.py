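"""Alignment-based ANI estimators.

Three families of estimator are implemented on top of shared primitives:

* **ANIb-style**: the query genome is cut into consecutive 1020-bp
  fragments; each fragment's best seed-and-extend local alignment against
  the whole reference is kept if it exceeds 30% identity over at least
  70% of the fragment length; ANI is the column-weighted identity over
  kept hits.
* **OrthoANI-style**: both genomes are fragmented and only reciprocal
  best fragment pairs contribute.
* **ANIm-style**: maximal exact matches (MEMs), optionally restricted to
  matches unique in both genomes (MUMs), anchor collinear chains; chains
  may be filtered to a 1-to-1 genome tiling; short gaps between anchors
  are closed by global alignment.  ANI is the identity over retained
  blocks, and the alignment fraction (AF, aligned bases / genome length)
  is reported per genome so that AF-weighted ANI and digital-DDH style
  distances can be derived.

The local aligner is a banded affine-gap Smith–Waterman (match +1,
mismatch -1, gap open -5, gap extend -2, x-drop 150) seeded by shared
11-mers; coordinates everywhere are 0-based half-open, with minus-strand
hits reported in plus coordinates plus a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit

from .errors import ConfigError, DataError
from .kmers import encode, packed_windows

__all__ = [
    "Fragment",
    "LocalHit",
    "AnchorMatch",
    "Chain",
    "ANIResult",
    "fragment_genome",
    "revcomp",
    "best_local_hit",
    "anib",
    "orthoani",
    "find_mems",
    "chain_and_filter",
    "anim",
    "af_weighted",
    "ddh_distances",
]

MIN_MEM_LEN = 8  # smaller seed tables blow up on genome-scale inputs
MAX_MEM_SEED = 32  # seeds are 2-bit packed into one 64-bit word


# ---------------------------------------------------------------------------
# fragments


@dataclass
class Fragment:
    parent_id: str
    offset: int
    sequence: str


def fragment_genome(
    genome: str, fragment_len: int = 1020, parent_id: str = ""
) -> list[Fragment]:
    """Cut a genome into consecutive fragments; the trailing short one is kept."""
    if fragment_len < 1:
        raise ConfigError(f"fragment_len must be >= 1, got {fragment_len}")
    return [
        Fragment(parent_id=parent_id, offset=off, sequence=genome[off : off + fragment_len])
        for off in range(0, len(genome), fragment_len)
    ]


# ---------------------------------------------------------------------------
# banded local alignment

_RC_TABLE = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_RC_TABLE)[::-1].decode("ascii")


@njit(cache=True)
def _banded_sw(q, t, diag, band, match, mismatch, gap_open, gap_ext, xdrop):
    """Banded affine local alignment of q against t around diagonal ``diag``.

    Cell (i, j) is inside the band iff |j - i - diag| <= band.  Gap of
    length L costs gap_open + L * gap_ext.  Returns
    (score, matches, aligned_cols, q_beg, q_end, t_beg, t_end).
    """
    m = q.shape[0]
    n = t.shape[0]
    W = 2 * band + 1
    NEG = np.int32(-(10**9) // 2)
    H = np.zeros((m + 1, W), dtype=np.int32)
    E = np.full((m + 1, W), NEG, dtype=np.int32)
    F = np.full((m + 1, W), NEG, dtype=np.int32)
    TB = np.zeros((m + 1, W), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    TE = np.zeros((m + 1, W), dtype=np.uint8)  # 1 = E extends
    TF = np.zeros((m + 1, W), dtype=np.uint8)  # 1 = F extends
    best = np.int32(0)
    bi = 0
    bb = 0
    for i in range(1, m + 1):
        row_best = np.int32(-1)
        for b in range(W):
            j = i + diag - band + b
            if j < 1 or j > n:
                H[i, b] = NEG if j != 0 else 0
                continue
            # E: gap consuming target (move along j), from (i, j-1) = (i, b-1)
            e = NEG
            if b - 1 >= 0 and H[i, b - 1] > NEG // 2:
                open_e = H[i, b - 1] - gap_open - gap_ext
                ext_e = E[i, b - 1] - gap_ext
                if ext_e > open_e:
                    e = ext_e
                    TE[i, b] = 1
                else:
                    e = open_e
                    TE[i, b] = 0
            E[i, b] = e
            # F: gap consuming query (move along i), from (i-1, j) = (i-1, b+1)
            f = NEG
            if b + 1 < W and H[i - 1, b + 1] > NEG // 2:
                open_f = H[i - 1, b + 1] - gap_open - gap_ext
                ext_f = F[i - 1, b + 1] - gap_ext
                if ext_f > open_f:
                    f = ext_f
                    TF[i, b] = 1
                else:
                    f = open_f
                    TF[i, b] = 0
            F[i, b] = f
            s = match if q[i - 1] == t[j - 1] else mismatch
            d = H[i - 1, b] + s if H[i - 1, b] > NEG // 2 else NEG
            h = np.int32(0)
            tb = np.uint8(0)
            if d > h:
                h = d
                tb = np.uint8(1)
            if e > h:
                h = e
                tb = np.uint8(2)
            if f > h:
                h = f
                tb = np.uint8(3)
            H[i, b] = h
            TB[i, b] = tb
            if h > best:
                best = h
                bi = i
                bb = b
            if h > row_best:
                row_best = h
        if row_best < best - xdrop:
            break
    # traceback
    matches = 0
    cols = 0
    i = bi
    b = bb
    q_end = bi
    t_end = bi + diag - band + bb
    while i > 0 and H[i, b] > 0 and TB[i, b] != 0:
        tb = TB[i, b]
        if tb == 1:
            j = i + diag - band + b
            if q[i - 1] == t[j - 1]:
                matches += 1
            cols += 1
            i -= 1
        elif tb == 2:
            # unwind a target-consuming gap run
            while True:
                cols += 1
                ext = TE[i, b]
                b -= 1
                if ext == 0:
                    break
        else:
            while True:
                cols += 1
                ext = TF[i, b]
                i -= 1
                b += 1
                if ext == 0:
                    break
    q_beg = i
    t_beg = i + diag - band + b
    return best, matches, cols, q_beg, q_end, t_beg, t_end


@dataclass
class LocalHit:
    """Best local alignment of one fragment against a target genome."""

    query_start: int  # fragment coordinates, 0-based half-open
    query_end: int
    target_start: int  # target plus-strand coordinates
    target_end: int
    strand: str
    matches: int
    aligned_cols: int
    score: float
    fragment_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0

    @property
    def coverage(self) -> float:
        return (self.query_end - self.query_start) / self.fragment_len


class _TargetIndex:
    """Forward k-mer position index of a target genome."""

    def __init__(self, sequence: str, k: int = 11):
        self.k = k
        self.length = len(sequence)
        self.codes = encode(sequence)
        fwd, _, ok = packed_windows(self.codes, k)
        pos = np.nonzero(ok)[0]
        vals = fwd[ok]
        order = np.argsort(vals, kind="stable")
        self.sorted_vals = vals[order]
        self.sorted_pos = pos[order]

    def seed_diagonals(self, frag_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(fragment_pos, target_pos) of all shared k-mer seeds."""
        fwd, _, ok = packed_windows(frag_codes, self.k)
        fpos = np.nonzero(ok)[0]
        fvals = fwd[ok]
        left = np.searchsorted(self.sorted_vals, fvals, "left")
        right = np.searchsorted(self.sorted_vals, fvals, "right")
        cnt = right - left
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        fp = np.repeat(fpos, cnt)
        grp = np.repeat(left, cnt) + (
            np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        )
        tp = self.sorted_pos[grp]
        return fp.astype(np.int64), tp.astype(np.int64)


def _best_hit_one_strand(
    frag_codes: np.ndarray,
    index: _TargetIndex,
    band: int,
    n_buckets: int,
) -> tuple | None:
    fp, tp = index.seed_diagonals(frag_codes)
    if fp.size == 0:
        return None
    diag = tp - fp
    bucket = diag // 32
    uniq, counts = np.unique(bucket, return_counts=True)
    order = np.argsort(counts)[::-1]
    best = None
    for bkt in uniq[order[:n_buckets]]:
        sel = (bucket >= bkt - 1) & (bucket <= bkt + 1)
        d0 = int(np.median(diag[sel]))
        t_off = max(0, d0 - band)
        t_end = min(index.length, d0 + frag_codes.size + band)
        res = _banded_sw(
            frag_codes,
            index.codes[t_off:t_end],
            d0 - t_off,
            band,
            np.int32(1),
            np.int32(-1),
            np.int32(5),
            np.int32(2),
            np.int32(150),
        )
        score, matches, cols, qb, qe, tb, te = res
        if cols == 0:
            continue
        if best is None or score > best[0]:
            best = (int(score), int(matches), int(cols), int(qb), int(qe),
                    int(tb) + t_off, int(te) + t_off)
    return best


def best_local_hit(
    fragment: Fragment | str,
    target: str | _TargetIndex,
    seed_k: int = 11,
    band: int = 75,
    n_buckets: int = 2,
) -> LocalHit | None:
    """Best-scoring banded local alignment of a fragment on either strand.

    Returns None when the fragment shares no ``seed_k``-mer with the
    target (absence of a hit is a value, not an error).
    """
    seq = fragment.sequence if isinstance(fragment, Fragment) else fragment
    index = target if isinstance(target, _TargetIndex) else _TargetIndex(target, seed_k)
    m = len(seq)
    hits = []
    fwd_codes = encode(seq)
    h = _best_hit_one_strand(fwd_codes, index, band, n_buckets)
    if h is not None:
        hits.append(("+", h))
    rc_codes = encode(revcomp(seq))
    h = _best_hit_one_strand(rc_codes, index, band, n_buckets)
    if h is not None:
        hits.append(("-", h))
    if not hits:
        return None
    strand, (score, matches, cols, qb, qe, tb, te) = max(hits, key=lambda x: x[1][0])
    if strand == "-":
        qb, qe = m - qe, m - qb
    return LocalHit(
        query_start=qb,
        query_end=qe,
        target_start=tb,
        target_end=te,
        strand=strand,
        matches=matches,
        aligned_cols=cols,
        score=float(score),
        fragment_len=m,
    )


# ---------------------------------------------------------------------------
# ANI results


@dataclass
class ANIResult:
    """Identity over aligned columns plus per-genome alignment fractions."""

    ani: float | None
    af_query: float
    af_ref: float
    aligned_bases: int
    n_units: int
    mode: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.ani is not None


def af_weighted(result: ANIResult) -> float:
    """ANI multiplied by the mean of the two per-genome alignment fractions."""
    if not result.defined:
        return 0.0
    return result.ani * 0.5 * (result.af_query + result.af_ref)


# ---------------------------------------------------------------------------
# ANIb / OrthoANI


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def anib(
    query: str,
    reference: str,
    fragment_len: int = 1020,
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
    seed_k: int = 11,
    per_fragment_mean: bool = False,
) -> ANIResult:
    """Fragment the query; keep best reference hits passing both filters.

    ANI is Sum(matches)/Sum(aligned columns) over kept hits (or, with
    ``per_fragment_mean``, the unweighted mean of per-fragment identity).
    """
    if not query or not reference:
        raise DataError("genomes must be non-empty")
    index = _TargetIndex(reference, seed_k)
    fragments = fragment_genome(query, fragment_len, parent_id="query")
    matches = cols = 0
    q_aligned = 0
    t_intervals: list[tuple[int, int]] = []
    identities = []
    kept = 0
    for frag in fragments:
        hit = best_local_hit(frag, index, seed_k=seed_k)
        if hit is None:
            continue
        if hit.identity > min_identity and hit.coverage > min_coverage:
            kept += 1
            matches += hit.matches
            cols += hit.aligned_cols
            q_aligned += hit.query_end - hit.query_start
            t_intervals.append((hit.target_start, hit.target_end))
            identities.append(hit.identity)
    if cols == 0:
        ani = None
    elif per_fragment_mean:
        ani = float(np.mean(identities))
    else:
        ani = matches / cols
    return ANIResult(
        ani=ani,
        af_query=q_aligned / len(query),
        af_ref=_interval_union(t_intervals) / len(reference),
        aligned_bases=cols,
        n_units=kept,
        mode={"method": "anib", "fragment_len": fragment_len},
    )


def _fragment_best_hits(
    fragments: list[Fragment], index: _TargetIndex, seed_k: int
) -> list[LocalHit | None]:
    return [best_local_hit(f, index, seed_k=seed_k) for f in fragments]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def orthoani(
    a: str,
    b: str,
    fragment_len: int = 1020,
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
    seed_k: int = 11,
) -> ANIResult:
    """Reciprocal-best-fragment ANI.

    Both genomes are fragmented; a pair (i, j) is reciprocal when
    fragment i's best hit lands in fragment j's window with >= 50%
    overlap and vice versa.  ANI is the mean identity of reciprocal
    pairs whose hits pass the ANIb filters.
    """
    if not a or not b:
        raise DataError("genomes must be non-empty")
    frags_a = fragment_genome(a, fragment_len, parent_id="a")
    frags_b = fragment_genome(b, fragment_len, parent_id="b")
    idx_a = _TargetIndex(a, seed_k)
    idx_b = _TargetIndex(b, seed_k)
    hits_ab = _fragment_best_hits(frags_a, idx_b, seed_k)
    hits_ba = _fragment_best_hits(frags_b, idx_a, seed_k)

    def window(frag: Fragment) -> tuple[int, int]:
        return frag.offset, frag.offset + len(frag.sequence)

    identities = []
    a_aligned = b_aligned = 0
    aligned_cols = 0
    for i, hit in enumerate(hits_ab):
        if hit is None:
            continue
        iv = (hit.target_start, hit.target_end)
        if iv[1] <= iv[0]:
            continue
        # fragment of b receiving the majority of this hit
        j = min(hit.target_start // fragment_len, len(frags_b) - 1)
        best_j, best_ov = None, 0
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < len(frags_b):
                ov = _overlap(iv, window(frags_b[cand]))
                if ov > best_ov:
                    best_j, best_ov = cand, ov
        if best_j is None or best_ov < 0.5 * (iv[1] - iv[0]):
            continue
        back = hits_ba[best_j]
        if back is None:
            continue
        biv = (back.target_start, back.target_end)
        if biv[1] <= biv[0]:
            continue
        if _overlap(biv, window(frags_a[i])) < 0.5 * (biv[1] - biv[0]):
            continue
        ok_i = hit.identity > min_identity and hit.coverage > min_coverage
        ok_j = back.identity > min_identity and back.coverage > min_coverage
        if ok_i and ok_j:
            identities.append(0.5 * (hit.identity + back.identity))
            a_aligned += hit.query_end - hit.query_start
            b_aligned += back.query_end - back.query_start
            aligned_cols += hit.aligned_cols + back.aligned_cols
    if not identities:
        return ANIResult(None, 0.0, 0.0, 0, 0, {"method": "orthoani"})
    return ANIResult(
        ani=float(np.mean(identities)),
        af_query=min(1.0, a_aligned / len(a)),
        af_ref=min(1.0, b_aligned / len(b)),
        aligned_bases=aligned_cols,
        n_units=len(identities),
        mode={"method": "orthoani", "fragment_len": fragment_len},
    )


# ---------------------------------------------------------------------------
# MEM / MUM finding


@dataclass
class AnchorMatch:
    """A maximal exact match; minus-strand matches carry plus coordinates."""

    pos_a: int
    pos_b: int
    length: int
    strand: str
    unique_a: bool = True
    unique_b: bool = True


class _OccIndex:
    """Occurrence counter for substrings of one sequence (forward strand)."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k
        fwd, _, ok = packed_windows(codes, k)
        self.fwd = fwd
        pos = np.nonzero(ok)[0]
        vals = fwd[pos]
        order = np.argsort(vals, kind="stable")
        self.pos = pos
        self.vals = vals
        self.sorted_vals = vals[order]
        self.sorted_pos = pos[order]

    def multiplicity(self, codes: np.ndarray) -> np.ndarray:
        """How many windows of the sequence carry each of the given codes."""
        lo = np.searchsorted(self.sorted_vals, codes, "left")
        hi = np.searchsorted(self.sorted_vals, codes, "right")
        return hi - lo

    def count(self, sub: np.ndarray, cap: int = 2) -> int:
        """Occurrences of ``sub`` (code array, len >= k), capped at ``cap``."""
        first = np.uint64(0)
        for c in sub[: self.k]:
            first = (first << np.uint64(2)) | np.uint64(c)
        lo = np.searchsorted(self.sorted_vals, first, "left")
        hi = np.searchsorted(self.sorted_vals, first, "right")
        n = 0
        for p in self.sorted_pos[lo:hi]:
            p = int(p)
            if p + sub.size <= self.codes.size and np.array_equal(
                self.codes[p : p + sub.size], sub
            ):
                n += 1
                if n >= cap:
                    return n
        return n


def _mems_vs_index(
    sva: np.ndarray,
    spa: np.ndarray,
    pb: np.ndarray,
    vb: np.ndarray,
    min_len: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal exact matches as (pos_a, pos_b, length).

    A maximal run of diagonal-consecutive shared seeds *is* a maximal
    exact match: a seed one position further in either direction would
    exist whenever the flanking characters still matched.
    """
    if sva.size == 0 or vb.size == 0:
        e = np.empty(0, np.int64)
        return e, e, e
    left = np.searchsorted(sva, vb, "left")
    right = np.searchsorted(sva, vb, "right")
    cnt = right - left
    total = int(cnt.sum())
    if total == 0:
        e = np.empty(0, np.int64)
        return e, e, e
    jj = np.repeat(pb, cnt).astype(np.int64)
    grp = np.repeat(left, cnt) + (
        np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    )
    ii = spa[grp].astype(np.int64)
    diag = jj - ii
    order2 = np.lexsort((ii, diag))
    d = diag[order2]
    i = ii[order2]
    j = jj[order2]
    newrun = np.empty(i.size, dtype=bool)
    newrun[0] = True
    newrun[1:] = (np.diff(d) != 0) | (np.diff(i) != 1)
    starts = np.nonzero(newrun)[0]
    ends = np.append(starts[1:], i.size) - 1
    pos_a = i[starts]
    pos_b = j[starts]
    length = i[ends] - i[starts] + min_len
    return pos_a, pos_b, length


def find_mems(
    a: str, b: str, min_len: int = 20, unique_mode: bool = True
) -> list[AnchorMatch]:
    """All maximal exact matches of length >= min_len on both strands.

    A match and its flanks: extending one base on either side (where the
    sequence allows) breaks equality.  With ``unique_mode`` only matches
    whose matched substring occurs exactly once in the forward strand of
    each genome are kept (MUMs).
    """
    if min_len < MIN_MEM_LEN:
        raise ConfigError(f"min_len must be >= {MIN_MEM_LEN}, got {min_len}")
    if min_len > MAX_MEM_SEED:
        raise ConfigError(f"min_len must be <= {MAX_MEM_SEED}, got {min_len}")
    ca = encode(a)
    cb = encode(b)
    occ_a = _OccIndex(ca, min_len)
    occ_b = _OccIndex(cb, min_len)
    anchors: list[AnchorMatch] = []
    len_b = len(b)
    for strand in ("+", "-"):
        if strand == "+":
            pbx, vbx = occ_b.pos, occ_b.vals
        else:
            cb_rc = (np.uint8(3) - cb[::-1]) % np.uint8(4)
            cb_rc[cb[::-1] > 3] = 255
            fbr, _, okr = packed_windows(cb_rc, min_len)
            pbx = np.nonzero(okr)[0]
            vbx = fbr[pbx]
        pos_a, pos_bx, length = _mems_vs_index(
            occ_a.sorted_vals, occ_a.sorted_pos, pbx, vbx, min_len
        )
        if pos_a.size == 0:
            continue
        pb_plus = pos_bx if strand == "+" else len_b - (pos_bx + length)
        # fast path: a substring whose leading seed occurs once is unique
        mult_a = occ_a.multiplicity(occ_a.fwd[pos_a])
        mult_b = occ_b.multiplicity(occ_b.fwd[pb_plus])
        for x, y, ln, ma, mb in zip(
            pos_a.tolist(), pb_plus.tolist(), length.tolist(),
            mult_a.tolist(), mult_b.tolist(),
        ):
            ua = ma == 1 or occ_a.count(ca[x : x + ln]) == 1
            ub = mb == 1 or occ_b.count(cb[y : y + ln]) == 1
            if unique_mode and not (ua and ub):
                continue
            anchors.append(
                AnchorMatch(pos_a=x, pos_b=y, length=ln, strand=strand,
                            unique_a=ua, unique_b=ub)
            )
    return anchors


# ---------------------------------------------------------------------------
# chaining, 1-to-1 filtering, gap closing


@dataclass
class Chain:
    """A collinear chain of anchors with its alignment statistics."""

    anchors: list[AnchorMatch]
    strand: str
    a_start: int
    a_end: int
    b_start: int  # plus coordinates of b
    b_end: int
    anchor_bases: int
    matches: int = 0
    aligned_cols: int = 0
    a_aligned: int = 0
    b_aligned: int = 0


@njit(cache=True)
def _chain_dp(a, b, ln, max_gap):
    """Heaviest collinear chain (total anchor bases); returns predecessor arcs."""
    n = a.shape[0]
    dp = ln.astype(np.int64).copy()
    pred = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        for j in range(i):
            if a[j] + ln[j] <= a[i] and b[j] + ln[j] <= b[i]:
                ga = a[i] - (a[j] + ln[j])
                gb = b[i] - (b[j] + ln[j])
                if ga <= max_gap and gb <= max_gap:
                    cand = dp[j] + ln[i]
                    if cand > dp[i]:
                        dp[i] = cand
                        pred[i] = j
    return dp, pred


def _edlib_stats(qa: str, qb: str) -> tuple[int, int]:
    """(matches, aligned_cols) of a unit-cost global alignment."""
    res = edlib.align(qa, qb, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def chain_and_filter(
    anchors: list[AnchorMatch],
    mode: str = "one_to_one",
    a: str | None = None,
    b: str | None = None,
    len_a: int | None = None,
    len_b: int | None = None,
    max_chain_gap: int = 5000,
    max_gap_align: int = 1000,
    min_chain_length: int = 1,
) -> list[Chain]:
    """Chain anchors into collinear blocks and optionally filter to 1-to-1.

    Chains are extracted greedily by descending total anchor length using
    a longest-increasing-subsequence style DP per strand (anchors in a
    chain are non-overlapping and within ``max_chain_gap`` of their
    neighbours).  In ``one_to_one`` mode chains are kept only while they
    cover mostly-new territory (>=50% novel) in both genomes.  When the
    sequences are provided, inter-anchor gaps shorter than
    ``max_gap_align`` are closed by global alignment and chain statistics
    (matches, aligned columns, aligned bases) are filled in; larger gaps
    stay unaligned.
    """
    if mode not in ("one_to_one", "all"):
        raise ConfigError(f"unknown chain filter mode: {mode!r}")
    if len_a is None and a is not None:
        len_a = len(a)
    if len_b is None and b is not None:
        len_b = len(b)
    chains: list[Chain] = []
    for strand in ("+", "-"):
        sub = [x for x in anchors if x.strand == strand]
        if not sub:
            continue
        if strand == "-" and len_b is None:
            raise ConfigError("minus-strand anchors require b or len_b")
        pa = np.array([x.pos_a for x in sub], dtype=np.int64)
        ln = np.array([x.length for x in sub], dtype=np.int64)
        if strand == "+":
            pb = np.array([x.pos_b for x in sub], dtype=np.int64)
        else:  # coordinates along the reverse complement of b
            pb = np.array([len_b - (x.pos_b + x.length) for x in sub], dtype=np.int64)
        order = np.lexsort((pb, pa))
        pa, pb, ln = pa[order], pb[order], ln[order]
        sub = [sub[i] for i in order]
        alive = np.ones(pa.size, dtype=bool)
        while alive.any():
            idx = np.nonzero(alive)[0]
            dp, pred = _chain_dp(pa[idx], pb[idx], ln[idx], max_chain_gap)
            best = int(np.argmax(dp))
            if dp[best] < min_chain_length:
                break
            members = []
            cur = best
            while cur != -1:
                members.append(idx[cur])
                cur = int(pred[cur])
            members.reverse()
            alive[members] = False
            mem_anchors = [sub[i] for i in members]
            chains.append(
                Chain(
                    anchors=mem_anchors,
                    strand=strand,
                    a_start=int(pa[members[0]]),
                    a_end=int(pa[members[-1]] + ln[members[-1]]),
                    b_start=int(min(x.pos_b for x in mem_anchors)),
                    b_end=int(max(x.pos_b + x.length for x in mem_anchors)),
                    anchor_bases=int(ln[members].sum()),
                )
            )
    chains.sort(key=lambda c: c.anchor_bases, reverse=True)
    if mode == "one_to_one" and chains:
        if len_a is None or len_b is None:
            raise ConfigError("one_to_one filtering requires sequences or lengths")
        cov_a = np.zeros(len_a, dtype=bool)
        cov_b = np.zeros(len_b, dtype=bool)

        def b_rc_start(ch: Chain) -> int:
            return ch.b_start if ch.strand == "+" else len_b - ch.b_end

        def crosses(c1: Chain, c2: Chain) -> bool:
            # order inconsistency between same-strand chains
            if c1.strand != c2.strand:
                return False
            return (c1.a_start < c2.a_start) != (b_rc_start(c1) < b_rc_start(c2))

        kept: list[Chain] = []
        for ch in chains:
            span_a = ch.a_end - ch.a_start
            span_b = ch.b_end - ch.b_start
            ov_a = int(cov_a[ch.a_start : ch.a_end].sum())
            ov_b = int(cov_b[ch.b_start : ch.b_end].sum())
            if ov_a > 0.5 * span_a or ov_b > 0.5 * span_b:
                continue
            if any(crosses(ch, other) for other in kept):
                continue
            kept.append(ch)
            cov_a[ch.a_start : ch.a_end] = True
            cov_b[ch.b_start : ch.b_end] = True
        chains = kept
    if a is not None and b is not None:
        b_rc = revcomp(b)
        for ch in chains:
            _fill_chain_stats(ch, a, b, b_rc, max_gap_align)
    return chains


def _fill_chain_stats(
    ch: Chain, a: str, b: str, b_rc: str, max_gap_align: int
) -> None:
    len_b = len(b)

    def b_prime(anchor: AnchorMatch) -> int:
        if anchor.strand == "+":
            return anchor.pos_b
        return len_b - (anchor.pos_b + anchor.length)

    matches = cols = a_al = b_al = 0
    prev = None
    for anchor in ch.anchors:
        matches += anchor.length
        cols += anchor.length
        a_al += anchor.length
        b_al += anchor.length
        if prev is not None:
            ga0, ga1 = prev.pos_a + prev.length, anchor.pos_a
            gb0, gb1 = b_prime(prev) + prev.length, b_prime(anchor)
            ga = ga1 - ga0
            gb = gb1 - gb0
            if ga == 0 and gb == 0:
                pass
            elif max(ga, gb) >= max_gap_align:
                pass  # left unaligned; counts only in AF denominators
            elif ga == 0 or gb == 0:
                cols += max(ga, gb)
                a_al += ga
                b_al += gb
            else:
                seg_a = a[ga0:ga1]
                if ch.strand == "+":
                    seg_b = b[gb0:gb1]
                else:
                    seg_b = b_rc[gb0:gb1]
                m, c = _edlib_stats(seg_a, seg_b)
                matches += m
                cols += c
                a_al += ga
                b_al += gb
        prev = anchor
    ch.matches = matches
    ch.aligned_cols = cols
    ch.a_aligned = a_al
    ch.b_aligned = b_al


# ---------------------------------------------------------------------------
# ANIm and digital-DDH distances


def anim(
    a: str,
    b: str,
    min_len: int = 20,
    anchor_mode: str = "mum",
    filter_1to1: bool = True,
    max_gap_align: int = 1000,
    min_chain_length: int = 65,
) -> ANIResult:
    """MEM/MUM-anchored whole-genome ANI with per-genome alignment fractions.

    When no anchor of length >= min_len survives, the result is the
    undefined flag (downstream serialization reports it as ANI 0).
    """
    if anchor_mode not in ("mum", "maxmatch"):
        raise ConfigError(f"unknown anchor mode: {anchor_mode!r}")
    if not a or not b:
        raise DataError("genomes must be non-empty")
    anchors = find_mems(a, b, min_len=min_len, unique_mode=(anchor_mode == "mum"))
    chains = chain_and_filter(
        anchors,
        mode="one_to_one" if filter_1to1 else "all",
        a=a,
        b=b,
        max_gap_align=max_gap_align,
        min_chain_length=min_chain_length,
    )
    matches = sum(c.matches for c in chains)
    cols = sum(c.aligned_cols for c in chains)
    a_al = sum(c.a_aligned for c in chains)
    b_al = sum(c.b_aligned for c in chains)
    return ANIResult(
        ani=(matches / cols) if cols else None,
        af_query=min(1.0, a_al / len(a)),
        af_ref=min(1.0, b_al / len(b)),
        aligned_bases=cols,
        n_units=sum(len(c.anchors) for c in chains),
        mode={
            "method": "anim",
            "min_len": min_len,
            "anchor_mode": anchor_mode,
            "filter_1to1": filter_1to1,
        },
    )


def ddh_distances(
    blocks_ab: list[Chain],
    blocks_ba: list[Chain],
    len_a: int,
    len_b: int,
) -> tuple[float, float | None, float]:
    """The three digital-DDH style distance formulas.

    d1 = 1 - (total alignment length, both directions) / (len_a + len_b);
    d2 = 1 - identical bases / total alignment length (None if nothing
    aligned); d3 = 1 - identical bases / (len_a + len_b).
    """
    aln = sum(c.aligned_cols for c in blocks_ab) + sum(
        c.aligned_cols for c in blocks_ba
    )
    ident = sum(c.matches for c in blocks_ab) + sum(c.matches for c in blocks_ba)
    total_len = len_a + len_b
    d1 = 1.0 - aln / total_len
    d2 = None if aln == 0 else 1.0 - ident / aln
    d3 = 1.0 - ident / total_len
    return d1, d2, d3
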