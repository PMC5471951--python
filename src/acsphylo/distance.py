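"""k-mismatch average common substring (ACS_k) distances.

For sequences X and Y and a mismatch budget k, let ``lambda_k(i)`` be the
length of the longest prefix of the suffix ``X_i`` that occurs somewhere in
Y within Hamming distance k.  The ACS_k similarity is the average of these
lengths over all start positions of X, and the evolutionary distance is the
usual ACS normalization

    Dist_k(X, Y) = 1/2 * (ln|Y| / ACS_k(X,Y) + ln|X| / ACS_k(Y,X))
                   - (ln|X| / |X| + ln|Y| / |Y|)

(natural logarithm; symmetric in X and Y; zero similarity maps to the
infinity flag).

Computing the true ``lambda_k`` for every i costs O(|X||Y|k), so this module
offers three estimators of the per-position match-length profile:

``exact``
    The quadratic brute force (the ground-truth oracle, intended for small
    inputs and for validating the heuristics).
``exact_seed``
    The kmacs-style heuristic: seed each position with ``alpha_i``, the
    Y-suffix maximizing the *exact* (0-mismatch) LCP, then extend through k
    mismatches from that seed.
``greedy_1mm``
    The greedy 1-mismatch heuristic: seed with ``beta_i``, the Y-suffix
    maximizing the *1-mismatch* LCP — computed exactly by processing every
    internal node of the virtual suffix tree — then extend through k
    mismatches.  At k = 1 the seed is provably optimal, so the profile
    equals the brute-force one.

At k = 0 all three estimators coincide with the classic ACS statistic.

The ``beta`` pass is the computational heart of the package.  For every
lcp-interval (virtual suffix-tree node) at string depth h, member suffixes
agree on their first h symbols and can only differ at symbol h + 1; mapping
each member to the lexicographic rank of its suffix h + 1 symbols further
along and sorting by that key brings together the members whose extensions
after a forgiven mismatch at h + 1 agree longest.  Each X-member is paired
with its nearest Y-neighbours on either side of the sorted order, and the
best 1-mismatch LCP seen over all nodes is recorded per position.  The
implementation below flattens the per-node work into a handful of
vectorized numpy passes (segment-tagged sort, segment-local neighbour
search, batched RMQ evaluation of the candidate 1-mismatch LCPs).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .index import GeneralizedIndex, SequenceRecord, build_index

__all__ = [
    "MatchLengthProfile",
    "CandidateArray",
    "DistanceMatrix",
    "INFINITE_DISTANCE",
    "exact_lambda_profile",
    "alpha_assignment",
    "beta_assignment",
    "lambda_profile",
    "acs_k",
    "dist_k",
    "pairwise_matrix",
    "pairwise_matrices",
]

logger = logging.getLogger("acsphylo")

#: Flag value returned by :func:`dist_k` when a similarity is zero.
INFINITE_DISTANCE = math.inf

#: Public estimator tags accepted by the matrix builders.
METHODS = ("exact", "acs", "exact_seed", "greedy")


@dataclass(frozen=True)
class MatchLengthProfile:
    """Per-position match lengths for the directed pair X -> Y.

    ``lambdas[i]`` (0-based over X positions) is the estimated k-mismatch
    match length of suffix ``X_{i+1}``; ``partners[i]`` is the 1-based start
    offset of the matched Y-suffix, 0 when no partner applies.
    """

    direction: Tuple[int, int]
    method: str  # exact | exact_seed | greedy_1mm
    k: int
    lambdas: np.ndarray
    partners: np.ndarray


@dataclass(frozen=True)
class CandidateArray:
    """Best seed per X position: offsets ``a`` and seed values ``value``.

    For the greedy pass ``value[i]`` is the best 1-mismatch LCP examined for
    position i + 1 and ``a[i]`` the smallest 1-based Y offset achieving it;
    for the exact-seed pass the value is the best exact LCP.  Offsets of 0
    mark the null (never-updated) state, which cannot survive processing
    because the root node supplies every position with a candidate.
    """

    direction: Tuple[int, int]
    method: str  # exact_seed | greedy_1mm
    a: np.ndarray
    value: np.ndarray


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Dist_k values over named taxa."""

    taxa: List[str]
    d: np.ndarray
    k: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        m = len(self.taxa)
        if len(set(self.taxa)) != m:
            raise InvalidInputError("duplicate taxon names in distance matrix")
        if self.d.shape != (m, m):
            raise InvalidInputError(
                f"matrix shape {self.d.shape} does not match {m} taxa"
            )
        if m and not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise InvalidInputError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.d[finite & finite.T], self.d.T[finite & finite.T], atol=1e-9
        ):
            raise InvalidInputError("distance matrix must be symmetric")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _codes(seq: SequenceRecord) -> np.ndarray:
    return np.fromiter(map(ord, seq.residues), dtype=np.int64, count=len(seq))


def _exact_lcp_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """L[i, j] = exact LCP of X_{i+1} and Y_{j+1}, shape (|X|+1, |Y|+1).

    Boundary row/column are zero (empty suffixes).  Filled bottom-up with
    one vectorized row per X position.
    """
    nx, ny = x.size, y.size
    table = np.zeros((nx + 1, ny + 1), dtype=np.int64)
    for i in range(nx - 1, -1, -1):
        table[i, :ny] = np.where(x[i] == y, table[i + 1, 1 : ny + 1] + 1, 0)
    return table


def _lcp_k_table(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """T[i, j] = k-mismatch LCP of X_{i+1}, Y_{j+1} for all pairs (brute force).

    Built by unrolling the mismatch recursion k times on top of the exact
    LCP table; a mismatch is only charged when neither suffix is exhausted.
    """
    nx, ny = x.size, y.size
    exact = _exact_lcp_table(x, y)
    level = exact
    ii = np.arange(nx + 1)[:, None]
    jj = np.arange(ny + 1)[None, :]
    for _ in range(k):
        z = exact
        alive = (ii + z < nx) & (jj + z < ny)
        gi = np.minimum(ii + z + 1, nx)
        gj = np.minimum(jj + z + 1, ny)
        level = z + np.where(alive, 1 + level[gi, gj], 0)
    return level


def exact_lambda_profile(x: SequenceRecord, y: SequenceRecord, k: int) -> MatchLengthProfile:
    """Ground-truth profile: lambda_k(i) by direct scan over every Y offset.

    Quadratic in the sequence lengths — this is the oracle the heuristics
    are judged against, not a production estimator.  Partners are the
    smallest maximizing offsets.
    """
    if k < 0:
        raise InvalidInputError("k must be non-negative")
    cx, cy = _codes(x), _codes(y)
    table = _lcp_k_table(cx, cy, k)[: len(x), : len(y)]
    lambdas = table.max(axis=1)
    partners = table.argmax(axis=1) + 1  # first occurrence == smallest offset
    return MatchLengthProfile((0, 1), "exact", k, lambdas, partners)


# ---------------------------------------------------------------------------
# Seed assignments
# ---------------------------------------------------------------------------

def _directed_positions(idx: GeneralizedIndex, seq: int) -> np.ndarray:
    start = idx._seq_start[seq]
    return start + np.arange(len(idx.seqs[seq]), dtype=np.int64)


def _check_direction(idx: GeneralizedIndex, dir_x: int, dir_y: int) -> None:
    if dir_x == dir_y:
        raise InvalidInputError("directed pair requires two distinct sequences")
    for s in (dir_x, dir_y):
        if not 0 <= s < idx.n_seqs:
            raise InvalidInputError(f"sequence index {s} not in index")


def alpha_assignment(idx: GeneralizedIndex, dir_x: int, dir_y: int) -> CandidateArray:
    """Exact-LCP seeds (the kmacs rule): alpha_i = argmax_j |LCP(X_i, Y_j)|.

    One sweep over the suffix array: the best Y-partner of any X-suffix is
    rank-adjacent among Y-suffixes, so it suffices to compare the nearest
    preceding and following Y-suffix in rank order (range-minimum LCP
    decides).  Ties go to the smaller Y offset.  O(n) after construction.
    """
    _check_direction(idx, dir_x, dir_y)
    s = idx.n_seqs
    sa, isa = idx.sa, idx.isa
    n_text = sa.size
    is_y = (idx._seq_id[sa] == dir_y) & (idx.text[sa] >= s)
    ranks = np.arange(n_text, dtype=np.int64)

    prev_y = np.maximum.accumulate(np.where(is_y, ranks, -1))
    next_rev = np.minimum.accumulate(np.where(is_y, ranks, 2 * n_text)[::-1])[::-1]

    xpos = _directed_positions(idx, dir_x)
    rx = isa[xpos]
    left = prev_y[rx]
    right = next_rev[rx]
    has_left = left >= 0
    has_right = right < n_text

    lcp_left = np.full(xpos.size, -1, dtype=np.int64)
    lcp_right = np.full(xpos.size, -1, dtype=np.int64)
    if has_left.any():
        lcp_left[has_left] = idx._rmq_min_batch(left[has_left] + 1, rx[has_left])
    if has_right.any():
        lcp_right[has_right] = idx._rmq_min_batch(rx[has_right] + 1, right[has_right])

    off_left = np.where(has_left, idx._local_off[sa[np.maximum(left, 0)]], 0)
    off_right = np.where(has_right, idx._local_off[sa[np.minimum(right, n_text - 1)]], 0)

    take_left = (lcp_left > lcp_right) | (
        (lcp_left == lcp_right) & has_left & (~has_right | (off_left <= off_right))
    )
    value = np.where(take_left, lcp_left, lcp_right)
    offset = np.where(take_left, off_left, off_right)
    # a zero-length best match is achieved by every offset: report the smallest
    offset = np.where(value > 0, offset, 1)
    return CandidateArray((dir_x, dir_y), "exact_seed", offset.astype(np.int64), value)


def _beta_candidates(
    idx: GeneralizedIndex, dir_x: int, dir_y: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Candidate (X offset, Y offset) pairs for both directions at once.

    Enumerates every lcp-interval, maps members to their depth-(h+1)
    extension rank keys, sorts within each interval (ties by origin then
    offset) and pairs every member with its nearest other-sequence
    neighbours.  Members whose extension runs past their sequence end keep
    a reserved minimal key (-1) so the sort stays total.  Returns global
    position arrays (x_for_xy, y_for_xy, y_for_yx, x_for_yx).
    """
    intervals = list(idx.enumerate_lcp_intervals())
    depth = np.fromiter((iv.depth for iv in intervals), dtype=np.int64, count=len(intervals))
    lo = np.fromiter((iv.lo for iv in intervals), dtype=np.int64, count=len(intervals))
    hi = np.fromiter((iv.hi for iv in intervals), dtype=np.int64, count=len(intervals))

    sizes = hi - lo + 1
    seg = np.repeat(np.arange(len(intervals), dtype=np.int64), sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    rank_arr = np.repeat(lo, sizes) + (np.arange(sizes.sum(), dtype=np.int64) - np.repeat(starts, sizes))

    pos = idx.sa[rank_arr]
    s = idx.n_seqs
    sid = idx._seq_id[pos]
    keep = ((sid == dir_x) | (sid == dir_y)) & (idx.text[pos] >= s)
    pos, seg, sid = pos[keep], seg[keep], sid[keep]

    h = depth[seg]
    ext = pos + h + 1
    sent = idx._sent_pos[sid]
    key = np.where(ext <= sent, idx.isa[np.minimum(ext, idx.size - 1)], -1)

    from_y = (sid == dir_y).astype(np.int64)
    order = np.lexsort((idx._local_off[pos], from_y, key, seg))
    pos_s, seg_s, from_y_s = pos[order], seg[order], from_y[order]

    m = pos_s.size
    arange = np.arange(m, dtype=np.int64)

    def nearest(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        prev = np.maximum.accumulate(np.where(mask, arange, -1))
        nxt = np.minimum.accumulate(np.where(mask, arange, 2 * m)[::-1])[::-1]
        prev_ok = (prev >= 0) & (seg_s[np.maximum(prev, 0)] == seg_s)
        nxt_ok = (nxt < m) & (seg_s[np.minimum(nxt, m - 1)] == seg_s)
        return np.where(prev_ok, prev, -1), np.where(nxt_ok, nxt, -1)

    prev_y, next_y = nearest(from_y_s == 1)
    prev_x, next_x = nearest(from_y_s == 0)

    def pairs(member_mask: np.ndarray, neigh: Tuple[np.ndarray, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
        members = np.flatnonzero(member_mask)
        mine: List[np.ndarray] = []
        theirs: List[np.ndarray] = []
        for side in neigh:
            partner = side[members]
            ok = partner >= 0
            mine.append(pos_s[members[ok]])
            theirs.append(pos_s[partner[ok]])
        return np.concatenate(mine), np.concatenate(theirs)

    x_xy, y_xy = pairs(from_y_s == 0, (prev_y, next_y))
    y_yx, x_yx = pairs(from_y_s == 1, (prev_x, next_x))
    return x_xy, y_xy, y_yx, x_yx


def _reduce_candidates(
    idx: GeneralizedIndex, mine: np.ndarray, theirs: np.ndarray, n_mine: int,
    direction: Tuple[int, int],
) -> CandidateArray:
    """Best 1-mismatch candidate per source position, smallest offset on ties."""
    values = idx._lcp_k_batch(mine, theirs, 1)
    i_loc = idx._local_off[mine] - 1  # 0-based
    j_loc = idx._local_off[theirs]
    order = np.lexsort((j_loc, -values, i_loc))
    first = np.unique(i_loc[order], return_index=True)[1]
    best = order[first]
    a = np.zeros(n_mine, dtype=np.int64)
    value = np.full(n_mine, -1, dtype=np.int64)
    a[i_loc[best]] = j_loc[best]
    value[i_loc[best]] = values[best]
    return CandidateArray(direction, "greedy_1mm", a, value)


def beta_assignment(idx: GeneralizedIndex, dir_x: int, dir_y: int) -> CandidateArray:
    """Greedy 1-mismatch seeds: beta_i = argmax_j |LCP_1(X_i, Y_j)|.

    Processes every internal node of the virtual suffix tree as described
    in the module docstring; the resulting value array equals the true
    1-mismatch maximum at every position (the node containing the lowest
    common ancestor of X_i and its optimal partner always supplies a
    candidate at least as good).
    """
    cand_xy, _ = beta_assignment_both(idx, dir_x, dir_y)
    return cand_xy


def beta_assignment_both(
    idx: GeneralizedIndex, dir_x: int, dir_y: int
) -> Tuple[CandidateArray, CandidateArray]:
    """Both directed greedy seed arrays from a single suffix-tree sweep."""
    _check_direction(idx, dir_x, dir_y)
    x_xy, y_xy, y_yx, x_yx = _beta_candidates(idx, dir_x, dir_y)
    cand_xy = _reduce_candidates(idx, x_xy, y_xy, len(idx.seqs[dir_x]), (dir_x, dir_y))
    cand_yx = _reduce_candidates(idx, y_yx, x_yx, len(idx.seqs[dir_y]), (dir_y, dir_x))
    return cand_xy, cand_yx


# ---------------------------------------------------------------------------
# Profiles and the distance
# ---------------------------------------------------------------------------

_PROFILE_METHOD = {"exact_seed": "exact_seed", "greedy_1mm": "greedy_1mm"}


def lambda_profile(idx: GeneralizedIndex, seed: CandidateArray, k: int) -> MatchLengthProfile:
    """Extend a seed assignment through k mismatches: lambda(i) = |LCP_k(X_i, Y_seed_i)|.

    At k = 0 every estimator is, by definition, the classic ACS statistic
    (the longest *exact* match per position), so a greedy 1-mismatch seed
    is replaced by the exact-LCP seed before extension; without this the
    budget-0 extension of a 1-mismatch-optimal partner would undershoot
    the classic values.
    """
    if k < 0:
        raise InvalidInputError("k must be non-negative")
    dir_x, dir_y = seed.direction
    _check_direction(idx, dir_x, dir_y)
    method = _PROFILE_METHOD[seed.method]
    if k == 0 and seed.method == "greedy_1mm":
        seed = alpha_assignment(idx, dir_x, dir_y)
        return MatchLengthProfile((dir_x, dir_y), method, 0, seed.value.copy(), seed.a.copy())
    n_x, n_y = len(idx.seqs[dir_x]), len(idx.seqs[dir_y])
    if seed.a.size != n_x or (seed.a.size and seed.a.max() > n_y):
        raise InvalidInputError("seed assignment does not match this index/direction")
    if seed.a.size and seed.a.min() < 1:
        raise InvalidInputError("seed assignment contains null partners")
    xpos = _directed_positions(idx, dir_x)
    ypos = idx._seq_start[dir_y] + seed.a - 1
    lambdas = idx._lcp_k_batch(xpos, ypos, k)
    return MatchLengthProfile((dir_x, dir_y), method, k, lambdas, seed.a.copy())


def acs_k(profile: MatchLengthProfile) -> float:
    """ACS_k similarity: mean of the per-position match lengths."""
    return float(profile.lambdas.mean())


def dist_k(acs_xy: float, acs_yx: float, len_x: int, len_y: int) -> float:
    """ACS-normalized evolutionary distance (natural logarithm).

    Symmetric under swapping the two directed similarities together with
    the lengths; a zero similarity yields the infinity flag.  Slightly
    negative values are possible (e.g. identical short sequences) and are
    reported as computed.
    """
    if len_x < 2 or len_y < 2:
        raise InvalidInputError("sequence lengths must be at least 2")
    if acs_xy < 0 or acs_yx < 0:
        raise InvalidInputError("ACS values must be non-negative")
    if acs_xy == 0 or acs_yx == 0:
        return INFINITE_DISTANCE
    return 0.5 * (math.log(len_y) / acs_xy + math.log(len_x) / acs_yx) - (
        math.log(len_x) / len_x + math.log(len_y) / len_y
    )


# ---------------------------------------------------------------------------
# All-pairs matrices
# ---------------------------------------------------------------------------

def _pair_distance(
    x: SequenceRecord, y: SequenceRecord, settings: Sequence[Tuple[str, int]]
) -> List[float]:
    """Dist_k of one pair for each (method, k) setting, sharing one index."""
    need_index = any(m != "exact" for m, _ in settings)
    idx = build_index([x, y]) if need_index else None
    alpha_xy = alpha_yx = beta_xy = beta_yx = None
    out = []
    for method, k in settings:
        if method == "exact":
            p_xy = exact_lambda_profile(x, y, k)
            p_yx = exact_lambda_profile(y, x, k)
        elif method in ("acs", "exact_seed"):
            if alpha_xy is None:
                alpha_xy = alpha_assignment(idx, 0, 1)
                alpha_yx = alpha_assignment(idx, 1, 0)
            kk = 0 if method == "acs" else k
            p_xy = lambda_profile(idx, alpha_xy, kk)
            p_yx = lambda_profile(idx, alpha_yx, kk)
        elif method == "greedy":
            if beta_xy is None:
                beta_xy, beta_yx = beta_assignment_both(idx, 0, 1)
            p_xy = lambda_profile(idx, beta_xy, k)
            p_yx = lambda_profile(idx, beta_yx, k)
        else:
            raise InvalidInputError(f"unknown method {method!r}; expected one of {METHODS}")
        a_xy, a_yx = acs_k(p_xy), acs_k(p_yx)
        logger.debug(
            "pair %s/%s method=%s k=%d ACS_k(X,Y)=%.4f ACS_k(Y,X)=%.4f",
            x.name, y.name, method, k, a_xy, a_yx,
        )
        out.append(dist_k(a_xy, a_yx, len(x), len(y)))
    return out


def pairwise_matrices(
    seqs: Sequence[SequenceRecord],
    settings: Sequence[Tuple[str, int]],
    clip_negative: bool = False,
) -> Dict[Tuple[str, int], DistanceMatrix]:
    """All-pairs Dist_k matrices for several (method, k) settings at once.

    Each unordered pair is indexed once and the index is reused across
    settings, which matters when sweeping k or comparing estimators.
    """
    names = [s.name for s in seqs]
    if len(seqs) < 2:
        raise InvalidInputError("need at least two sequences")
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate sequence names")
    for method, k in settings:
        if method not in METHODS:
            raise InvalidInputError(f"unknown method {method!r}; expected one of {METHODS}")
        if k < 0:
            raise InvalidInputError("k must be non-negative")
    m = len(seqs)
    mats = {key: np.zeros((m, m), dtype=float) for key in settings}
    for p, q in itertools.combinations(range(m), 2):
        values = _pair_distance(seqs[p], seqs[q], settings)
        for key, v in zip(settings, values):
            if clip_negative and v < 0:
                v = 0.0
            mats[key][p, q] = mats[key][q, p] = v
    return {
        (method, k): DistanceMatrix(list(names), mats[(method, k)], k=k, method=method)
        for method, k in settings
    }


def pairwise_matrix(
    seqs: Sequence[SequenceRecord],
    k: int = 1,
    method: str = "greedy",
    clip_negative: bool = False,
) -> DistanceMatrix:
    """Symmetric Dist_k matrix over named sequences (diagonal defined as 0)."""
    return pairwise_matrices(seqs, [(method, k)], clip_negative=clip_negative)[(method, k)]
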