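"""Generalized suffix-array index over a set of sequences.

The classic data structure behind average-common-substring statistics is the
generalized suffix tree (GST) of the input sequences.  As is standard
practice, this module simulates the GST with four flat arrays — the suffix
array (SA), its inverse (ISA), the LCP array (built with Kasai's algorithm)
and a sparse-table range-minimum structure over the LCP array — which
together answer every query the distance estimators need:

* ``lcp_length``       — exact longest-common-prefix length of two suffixes,
  in O(1) per query (an RMQ over the LCP array between the two ranks);
* ``lcp_k_length``     — LCP with up to ``k`` Hamming mismatches forgiven,
  in O(k) exact-LCP queries;
* ``enumerate_lcp_intervals`` — the lcp-intervals of the SA, i.e. the
  internal nodes of the virtual suffix tree, each as a (string depth,
  rank range) triple;
* ``suffix_key``       — the lexicographic rank of an arbitrary suffix,
  used as a sort key by the greedy 1-mismatch seeding pass.

Sequences are joined with one *distinct* sentinel per sequence, every
sentinel ordered below every residue, so that no common prefix can extend
across a sequence boundary.  Internally the text is held as an integer
array: sentinel ``s`` of the ``s``-th sequence gets code ``s`` and residue
``c`` gets code ``n_seqs + ord(c)``, which preserves lexicographic order of
the residues while keeping the sentinels mutually distinct and minimal.

Coordinates: all public query methods take *global* positions into the
joined text.  ``global_pos``/``origin`` convert between global positions and
(sequence index, 1-based local offset) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Sequence, Tuple

import numpy as np

from .errors import InvalidAlphabetError, InvalidInputError

__all__ = [
    "SequenceRecord",
    "GeneralizedIndex",
    "LcpInterval",
    "build_index",
    "lcp_length",
    "lcp_k_length",
    "enumerate_lcp_intervals",
    "suffix_key",
]

#: Smallest code point allowed for a residue symbol.  Everything below this
#: (control characters and the space) is reserved so that sentinel handling
#: can never collide with user data, whatever the alphabet (DNA, protein,
#: arbitrary printable symbols).
MIN_RESIDUE_ORD = 33


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a finite residue alphabet.

    Residues are uppercased on ingest.  Any printable symbol (code point
    >= ``MIN_RESIDUE_ORD``) is legal, so DNA, protein and ad-hoc alphabets
    are all supported; ``N`` matches only ``N``.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("sequence record must have a non-empty name")
        if not self.residues:
            raise InvalidInputError(f"sequence {self.name!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        for ch in set(self.residues):
            if ord(ch) < MIN_RESIDUE_ORD:
                raise InvalidAlphabetError(
                    f"sequence {self.name!r} contains reserved symbol {ch!r} "
                    f"(code points below {MIN_RESIDUE_ORD} are sentinel space)"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LcpInterval:
    """An lcp-interval: internal node of the virtual suffix tree.

    ``depth`` is the node's string depth; ``lo``..``hi`` (inclusive) are the
    suffix-array ranks of the leaves below it.  Every rank in ``(lo, hi]``
    has an LCP entry >= ``depth`` and the minimum over that range equals
    ``depth``.
    """

    depth: int
    lo: int
    hi: int

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1


def _build_suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array of an integer text by prefix doubling (numpy lexsorts).

    O(N log N) sorting rounds; entirely adequate for the desk-scale inputs
    this package targets (the per-pair texts are tens of kilobases).
    """
    n = text.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(text, return_inverse=True)[1].astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1:
            return order
        step <<= 1


def _kasai_lcp(text: np.ndarray, sa: np.ndarray, isa: np.ndarray) -> np.ndarray:
    """LCP array via Kasai's algorithm: lcp[r] = |LCP| of ranks r-1 and r."""
    n = text.size
    lcp = np.zeros(n, dtype=np.int64)
    # plain-int lists: the h-decrement scan is branchy, and python-level
    # list indexing beats numpy scalar indexing by a wide margin here
    t, sa_l, isa_l = text.tolist(), sa.tolist(), isa.tolist()
    out = lcp.tolist()
    h = 0
    for i in range(n):
        r = isa_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            out[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(out, dtype=np.int64)


def _sparse_table(values: np.ndarray) -> np.ndarray:
    """Sparse min-table: row j holds window minima of width 2**j."""
    n = values.size
    levels = max(1, int(n).bit_length())
    table = np.full((levels, n), np.iinfo(np.int64).max, dtype=np.int64)
    table[0] = values
    j = 1
    while (1 << j) <= n:
        half = 1 << (j - 1)
        width = n - (1 << j) + 1
        table[j, :width] = np.minimum(table[j - 1, :width], table[j - 1, half : half + width])
        j += 1
    return table


@dataclass
class GeneralizedIndex:
    """SA/ISA/LCP/RMQ bundle over the sentinel-joined text of all sequences.

    Attributes
    ----------
    seqs : list of SequenceRecord
        The indexed sequences, in input order.
    text : ndarray of int64
        Joined integer text (length ``n + n_seqs``): residue codes with one
        distinct sub-residue sentinel terminating each sequence.
    sa, isa, lcp : ndarray of int64
        Suffix array, inverse suffix array, LCP array.
    n : int
        Total residue count over all sequences (sentinels excluded).
    """

    seqs: List[SequenceRecord]
    text: np.ndarray
    sa: np.ndarray
    isa: np.ndarray
    lcp: np.ndarray
    n: int
    _rmq: np.ndarray = field(repr=False)
    _seq_id: np.ndarray = field(repr=False)    # global pos -> sequence index
    _local_off: np.ndarray = field(repr=False)  # global pos -> 1-based offset
    _seq_start: np.ndarray = field(repr=False)  # sequence index -> global start
    _sent_pos: np.ndarray = field(repr=False)   # sequence index -> sentinel position

    # -- construction ---------------------------------------------------

    @classmethod
    def build(cls, seqs: Sequence[SequenceRecord]) -> "GeneralizedIndex":
        if not seqs:
            raise InvalidInputError("cannot build an index over zero sequences")
        seqs = list(seqs)
        s = len(seqs)
        chunks, seq_id, local_off = [], [], []
        seq_start = np.empty(s, dtype=np.int64)
        sent_pos = np.empty(s, dtype=np.int64)
        cursor = 0
        for i, rec in enumerate(seqs):
            if not isinstance(rec, SequenceRecord):
                rec = SequenceRecord(getattr(rec, "name", f"seq{i}"), str(rec))
                seqs[i] = rec
            try:
                codes = np.frombuffer(rec.residues.encode("latin-1"), dtype=np.uint8).astype(np.int64) + s
            except UnicodeEncodeError:  # exotic wide symbols: slower generic path
                codes = np.fromiter(map(ord, rec.residues), dtype=np.int64, count=len(rec)) + s
            chunks.append(np.concatenate([codes, [i]]))  # sentinel code == i
            seq_start[i] = cursor
            sent_pos[i] = cursor + len(rec)
            seq_id.extend([i] * (len(rec) + 1))
            local_off.extend(range(1, len(rec) + 2))
            cursor += len(rec) + 1
        text = np.concatenate(chunks)
        sa = _build_suffix_array(text)
        isa = np.empty_like(sa)
        isa[sa] = np.arange(sa.size)
        lcp = _kasai_lcp(text, sa, isa)
        return cls(
            seqs=seqs,
            text=text,
            sa=sa,
            isa=isa,
            lcp=lcp,
            n=int(cursor - s),
            _rmq=_sparse_table(lcp),
            _seq_id=np.asarray(seq_id, dtype=np.int64),
            _local_off=np.asarray(local_off, dtype=np.int64),
            _seq_start=seq_start,
            _sent_pos=sent_pos,
        )

    # -- coordinates ----------------------------------------------------

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def size(self) -> int:
        """Length of the joined text (residues + sentinels)."""
        return int(self.text.size)

    def global_pos(self, seq: int, offset: int) -> int:
        """Global position of 1-based ``offset`` within sequence ``seq``."""
        if not 0 <= seq < self.n_seqs:
            raise InvalidInputError(f"sequence index {seq} out of range")
        if not 1 <= offset <= len(self.seqs[seq]) + 1:
            raise InvalidInputError(
                f"offset {offset} out of range for sequence {self.seqs[seq].name!r}"
            )
        return int(self._seq_start[seq] + offset - 1)

    def origin(self, pos: int) -> Tuple[int, int]:
        """Map a global text position to (sequence index, 1-based offset)."""
        self._check_pos(pos)
        return int(self._seq_id[pos]), int(self._local_off[pos])

    def _check_pos(self, pos: int, allow_sentinel: bool = True) -> None:
        if not 0 <= pos < self.text.size:
            raise InvalidInputError(f"position {pos} outside text of length {self.text.size}")
        if not allow_sentinel and self.text[pos] < self.n_seqs:
            raise InvalidInputError(f"position {pos} is a sentinel position")

    def _remaining(self, pos: int) -> int:
        """Residues from ``pos`` to the end of its sequence (inclusive)."""
        return int(self._sent_pos[self._seq_id[pos]] - pos)

    # -- queries ---------------------------------------------------------

    def _rmq_min(self, lo: int, hi: int) -> int:
        """Minimum of lcp[lo..hi] inclusive, O(1)."""
        span = hi - lo + 1
        j = span.bit_length() - 1
        return int(min(self._rmq[j, lo], self._rmq[j, hi - (1 << j) + 1]))

    def lcp_length(self, pos_a: int, pos_b: int) -> int:
        """Exact LCP length of the suffixes at two global positions.

        Never crosses a sentinel (sentinels are distinct symbols, so any
        pair of suffixes from different sequences mismatches there); a
        suffix compared against itself yields its remaining in-sequence
        length.
        """
        self._check_pos(pos_a, allow_sentinel=False)
        self._check_pos(pos_b, allow_sentinel=False)
        if pos_a == pos_b:
            return self._remaining(pos_a)
        ra, rb = int(self.isa[pos_a]), int(self.isa[pos_b])
        if ra > rb:
            ra, rb = rb, ra
        return self._rmq_min(ra + 1, rb)

    def lcp_k_length(self, pos_x: int, pos_y: int, k: int) -> int:
        """LCP length with up to ``k`` Hamming mismatches forgiven.

        Follows the standard recursion: with ``z`` the exact LCP, the
        answer is ``z`` when either suffix is exhausted at offset ``z``
        (a mismatch is never charged at or past a sequence end), else
        ``z + 1 + lcp_{k-1}`` of the suffixes advanced past the mismatch.
        Runs in at most ``k + 1`` exact-LCP queries.
        """
        if k < 0:
            raise InvalidInputError(f"k must be non-negative, got {k}")
        self._check_pos(pos_x, allow_sentinel=False)
        self._check_pos(pos_y, allow_sentinel=False)
        total = 0
        s = self.n_seqs
        while True:
            # after advancing past a mismatch a position may sit on its
            # sentinel (suffix exhausted, z = 0), so skip re-validation
            if self.text[pos_x] < s or self.text[pos_y] < s:
                z = 0
            else:
                z = self.lcp_length(pos_x, pos_y)
            total += z
            if k == 0:
                return total
            ax, ay = pos_x + z, pos_y + z
            if self.text[ax] < s or self.text[ay] < s:  # sentinel: suffix exhausted
                return total
            total += 1
            pos_x, pos_y, k = ax + 1, ay + 1, k - 1

    def suffix_key(self, pos: int) -> int:
        """Lexicographic rank of the suffix starting at a global position.

        Valid for residue positions and for the position one past a
        sequence's last residue (its sentinel): sentinel-led suffixes sort
        below every real suffix, giving the reserved minimal-rank
        convention for exhausted suffixes.
        """
        self._check_pos(pos)
        return int(self.isa[pos])

    def enumerate_lcp_intervals(self) -> Iterator[LcpInterval]:
        """Yield every internal node of the virtual suffix tree once.

        Classic stack sweep over the LCP array: at most ``N - 1`` intervals,
        each emitted as (string depth, inclusive rank range).  The root
        (depth 0, full range) is always included.
        """
        lcp = self.lcp.tolist()
        n = len(lcp)
        stack: List[List[int]] = [[0, 0]]  # [depth, left bound]
        for i in range(1, n):
            li = lcp[i]
            lb = i - 1
            while stack[-1][0] > li:
                depth, left = stack.pop()
                yield LcpInterval(depth, left, i - 1)
                lb = left
            if stack[-1][0] < li:
                stack.append([li, lb])
        while stack:
            depth, left = stack.pop()
            yield LcpInterval(depth, left, n - 1)

    # -- vectorized internals (used by the distance estimators) ----------

    def _rmq_min_batch(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo + 1
        j = np.frexp(span)[1] - 1  # floor(log2(span))
        left = self._rmq[j, lo]
        right = self._rmq[j, hi - (1 << j.astype(np.int64)) + 1]
        return np.minimum(left, right)

    def _lcp_batch(self, pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
        """Vectorized exact LCP for arrays of global residue positions."""
        pos_a = np.asarray(pos_a, dtype=np.int64)
        pos_b = np.asarray(pos_b, dtype=np.int64)
        out = np.empty(pos_a.size, dtype=np.int64)
        same = pos_a == pos_b
        if same.any():
            out[same] = self._sent_pos[self._seq_id[pos_a[same]]] - pos_a[same]
        diff = ~same
        if diff.any():
            ra = self.isa[pos_a[diff]]
            rb = self.isa[pos_b[diff]]
            lo = np.minimum(ra, rb) + 1
            hi = np.maximum(ra, rb)
            out[diff] = self._rmq_min_batch(lo, hi)
        return out

    def _lcp_k_batch(self, pos_x: np.ndarray, pos_y: np.ndarray, k: int) -> np.ndarray:
        """Vectorized ``lcp_k_length`` over parallel position arrays."""
        pos_x = np.asarray(pos_x, dtype=np.int64)
        pos_y = np.asarray(pos_y, dtype=np.int64)
        total = np.zeros(pos_x.size, dtype=np.int64)
        ids = np.arange(pos_x.size)
        a, b = pos_x.copy(), pos_y.copy()
        s = self.n_seqs
        for step in range(k + 1):
            if ids.size == 0:
                break
            z = self._lcp_batch(a, b)
            total[ids] += z
            if step == k:
                break
            a2, b2 = a + z, b + z
            alive = (self.text[a2] >= s) & (self.text[b2] >= s)
            ids = ids[alive]
            total[ids] += 1
            a = a2[alive] + 1
            b = b2[alive] + 1
        return total


# -- module-level operation surface --------------------------------------

def build_index(seqs: Sequence[SequenceRecord]) -> GeneralizedIndex:
    """Build the generalized suffix-array index over one or more sequences."""
    return GeneralizedIndex.build(seqs)


def lcp_length(idx: GeneralizedIndex, pos_a: int, pos_b: int) -> int:
    return idx.lcp_length(pos_a, pos_b)


def lcp_k_length(idx: GeneralizedIndex, pos_x: int, pos_y: int, k: int) -> int:
    return idx.lcp_k_length(pos_x, pos_y, k)


def enumerate_lcp_intervals(idx: GeneralizedIndex) -> Iterator[LcpInterval]:
    return idx.enumerate_lcp_intervals()


def suffix_key(idx: GeneralizedIndex, pos: int) -> int:
    return idx.suffix_key(pos)
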