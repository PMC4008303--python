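"""Design and decoding of error-correcting DNA sample barcodes.

Sample barcodes (indexes) are fixed-length words over {A,C,G,T}.  A set with
minimum pairwise Hamming distance ``d`` supports unambiguous correction of up
to ``floor((d-1)/2)`` substitution errors; with single-error correction a read
must accumulate at least ``d - 1`` substitutions in the index before it can be
counted as a different barcode.  This module designs such sets by greedy
accretion over a seeded random permutation of the full ``4^L`` candidate
space, decodes observed index reads with bounded-radius correction, and
computes exact misassignment probabilities under an iid substitution channel.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Barcode",
    "BarcodeSet",
    "DesignConstraints",
    "ChannelModel",
    "DecodeResult",
    "DesignExhaustedError",
    "SetReport",
    "PROFILES",
    "design_barcode_set",
    "validate_set",
    "decode_index",
    "decode_batch",
    "min_errors_to_misassign",
    "misassignment_probability",
    "count_misassigned_perturbations",
    "enumerate_perturbations",
    "write_barcode_set",
    "read_barcode_set",
]

_ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_ALPHABET)}
# Code 4 is reserved for any non-ACGT character (N etc.); it mismatches every
# base, so ambiguity is never converted into a confident call.
_NON_ACGT = 4

# Named design profiles: (length, min distance, set size).
PROFILES = {
    "96x8_d4": (8, 4, 96),
    "384x9_d4": (9, 4, 384),
    "384x11_d5": (11, 5, 384),
}


def encode_seq(seq: str) -> np.ndarray:
    """Map a DNA string to an array of base codes (A=0,C=1,G=2,T=3, other=4)."""
    return np.array([_BASE_TO_CODE.get(c, _NON_ACGT) for c in seq.upper()], dtype=np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    return "".join(_ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class Barcode:
    """A single barcode word with a 1-based integer id."""

    id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("barcode id must be a positive integer")
        if not self.sequence or any(c not in _ALPHABET for c in self.sequence):
            raise ValueError(f"barcode {self.id}: sequence must be non-empty ACGT-only")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BarcodeSet:
    """An ordered quaternary code with a declared minimum pairwise distance."""

    length: int
    declared_min_distance: int
    barcodes: list[Barcode]
    design_seed: int | None = None
    profile_name: str | None = None

    def __post_init__(self) -> None:
        for bc in self.barcodes:
            if bc.length != self.length:
                raise ValueError(
                    f"barcode {bc.id} has length {bc.length}, set declares {self.length}"
                )

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def sequences(self) -> list[str]:
        return [bc.sequence for bc in self.barcodes]

    @property
    def ids(self) -> list[int]:
        return [bc.id for bc in self.barcodes]

    def matrix(self) -> np.ndarray:
        """Codewords as an (n, L) uint8 array of base codes."""
        return np.vstack([encode_seq(bc.sequence) for bc in self.barcodes])

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        declared_min_distance: int = 1,
        design_seed: int | None = None,
        profile_name: str | None = None,
    ) -> "BarcodeSet":
        if not sequences:
            raise ValueError("cannot build a barcode set from zero sequences")
        L = len(sequences[0])
        barcodes = [Barcode(i + 1, s) for i, s in enumerate(sequences)]
        return cls(L, declared_min_distance, barcodes, design_seed, profile_name)


@dataclass(frozen=True)
class DesignConstraints:
    """Composition constraints applied to candidate words before the search.

    Defaults keep words synthesizable and sequencer-friendly; they are
    conventions of this package, configurable and fully removable with
    :meth:`none` for pure code-theoretic work.
    """

    gc_fraction_range: tuple[float, float] = (0.25, 0.75)
    max_homopolymer_run: int = 3
    forbidden_prefixes: tuple[str, ...] = ()
    forbidden_suffixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.gc_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"gc_fraction_range must be ordered within [0,1], got {lo}..{hi}")
        if self.max_homopolymer_run < 1:
            raise ValueError("max_homopolymer_run must be >= 1")

    @classmethod
    def none(cls) -> "DesignConstraints":
        """No composition filtering (every 4^L word is a candidate)."""
        return cls(gc_fraction_range=(0.0, 1.0), max_homopolymer_run=10**9)


@dataclass(frozen=True)
class ChannelModel:
    """Iid per-base substitution channel, uniform over the 3 alternative bases."""

    per_base_substitution_rate: float = 0.01

    def __post_init__(self) -> None:
        p = self.per_base_substitution_rate
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"substitution rate must lie in [0,1], got {p}")


#: decode outcome codes used by the vectorized batch decoder
STATUS_PERFECT = 0
STATUS_CORRECTED = 1
STATUS_UNASSIGNED = 2
STATUS_AMBIGUOUS = 3

_STATUS_NAMES = ("perfect", "corrected", "unassigned", "ambiguous")


@dataclass(frozen=True)
class DecodeResult:
    status: str  # perfect | corrected | unassigned | ambiguous
    barcode_id: int | None = None
    distance: int | None = None


class DesignExhaustedError(RuntimeError):
    """Raised when the candidate space is exhausted below the target count.

    Carries the partial set achieved so the caller can inspect or keep it.
    """

    def __init__(self, partial: BarcodeSet, target: int):
        self.partial = partial
        self.target = target
        super().__init__(
            f"candidate space exhausted: achieved {len(partial)} codewords "
            f"of the requested {target} at (L={partial.length}, "
            f"d={partial.declared_min_distance})"
        )


# ---------------------------------------------------------------------------
# candidate enumeration and constraint filtering


def _enumerate_words(L: int) -> np.ndarray:
    """All 4^L words as an (N, L) uint8 array, lexicographic in A<C<G<T."""
    n = 4**L
    idx = np.arange(n, dtype=np.int64)
    out = np.empty((n, L), dtype=np.uint8)
    for j in range(L):
        out[:, L - 1 - j] = (idx >> (2 * j)) & 3
    return out


def _constraint_mask(words: np.ndarray, constraints: DesignConstraints) -> np.ndarray:
    n, L = words.shape
    keep = np.ones(n, dtype=bool)
    lo, hi = constraints.gc_fraction_range
    if lo > 0.0 or hi < 1.0:
        gc = ((words == 1) | (words == 2)).sum(axis=1) / L
        keep &= (gc >= lo) & (gc <= hi)
    r = constraints.max_homopolymer_run
    if r < L:
        run = np.ones(n, dtype=np.int16)
        maxrun = np.ones(n, dtype=np.int16)
        for j in range(1, L):
            same = words[:, j] == words[:, j - 1]
            run = np.where(same, run + 1, 1)
            np.maximum(maxrun, run, out=maxrun)
        keep &= maxrun <= r
    for pre in constraints.forbidden_prefixes:
        enc = encode_seq(pre)
        keep &= ~np.all(words[:, : len(enc)] == enc, axis=1)
    for suf in constraints.forbidden_suffixes:
        enc = encode_seq(suf)
        keep &= ~np.all(words[:, L - len(enc) :] == enc, axis=1)
    return keep


def _one_hot(words: np.ndarray) -> np.ndarray:
    """(n, L) base codes -> (n, 4L) float32 one-hot; non-ACGT rows are all-zero."""
    n, L = words.shape
    out = np.zeros((n, 4 * L), dtype=np.float32)
    cols = np.arange(L) * 4
    for b in range(4):
        mask = words == b
        rows, pos = np.nonzero(mask)
        out[rows, cols[pos] + b] = 1.0
    return out


def _distances_to(words: np.ndarray, code_oh: np.ndarray, L: int) -> np.ndarray:
    """Hamming distances (n_words, n_codewords) via one-hot match counting."""
    matches = _one_hot(words) @ code_oh.T
    return (L - matches).astype(np.int32)


# ---------------------------------------------------------------------------
# design and validation


def design_barcode_set(
    L: int,
    d: int,
    target_count: int,
    constraints: DesignConstraints | None = None,
    seed: int = 1,
    profile_name: str | None = None,
    chunk_size: int = 1 << 16,
) -> BarcodeSet:
    """Design a barcode set of ``target_count`` length-``L`` words with
    minimum pairwise Hamming distance ``>= d``.

    The search is a greedy lexicode over a seeded random permutation of all
    ``4^L`` candidates that survive the composition constraints: candidates
    are considered in permuted order and accepted whenever they sit at
    distance ``>= d`` from every word accepted so far.  The search stops as
    soon as ``target_count`` words have been accepted, so the output is
    deterministic for a fixed ``(L, d, target_count, constraints, seed)``.

    Raises :class:`DesignExhaustedError` (carrying the partial set) if the
    candidate space runs out first, rather than silently truncating.
    """
    if not (1 <= d <= L):
        raise ValueError(f"need 1 <= d <= L, got d={d}, L={L}")
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if L > 12:
        raise ValueError(f"full enumeration limited to L <= 12 (4^{L} candidates)")
    if constraints is None:
        constraints = DesignConstraints()

    words = _enumerate_words(L)
    mask = _constraint_mask(words, constraints)
    if not mask.any():
        raise ValueError("constraints admit no candidate words (contradictory constraints)")
    candidates = words[mask]

    rng = np.random.default_rng(seed)
    candidates = candidates[rng.permutation(len(candidates))]

    accepted = np.empty((target_count, L), dtype=np.uint8)
    k = 0
    for start in range(0, len(candidates), chunk_size):
        chunk = candidates[start : start + chunk_size]
        k0 = k
        if k0 > 0:
            # vectorized prefilter against everything accepted before this chunk
            dist = _distances_to(chunk, _one_hot(accepted[:k0]), L)
            chunk = chunk[dist.min(axis=1) >= d]
        for word in chunk:
            if k > k0:
                # only the words accepted within this chunk still need checking
                if int((accepted[k0:k] != word).sum(axis=1).min()) < d:
                    continue
            accepted[k] = word
            k += 1
            if k == target_count:
                break
        if k == target_count:
            break

    seqs = [decode_codes(accepted[i]) for i in range(k)]
    result = BarcodeSet.from_sequences(seqs, d, design_seed=seed, profile_name=profile_name)
    if k < target_count:
        raise DesignExhaustedError(result, target_count)
    return result


@dataclass(frozen=True)
class SetReport:
    """Validation report for a barcode set."""

    n_codewords: int
    min_distance: int
    duplicate_pairs: int
    constraint_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.duplicate_pairs == 0 and not self.constraint_violations


def pairwise_distances(bset: BarcodeSet) -> np.ndarray:
    """Full (n, n) Hamming distance matrix of the set's codewords."""
    m = bset.matrix()
    return _distances_to(m, _one_hot(m), bset.length)


def validate_set(bset: BarcodeSet, constraints: DesignConstraints | None = None) -> SetReport:
    """Compute the exact minimum pairwise distance (all C(n,2) pairs),
    count duplicate pairs, and optionally check composition constraints."""
    n = len(bset)
    if n == 0:
        raise ValueError("cannot validate an empty barcode set")
    if n == 1:
        dmin, dups = bset.length, 0
    else:
        dist = pairwise_distances(bset)
        iu = np.triu_indices(n, k=1)
        upper = dist[iu]
        dmin = int(upper.min())
        dups = int((upper == 0).sum())
    violations: list[str] = []
    if constraints is not None:
        mask = _constraint_mask(bset.matrix(), constraints)
        for ok, bc in zip(mask, bset):
            if not ok:
                violations.append(f"barcode {bc.id} ({bc.sequence}) violates constraints")
    return SetReport(n, dmin, dups, violations)


# ---------------------------------------------------------------------------
# decoding


def decode_batch(
    observed: Sequence[str] | np.ndarray,
    bset: BarcodeSet,
    max_correct: int = 1,
    chunk_size: int = 1 << 15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode many observed index words at once.

    Returns ``(status, barcode_id, distance)`` arrays.  ``status`` uses the
    ``STATUS_*`` codes; ``barcode_id`` is 0 where no assignment was made.
    Words whose length differs from the set length are reported unassigned.
    Non-ACGT characters mismatch every codeword base.
    """
    L = bset.length
    if isinstance(observed, np.ndarray) and observed.ndim == 2:
        words = observed.astype(np.uint8)
        bad_len = np.zeros(len(words), dtype=bool)
    else:
        words = np.full((len(observed), L), _NON_ACGT, dtype=np.uint8)
        bad_len = np.zeros(len(observed), dtype=bool)
        for i, s in enumerate(observed):
            if len(s) != L:
                bad_len[i] = True
            else:
                words[i] = encode_seq(s)

    code_oh = _one_hot(bset.matrix())
    ids = np.asarray(bset.ids, dtype=np.int64)
    n = len(words)
    status = np.full(n, STATUS_UNASSIGNED, dtype=np.int8)
    out_id = np.zeros(n, dtype=np.int64)
    out_dist = np.full(n, -1, dtype=np.int32)

    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        dist = _distances_to(words[sl], code_oh, L)
        dmin = dist.min(axis=1)
        within = (dist <= max_correct).sum(axis=1)
        best = dist.argmin(axis=1)
        perfect = dmin == 0
        corrected = (~perfect) & (dmin <= max_correct) & (within == 1)
        ambiguous = (dmin <= max_correct) & (within > 1) & ~perfect
        st = np.full(dist.shape[0], STATUS_UNASSIGNED, dtype=np.int8)
        st[ambiguous] = STATUS_AMBIGUOUS
        st[corrected] = STATUS_CORRECTED
        st[perfect] = STATUS_PERFECT
        assigned = perfect | corrected
        status[sl] = st
        ids_chunk = np.where(assigned, ids[best], 0)
        out_id[sl] = ids_chunk
        out_dist[sl] = np.where(assigned, dmin, -1)

    status[bad_len] = STATUS_UNASSIGNED
    out_id[bad_len] = 0
    out_dist[bad_len] = -1
    return status, out_id, out_dist


def decode_index(observed: str, bset: BarcodeSet, max_correct: int = 1) -> DecodeResult:
    """Decode a single observed index word with bounded-radius correction.

    perfect: equals a codeword; corrected: exactly one codeword within
    ``max_correct``; unassigned: none within reach; ambiguous: several within
    reach (only possible when the set's minimum distance is below
    ``2*max_correct + 1``).
    """
    if len(observed) != bset.length:
        raise ValueError(
            f"observed word has length {len(observed)}, set length is {bset.length}"
        )
    status, bid, dist = decode_batch([observed], bset, max_correct)
    s = _STATUS_NAMES[status[0]]
    if s in ("perfect", "corrected"):
        return DecodeResult(s, int(bid[0]), int(dist[0]))
    return DecodeResult(s)


# ---------------------------------------------------------------------------
# misassignment geometry and channel probability


def min_errors_to_misassign(bset: BarcodeSet, max_correct: int = 1) -> int:
    """Smallest number of substitutions turning some codeword into a word
    that decodes (radius ``max_correct``) to a *different* codeword.

    Equals ``min_{i != j} Hamming(c_i, c_j) - max_correct``: the cheapest
    route is to walk from a codeword toward its nearest neighbour until the
    word falls inside the neighbour's correction ball.
    """
    if len(bset) < 2:
        raise ValueError("misassignment undefined for a set with fewer than 2 codewords")
    report = validate_set(bset)
    return report.min_distance - max_correct


def enumerate_perturbations(word: np.ndarray, n_errors: int) -> np.ndarray:
    """All words at Hamming distance exactly ``n_errors`` from ``word``
    (base-code representation), as an (m, L) uint8 array."""
    L = len(word)
    if n_errors == 0:
        return word.reshape(1, L).copy()
    rows = []
    for positions in itertools.combinations(range(L), n_errors):
        for subs in itertools.product(range(3), repeat=n_errors):
            w = word.copy()
            for pos, s in zip(positions, subs):
                alts = [b for b in range(4) if b != word[pos]]
                w[pos] = alts[s]
            rows.append(w)
    return np.vstack(rows)


def count_misassigned_perturbations(
    bset: BarcodeSet,
    max_errors: int,
    max_correct: int = 1,
    chunk_size: int = 1 << 15,
) -> tuple[int, int]:
    """Exhaustively enumerate every word within ``max_errors`` substitutions
    of every codeword and decode each with radius ``max_correct``.

    Returns ``(n_misassigned, n_enumerated)`` where a misassignment is a
    perturbed word assigned (perfect or corrected) to a codeword other than
    the one it was derived from.  This is the brute-force check that the
    code's error-correction geometry delivers what the pairwise distances
    promise.
    """
    m = bset.matrix()
    ids = np.asarray(bset.ids)
    total = 0
    bad = 0
    for i in range(len(bset)):
        pert = [enumerate_perturbations(m[i], e) for e in range(1, max_errors + 1)]
        words = np.vstack(pert)
        total += len(words)
        status, bid, _ = decode_batch(words, bset, max_correct, chunk_size=chunk_size)
        assigned = (status == STATUS_PERFECT) | (status == STATUS_CORRECTED)
        bad += int((assigned & (bid != ids[i])).sum())
    return bad, total


def misassignment_probability(
    bset: BarcodeSet, channel: ChannelModel, max_correct: int = 1
) -> float:
    """Exact probability, averaged uniformly over true codewords, that the
    substitution channel's output falls within Hamming distance
    ``max_correct`` of a *different* codeword.

    Computed by exact enumeration over the radius-``max_correct`` balls of
    all competing codewords (deduplicated, so overlapping balls in malformed
    sets are not double counted) — not by sampling.
    """
    n = len(bset)
    if n < 2:
        return 0.0
    p = channel.per_base_substitution_rate
    L = bset.length
    t = p / 3.0
    q = 1.0 - p
    m = bset.matrix()

    # radius-r ball around each codeword, packed into base-4 integers
    powers = (4 ** np.arange(L, dtype=np.int64))[::-1]
    balls = []
    for j in range(n):
        ball = np.vstack(
            [enumerate_perturbations(m[j], e) for e in range(0, max_correct + 1)]
        )
        balls.append(ball.astype(np.int64) @ powers)

    total = 0.0
    for i in range(n):
        other = np.unique(np.concatenate([balls[j] for j in range(n) if j != i]))
        # unpack and measure distance from the true codeword
        digits = np.empty((len(other), L), dtype=np.uint8)
        v = other.copy()
        for pos in range(L - 1, -1, -1):
            digits[:, pos] = v & 3
            v >>= 2
        k = (digits != m[i]).sum(axis=1)
        if p == 0.0:
            prob = float((k == 0).sum())  # only distance-0 words have mass
        else:
            prob = float(np.sum(np.power(t, k) * np.power(q, L - k)))
        total += prob
    return total / n


def simulate_channel_reads(
    bset: BarcodeSet,
    barcode_ids: Sequence[int],
    n_reads: int,
    channel: ChannelModel,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_reads`` index reads uniformly from the named codewords and
    pass every base through the substitution channel.

    Returns ``(true_ids, observed_words)`` with observed words in base-code
    representation, ready for :func:`decode_batch`.  Used to measure
    empirical mis-attribution rates of a barcode pool.
    """
    rng = np.random.default_rng(seed)
    id_arr = np.asarray(barcode_ids)
    pos_of_id = {bid: k for k, bid in enumerate(bset.ids)}
    rows = np.array([pos_of_id[b] for b in id_arr])
    m = bset.matrix()
    pick = rng.integers(0, len(rows), size=n_reads)
    true_ids = id_arr[pick]
    words = m[rows[pick]].copy()
    p = channel.per_base_substitution_rate
    if p > 0:
        hit = rng.random(words.shape) < p
        shift = rng.integers(1, 4, size=words.shape).astype(np.uint8)
        words[hit] = (words[hit] + shift[hit]) % 4
    return true_ids, words


# ---------------------------------------------------------------------------
# on-disk representation: TSV of (id, sequence) + JSON sidecar


def write_barcode_set(bset: BarcodeSet, path: str | Path) -> Path:
    """Write a set as TSV (columns id, sequence) with a JSON sidecar holding
    length, distance, seed, profile and the achieved minimum distance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tsequence\n")
        for bc in bset:
            fh.write(f"{bc.id}\t{bc.sequence}\n")
    report = validate_set(bset)
    sidecar = {
        "length": bset.length,
        "declared_min_distance": bset.declared_min_distance,
        "design_seed": bset.design_seed,
        "profile_name": bset.profile_name,
        "n_codewords": len(bset),
        "achieved_min_distance": report.min_distance,
    }
    side_path = path.with_suffix(path.suffix + ".json")
    side_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return side_path


def read_barcode_set(path: str | Path) -> BarcodeSet:
    path = Path(path)
    ids: list[int] = []
    seqs: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id"):
            raise ValueError(f"{path}: expected TSV header starting with 'id'")
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bid, seq = line.split("\t")
            ids.append(int(bid))
            seqs.append(seq.upper())
    if not seqs:
        raise ValueError(f"{path}: no barcodes found")
    meta = {}
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        meta = json.loads(side_path.read_text())
    barcodes = [Barcode(i, s) for i, s in zip(ids, seqs)]
    return BarcodeSet(
        length=len(seqs[0]),
        declared_min_distance=meta.get("declared_min_distance", 1),
        barcodes=barcodes,
        design_seed=meta.get("design_seed"),
        profile_name=meta.get("profile_name"),
    )
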