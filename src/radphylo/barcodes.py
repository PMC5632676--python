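"""Variable-length inline barcode design for RADseq libraries.

Single-index RADseq barcodes are ligated directly against the restriction
cutsite, so every read shows the same few constant bases immediately after
its barcode.  Using barcodes of mixed length (7-10 bp) staggers those
constant bases across the flowcell, restoring per-cycle base diversity and
improving Illumina base calling.  This module designs such a panel:

1. a pool of 10-bp candidates is accumulated greedily, accepting a random
   candidate only when its Levenshtein distance to every accepted barcode
   meets a threshold (default 4), with homopolymer runs of five or more
   excluded;
2. all pairwise *slippage-aware* distances (Hamming distance minimised over
   a +/-1 bp relative offset) are computed, and a two-pass filter discards
   barcodes involved in too many near-collisions (distance < 3);
3. shorter barcodes are derived by suffix truncation against the enzyme's
   recognition motif (for "CAATTC": trailing "CAA" -> 7-mers, "CA" ->
   8-mers, "C" -> 9-mers), exploiting the fact that the truncated bases are
   re-created by the cutsite during sequencing;
4. the final 10-mers are drawn without replacement with probability
   proportional to a base-composition weight that favours barcodes carrying
   under-represented bases at compositionally skewed positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Barcode",
    "BarcodeSet",
    "PanelConfig",
    "levenshtein",
    "slippage_distance",
    "generate_candidates",
    "filter_two_strike",
    "derive_variable_length",
    "weighted_sample_final",
    "design_barcode_panel",
    "write_panel",
    "read_panel",
]

_ALPHABET = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_ALPHABET)}

MIN_SLIPPAGE_DISTANCE = 3


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"barcode {seq!r} contains a non-ACGT base") from exc


def _validate_barcode(seq: str, lengths=(7, 8, 9, 10)) -> None:
    if len(seq) not in lengths:
        raise ValueError(f"barcode {seq!r} has length {len(seq)}, expected one of {lengths}")
    if any(b not in _BASE_CODE for b in seq):
        raise ValueError(f"barcode {seq!r} contains a non-ACGT base")


@dataclass(frozen=True)
class Barcode:
    """An inline index sequence of 7-10 bp over the DNA alphabet."""

    sequence: str

    def __post_init__(self) -> None:
        _validate_barcode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass
class BarcodeSet:
    """A collection of barcode sequences with design metadata.

    ``complete`` is False when greedy generation exhausted its attempt
    budget before reaching the requested size.
    """

    barcodes: list[str]
    cutsite: str = "CAATTC"
    min_slippage_distance: int = MIN_SLIPPAGE_DISTANCE
    complete: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for seq in self.barcodes:
            _validate_barcode(seq)
            if seq in seen:
                raise ValueError(f"duplicate barcode {seq!r}")
            seen.add(seq)

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def min_pairwise_slippage(self) -> int:
        """Exhaustive minimum slippage distance over all pairs (inf if < 2 members)."""
        best = float("inf")
        for i, a in enumerate(self.barcodes):
            for b in self.barcodes[i + 1 :]:
                best = min(best, slippage_distance(a, b))
        return best


def levenshtein(a: str, b: str) -> int:
    """Textbook edit distance (substitutions, insertions, deletions all cost 1)."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _levenshtein_to_pool(cand: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Edit distance from one encoded barcode to every row of an encoded pool.

    Vectorised over the pool: the DP table is (pool_size,) per cell, so the
    inner loops run len(cand) x pool_width numpy operations regardless of
    pool size.
    """
    n = pool.shape[0]
    width = pool.shape[1]
    prev = np.broadcast_to(np.arange(width + 1), (n, width + 1)).astype(np.int32).copy()
    for i in range(1, len(cand) + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        ca = cand[i - 1]
        for j in range(1, width + 1):
            sub = prev[:, j - 1] + (pool[:, j - 1] != ca)
            np.minimum(sub, prev[:, j] + 1, out=sub)
            np.minimum(sub, cur[:, j - 1] + 1, out=sub)
            cur[:, j] = sub
        prev = cur
    return prev[:, -1]


def slippage_distance(a: str, b: str) -> int:
    """Barcode distance allowing 1 bp of slippage at either end.

    Minimum over relative offsets {-1, 0, +1} of the Hamming distance on
    the overlapping window; overhanging bases are not charged.  This is the
    distance that guards against frameshifted read-to-sample misassignment:
    a single lost or gained base at the start of a read must not convert
    one barcode into another.
    """
    _validate_barcode(a)
    _validate_barcode(b)
    best = len(a) + len(b)
    for offset in (-1, 0, 1):
        # align a[i] with b[i + offset]
        start = max(0, -offset)
        stop = min(len(a), len(b) - offset)
        if stop <= start:
            continue
        mism = sum(1 for i in range(start, stop) if a[i] != b[i + offset])
        best = min(best, mism)
    return best


def _pairwise_slippage_matrix(encoded: np.ndarray) -> np.ndarray:
    """All-pairs slippage distance for equal-length encoded barcodes."""
    n, width = encoded.shape
    out = np.full((n, n), np.iinfo(np.int32).max, dtype=np.int32)
    for offset in (-1, 0, 1):
        if offset == 0:
            a = b = encoded
            pad = 0
        elif offset == 1:
            a, b = encoded[:, :-1], encoded[:, 1:]
            pad = 0
        else:
            a, b = encoded[:, 1:], encoded[:, :-1]
            pad = 0
        mism = (a[:, None, :] != b[None, :, :]).sum(axis=2).astype(np.int32) + pad
        np.minimum(out, mism, out=out)
    np.fill_diagonal(out, 0)
    return out


def _has_long_homopolymer(seq: str, max_run: int = 4) -> bool:
    run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > max_run:
            return True
    return False


def generate_candidates(
    n_target: int,
    length: int = 10,
    min_edit_distance: int = 4,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 2_000_000,
    cutsite: str = "CAATTC",
) -> BarcodeSet:
    """Greedily accumulate random barcodes at a minimum pairwise edit distance.

    A random candidate is accepted only if its Levenshtein distance to every
    already-accepted barcode is at least ``min_edit_distance``; candidates
    containing a homopolymer run of 5+ are rejected outright.  Generation
    stops at ``n_target`` or when the attempt budget is exhausted, in which
    case the smaller set is returned with ``complete=False`` and a warning.

    Greedy random packing saturates well below the best structured codes at
    this distance, so very large pools are unreachable by construction; the
    default panel pool (2,000) is comfortably inside the feasible region.
    """
    if min_edit_distance < 1:
        raise ValueError("min_edit_distance must be >= 1")
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted: list[str] = []
    capacity = max(n_target, 1)
    pool = np.empty((capacity, length), dtype=np.uint8)
    n_pool = 0
    attempts = 0
    batch_size = 8192
    while len(accepted) < n_target and attempts < max_attempts:
        batch = rng.integers(0, 4, size=(min(batch_size, max_attempts - attempts), length), dtype=np.uint8)
        attempts += batch.shape[0]
        # Reject homopolymer runs >= 5 vectorised: a run of 5 means 4
        # consecutive equal-neighbour positions.
        eq = batch[:, 1:] == batch[:, :-1]
        run4 = np.zeros(batch.shape[0], dtype=bool)
        for s in range(length - 4):
            run4 |= eq[:, s : s + 4].all(axis=1)
        batch = batch[~run4]
        if not batch.shape[0]:
            continue
        if n_pool:
            # Cheap prescreen: Levenshtein <= Hamming, so a pool member within
            # Hamming < threshold already violates the constraint.  Accumulate
            # mismatch counts column-wise to avoid a (B, N, width) temporary.
            hamming = np.zeros((batch.shape[0], n_pool), dtype=np.uint8)
            for j in range(length):
                hamming += batch[:, j : j + 1] != pool[None, :n_pool, j]
            batch = batch[hamming.min(axis=1) >= min_edit_distance]
        # Survivors are rare near saturation; verify them sequentially with
        # exact Levenshtein (greedy order matters within a batch too).
        for cand in batch:
            if n_pool and int(_levenshtein_to_pool(cand, pool[:n_pool]).min()) < min_edit_distance:
                continue
            accepted.append("".join(_ALPHABET[c] for c in cand))
            if n_pool == capacity:
                capacity *= 2
                pool = np.vstack([pool, np.empty_like(pool)])
            pool[n_pool] = cand
            n_pool += 1
            if len(accepted) >= n_target:
                break
    complete = len(accepted) >= n_target
    if not complete:
        warnings.warn(
            f"generate_candidates reached {len(accepted)}/{n_target} barcodes "
            f"within {max_attempts} attempts",
            stacklevel=2,
        )
    return BarcodeSet(accepted, cutsite=cutsite, complete=complete)


def filter_two_strike(candidates: BarcodeSet) -> BarcodeSet:
    """Two-pass slippage filter enforcing a minimum pairwise distance of 3.

    Pass 1: every pair at slippage distance < 3 puts one strike on *both*
    members; members with two or more strikes are discarded.  Pass 2:
    distances are recomputed among survivors, and any barcode whose minimum
    distance to another survivor is still < 3 is discarded.  The result
    satisfies the BarcodeSet guarantee (all pairwise slippage distances >= 3).
    """
    seqs = list(candidates.barcodes)
    if not seqs:
        return BarcodeSet([], cutsite=candidates.cutsite)
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("filter_two_strike expects equal-length barcodes")
    encoded = np.vstack([_encode(s) for s in seqs])
    dist = _pairwise_slippage_matrix(encoded)
    close = dist < MIN_SLIPPAGE_DISTANCE
    np.fill_diagonal(close, False)
    strikes = close.sum(axis=1)
    keep1 = strikes < 2
    survivors = [s for s, k in zip(seqs, keep1) if k]
    if not survivors:
        return BarcodeSet([], cutsite=candidates.cutsite)
    dist2 = dist[np.ix_(keep1, keep1)]
    close2 = dist2 < MIN_SLIPPAGE_DISTANCE
    np.fill_diagonal(close2, False)
    keep2 = ~close2.any(axis=1)
    final = [s for s, k in zip(survivors, keep2) if k]
    return BarcodeSet(final, cutsite=candidates.cutsite)


def derive_variable_length(set10: BarcodeSet, cutsite: str | None = None) -> dict[int, BarcodeSet]:
    """Partition a 10-mer pool into 7/8/9-mer truncations plus the residual pool.

    A 10-mer ending with the first three bases of the cutsite (for "CAATTC":
    "CAA") loses that suffix and becomes a 7-mer, because those bases are
    regenerated by the cutsite during sequencing; suffix "CA" yields 8-mers
    and "C" yields 9-mers.  A 10-mer matching several suffixes is assigned to
    the longest-suffix class only, making the partition deterministic.
    Duplicates arising after truncation are dropped (first occurrence kept).
    Returns ``{7: ..., 8: ..., 9: ..., 10: residual pool}``.
    """
    cutsite = cutsite if cutsite is not None else set10.cutsite
    if len(cutsite) < 3:
        raise ValueError("cutsite must be at least 3 bp for suffix truncation")
    if any(len(s) != 10 for s in set10.barcodes):
        raise ValueError("derive_variable_length expects a 10-mer pool")
    suffixes = {7: cutsite[:3], 8: cutsite[:2], 9: cutsite[:1]}
    out: dict[int, list[str]] = {7: [], 8: [], 9: [], 10: []}
    seen: dict[int, set[str]] = {7: set(), 8: set(), 9: set()}
    for seq in set10.barcodes:
        for target_len in (7, 8, 9):  # longest suffix first
            suffix = suffixes[target_len]
            if seq.endswith(suffix):
                trunc = seq[: len(seq) - len(suffix)]
                if trunc not in seen[target_len]:
                    seen[target_len].add(trunc)
                    out[target_len].append(trunc)
                break
        else:
            out[10].append(seq)
    return {
        length: BarcodeSet(seqs, cutsite=cutsite, min_slippage_distance=set10.min_slippage_distance)
        for length, seqs in out.items()
    }


def barcode_weights(pool: list[str], floor: float = 1e-9) -> np.ndarray:
    """Composition-diversity weights for a pool of equal-length barcodes.

    Per site, each base's frequency across the pool is computed.  A base's
    weight at a site is 1/max(frequency, floor) (rarer bases weigh more) and
    the site's weight is the ratio of its most to least common observed base
    (more skewed sites weigh more).  A barcode's weight is the product over
    sites of site weight x weight of its own base at that site.
    """
    if not pool:
        return np.zeros(0)
    width = len(pool[0])
    if any(len(s) != width for s in pool):
        raise ValueError("weighted sampling expects equal-length barcodes")
    encoded = np.vstack([_encode(s) for s in pool])
    n = len(pool)
    log_w = np.zeros(n)
    for j in range(width):
        counts = np.bincount(encoded[:, j], minlength=4)
        freqs = counts / n
        observed = freqs[freqs > 0]
        site_weight = observed.max() / observed.min()
        base_weight = 1.0 / np.maximum(freqs, floor)
        log_w += np.log(site_weight) + np.log(base_weight[encoded[:, j]])
    log_w -= log_w.max()
    return np.exp(log_w)


def weighted_sample_final(
    pool10: BarcodeSet, k: int, seed: int | np.random.Generator = 0
) -> BarcodeSet:
    """Draw k 10-mers without replacement, proportional to composition weights.

    Barcodes carrying under-represented bases at skewed sites are favoured,
    maximising base diversity in the final set.  Deterministic under a fixed
    seed.
    """
    if k > len(pool10):
        raise ValueError(f"cannot sample {k} barcodes from a pool of {len(pool10)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(pool10.barcodes)
    if k == len(pool):
        return BarcodeSet(pool, cutsite=pool10.cutsite)
    weights = barcode_weights(pool)
    chosen: list[str] = []
    available = list(range(len(pool)))
    for _ in range(k):
        w = weights[available]
        probs = w / w.sum()
        idx = rng.choice(len(available), p=probs)
        chosen.append(pool[available.pop(idx)])
    return BarcodeSet(chosen, cutsite=pool10.cutsite)


@dataclass
class PanelConfig:
    """Requested composition of the final barcode panel.

    Defaults mirror a 96-barcode panel: every surviving 7-mer (capped at
    ``n7``), 24 8-mers, 24 9-mers, and 30 weighted-sampled 10-mers.
    """

    n7: int = 18
    n8: int = 24
    n9: int = 24
    n10: int = 30
    pool_size: int = 1500
    min_edit_distance: int = 4
    cutsite: str = "CAATTC"
    seed: int = 0
    max_attempts: int = 400_000


@dataclass
class PanelResult:
    """Designed panel with per-length members and any shortfall report."""

    panel: BarcodeSet
    by_length: dict[int, BarcodeSet]
    shortfall: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.panel)

    def assignment_template(self, sample_ids: list[str] | None = None) -> list[tuple[str, str, int]]:
        """(sample_id, barcode, length) rows, samples named S01.. by default."""
        seqs = list(self.panel.barcodes)
        if sample_ids is None:
            sample_ids = [f"S{i + 1:02d}" for i in range(len(seqs))]
        if len(sample_ids) > len(seqs):
            raise ValueError("more samples than barcodes in panel")
        return [(sid, seq, len(seq)) for sid, seq in zip(sample_ids, seqs)]


def design_barcode_panel(config: PanelConfig | None = None) -> PanelResult:
    """Run the full design: generate, two-strike filter, truncate, sample.

    Shorter barcodes (7/8/9-mers) are drawn uniformly at random from their
    truncation classes; the 10-mers are drawn by composition weighting.  If
    any class holds fewer survivors than requested, every survivor is taken
    and the deficit is recorded in ``shortfall``.
    """
    cfg = config or PanelConfig()
    rng = np.random.default_rng(cfg.seed)
    candidates = generate_candidates(
        cfg.pool_size,
        length=10,
        min_edit_distance=cfg.min_edit_distance,
        seed=rng,
        max_attempts=cfg.max_attempts,
        cutsite=cfg.cutsite,
    )
    filtered = filter_two_strike(candidates)
    classes = derive_variable_length(filtered, cfg.cutsite)
    requested = {7: cfg.n7, 8: cfg.n8, 9: cfg.n9, 10: cfg.n10}
    chosen: dict[int, BarcodeSet] = {}
    shortfall: dict[int, int] = {}
    for length in (7, 8, 9):
        want = requested[length]
        have = list(classes[length].barcodes)
        if want > len(have):
            shortfall[length] = want - len(have)
            want = len(have)
        idx = rng.choice(len(have), size=want, replace=False) if have and want else []
        chosen[length] = BarcodeSet([have[i] for i in sorted(idx)], cutsite=cfg.cutsite)
    want10 = requested[10]
    if want10 > len(classes[10]):
        shortfall[10] = want10 - len(classes[10])
        want10 = len(classes[10])
    chosen[10] = weighted_sample_final(classes[10], want10, seed=rng)
    panel_seqs = [s for length in (7, 8, 9, 10) for s in chosen[length].barcodes]
    if shortfall:
        warnings.warn(f"barcode panel shortfall by length: {shortfall}", stacklevel=2)
    return PanelResult(
        panel=BarcodeSet(panel_seqs, cutsite=cfg.cutsite),
        by_length=chosen,
        shortfall=shortfall,
    )


def write_panel(result: PanelResult, path, sample_ids: list[str] | None = None) -> None:
    """Write the panel as tab-delimited (sample_id, barcode, length)."""
    rows = result.assignment_template(sample_ids)
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\tlength\n")
        for sid, seq, length in rows:
            fh.write(f"{sid}\t{seq}\t{length}\n")


def read_panel(path) -> dict[str, str]:
    """Read a tab-delimited panel back as {sample_id: barcode}."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError(f"unrecognised panel header in {path}")
        for line in fh:
            if not line.strip():
                continue
            sid, seq, _length = line.rstrip("\n").split("\t")
            _validate_barcode(seq)
            if sid in out:
                raise ValueError(f"duplicate sample id {sid!r} in {path}")
            out[sid] = seq
    return out
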