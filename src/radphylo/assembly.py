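"""Stack-based de novo RAD locus assembly and cross-sample catalog building.

The assembler exposes the four parameters that govern a Stacks-style
pipeline:

``m``
    minimum number of identical reads required to found a primary stack;
``M``
    maximum Hamming distance at which two stacks within a sample are merged
    into one locus (allelic distance);
``max_locus_stacks``
    maximum number of stacks a merged locus may contain before the whole
    cluster is discarded as a likely repeat/paralog collapse;
``n``
    maximum Hamming distance at which loci from different samples are
    merged into one catalog locus.

Within a sample, stacks are merged by single linkage; across samples the
catalog grows by greedy first-fit in deterministic (sorted sample id,
then locus id) order.  These tie-break rules are this package's own - the
upstream tools do not document theirs - and are fixed so that every run is
reproducible.  SNP calling is a simplified frequency threshold (a column is
polymorphic when two bases each carry >= 25% of locus depth), standing in
for likelihood models that the source pipeline does not specify.

A simplified reference-placement mode (exact 20-mer seed, ungapped extension,
both strands) substitutes for an external aligner; reads placed at the same
(contig, position, strand) form positional stacks with a fixed minimum
depth of 2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AssemblyParams",
    "Stack",
    "SampleLocus",
    "CatalogLocus",
    "Catalog",
    "build_stacks",
    "merge_stacks",
    "call_snps",
    "assemble_sample",
    "map_to_reference",
    "build_catalog",
    "match_to_catalog",
]

_ALPHABET = "ACGT"
SNP_MIN_FRACTION = 0.25
REFERENCE_MIN_DEPTH = 2
SEED_K = 20


@dataclass(frozen=True)
class AssemblyParams:
    """The four assembly knobs plus the missing-data threshold they feed."""

    m: int = 2
    M: int = 2
    max_locus_stacks: int = 3
    n: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.m <= 20:
            raise ValueError("m must be in [1, 20]")
        if self.M < 0 or self.n < 0:
            raise ValueError("M and n must be >= 0")
        if self.max_locus_stacks < 1:
            raise ValueError("max_locus_stacks must be >= 1")


@dataclass
class Stack:
    """A pile of identical reads within one sample."""

    sequence: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("stack depth must be >= 1")


@dataclass
class SampleLocus:
    """A merged locus within one sample."""

    locus_id: int
    sample_id: str
    consensus: str
    member_stacks: list[Stack]
    snp_columns: list[int] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return sum(s.depth for s in self.member_stacks)


@dataclass
class CatalogLocus:
    """A cross-sample consensus locus."""

    catalog_id: int
    consensus: str
    matched: dict[str, SampleLocus] = field(default_factory=dict)


@dataclass
class Catalog:
    loci: list[CatalogLocus]

    def __len__(self) -> int:
        return len(self.loci)

    def occupancy(self, sample_ids: list[str]) -> pd.DataFrame:
        """Boolean samples x catalog-loci matrix of who has data where."""
        data = np.zeros((len(sample_ids), len(self.loci)), dtype=bool)
        col_ids = [f"C{locus.catalog_id:05d}" for locus in self.loci]
        index = {sid: i for i, sid in enumerate(sample_ids)}
        for j, locus in enumerate(self.loci):
            for sid in locus.matched:
                data[index[sid], j] = True
        return pd.DataFrame(data, index=list(sample_ids), columns=col_ids)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


def build_stacks(reads, m: int) -> tuple[list[Stack], list[str]]:
    """Group identical read sequences into primary stacks.

    Sequences with fewer than ``m`` copies become secondary reads, to be
    attached to formed loci later.  Accepts ReadRecords or plain strings.
    Stacks are ordered by (depth desc, sequence) for determinism.
    """
    seqs = [getattr(r, "sequence", r) for r in reads]
    if not seqs:
        return [], []
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"reads must share one length, got {sorted(lengths)}")
    counts = Counter(seqs)
    stacks = [
        Stack(seq, depth) for seq, depth in counts.items() if depth >= m
    ]
    stacks.sort(key=lambda s: (-s.depth, s.sequence))
    secondary = [
        seq for seq, depth in counts.items() if depth < m for _ in range(depth)
    ]
    secondary.sort()
    return stacks, secondary


def _consensus(stacks: list[Stack]) -> tuple[str, np.ndarray]:
    """Depth-weighted majority base per column; ties to the smaller base.

    Returns the consensus string and the (4, length) depth-per-base matrix
    used for SNP calling.
    """
    length = len(stacks[0].sequence)
    depth_matrix = np.zeros((4, length), dtype=np.int64)
    for stack in stacks:
        codes = np.frombuffer(stack.sequence.encode(), dtype=np.uint8)
        for bi, base in enumerate(_ALPHABET):
            depth_matrix[bi, codes == ord(base)] += stack.depth
    # argmax returns the first (lexicographically smallest) base on ties
    consensus = "".join(_ALPHABET[i] for i in depth_matrix.argmax(axis=0))
    return consensus, depth_matrix


def call_snps(depth_matrix: np.ndarray) -> list[int]:
    """Columns where >= 2 bases each reach ceil(25% of locus depth).

    A simplified frequency-threshold caller: real RAD pipelines use
    per-sample likelihood models, but those are not needed to exercise the
    parameter grid and would add unspecified behaviour.
    """
    total = depth_matrix.sum(axis=0)
    out = []
    for j in range(depth_matrix.shape[1]):
        if total[j] == 0:
            continue
        need = -(-total[j] // 4)  # ceil(0.25 * depth)
        if (depth_matrix[:, j] >= need).sum() >= 2:
            out.append(j)
    return out


def merge_stacks(
    stacks: list[Stack], M: int, max_locus_stacks: int, sample_id: str = ""
) -> list[SampleLocus]:
    """Single-linkage merge of a sample's stacks into loci.

    Stacks within Hamming distance ``M`` join the same cluster; any cluster
    with more than ``max_locus_stacks`` members is discarded outright
    (repeat filter).  Consensus is the depth-weighted majority base per
    column with ties to the lexicographically smallest base.
    """
    if not stacks:
        return []
    n = len(stacks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming(stacks[i].sequence, stacks[j].sequence) <= M:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    loci = []
    locus_id = 0
    # iterate clusters in order of their first member for determinism
    for members in sorted(clusters.values(), key=lambda ms: ms[0]):
        if len(members) > max_locus_stacks:
            continue  # blacklist: likely repetitive
        cluster = [stacks[i] for i in members]
        consensus, depth_matrix = _consensus(cluster)
        loci.append(
            SampleLocus(
                locus_id=locus_id,
                sample_id=sample_id,
                consensus=consensus,
                member_stacks=cluster,
                snp_columns=call_snps(depth_matrix),
            )
        )
        locus_id += 1
    return loci


def assemble_sample(reads, params: AssemblyParams, sample_id: str = "") -> list[SampleLocus]:
    """Full within-sample assembly: stacks, merge, secondary-read rescue.

    Secondary reads (below the ``m`` depth floor) are attached to the
    nearest formed locus within ``M`` mismatches (ties to the lowest locus
    id); consensus and SNP columns are then recomputed with them included.
    """
    stacks, secondary = build_stacks(reads, params.m)
    loci = merge_stacks(stacks, params.M, params.max_locus_stacks, sample_id)
    if loci and secondary:
        extras: dict[int, Counter] = {}
        for seq in secondary:
            best_d, best_locus = None, None
            for locus in loci:
                d = _hamming(seq, locus.consensus)
                if d <= params.M and (best_d is None or d < best_d):
                    best_d, best_locus = d, locus.locus_id
            if best_locus is not None:
                extras.setdefault(best_locus, Counter())[seq] += 1
        for locus in loci:
            if locus.locus_id in extras:
                for seq, depth in sorted(extras[locus.locus_id].items()):
                    locus.member_stacks.append(Stack(seq, depth))
                consensus, depth_matrix = _consensus(locus.member_stacks)
                locus.consensus = consensus
                locus.snp_columns = call_snps(depth_matrix)
    return loci


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def map_to_reference(
    reads,
    reference_fasta,
    max_mismatch: int = 4,
    sample_id: str = "",
) -> tuple[list[SampleLocus], float]:
    """Place reads on a reference by exact 20-mer seed and ungapped extension.

    Seeds are taken at non-overlapping offsets along the read (pigeonhole:
    with <= 4 mismatches over 100 bp, at least one of five 20-mers is
    exact).  Both strands are searched; the first acceptable placement in
    (contig, position, strand-forward-first) order wins.  Reads sharing a
    placement form a positional stack; positional loci require depth >= 2
    (the fixed minimum the reference mode of the source pipeline used).
    Returns (loci, alignment_rate).
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_fasta), "fasta")
    }
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError(f"reference {reference_fasta} is empty")
    index: dict[str, list[tuple[str, int]]] = {}
    for cid in sorted(contigs):
        seq = contigs[cid]
        for i in range(len(seq) - SEED_K + 1):
            index.setdefault(seq[i : i + SEED_K], []).append((cid, i))
    placements: dict[tuple[str, int, str], Counter] = {}
    seqs = [getattr(r, "sequence", r) for r in reads]
    n_placed = 0
    for seq in seqs:
        placed = None
        for strand in "+-":
            query = seq if strand == "+" else _revcomp(seq)
            hits: list[tuple[str, int]] = []
            for off in range(0, len(query) - SEED_K + 1, SEED_K):
                for cid, pos in index.get(query[off : off + SEED_K], ()):
                    start = pos - off
                    if start < 0 or start + len(query) > len(contigs[cid]):
                        continue
                    hits.append((cid, start))
            for cid, start in sorted(set(hits)):
                ref_window = contigs[cid][start : start + len(query)]
                if _hamming(query, ref_window) <= max_mismatch:
                    placed = (cid, start, strand, query)
                    break
            if placed:
                break
        if placed:
            cid, start, strand, query = placed
            placements.setdefault((cid, start, strand), Counter())[query] += 1
            n_placed += 1
    loci = []
    locus_id = 0
    for key in sorted(placements):
        counter = placements[key]
        total_depth = sum(counter.values())
        if total_depth < REFERENCE_MIN_DEPTH:
            continue
        stacks = [Stack(seq, d) for seq, d in sorted(counter.items())]
        consensus, depth_matrix = _consensus(stacks)
        loci.append(
            SampleLocus(
                locus_id=locus_id,
                sample_id=sample_id,
                consensus=consensus,
                member_stacks=stacks,
                snp_columns=call_snps(depth_matrix),
            )
        )
        locus_id += 1
    rate = n_placed / len(seqs) if seqs else 0.0
    return loci, rate


def build_catalog(sample_loci: dict[str, list[SampleLocus]], n: int) -> Catalog:
    """Greedy first-fit catalog construction across samples.

    Samples are processed in sorted id order, loci in locus-id order; each
    locus merges into the first existing catalog entry whose *current*
    consensus is within Hamming distance ``n``, else founds a new entry.
    After a merge the entry's consensus is recomputed as the unweighted
    majority over member consensuses (ties to the smallest base).
    """
    catalog: list[CatalogLocus] = []
    consensus_arr: list[np.ndarray] = []  # encoded consensuses, parallel list
    counts: list[np.ndarray] = []  # per-entry (4, L) member base counts
    matrix: np.ndarray | None = None

    def encode(s: str) -> np.ndarray:
        return np.frombuffer(s.encode(), dtype=np.uint8)

    for sid in sorted(sample_loci):
        for locus in sorted(sample_loci[sid], key=lambda l: l.locus_id):
            code = encode(locus.consensus)
            hit = None
            if catalog:
                stacked = np.vstack(consensus_arr)
                dists = (stacked != code[None, :]).sum(axis=1)
                within = np.nonzero(dists <= n)[0]
                if within.size:
                    hit = int(within[0])  # first-fit in catalog_id order
            if hit is None:
                entry = CatalogLocus(
                    catalog_id=len(catalog), consensus=locus.consensus
                )
                entry.matched[sid] = locus
                catalog.append(entry)
                consensus_arr.append(code)
                cnt = np.zeros((4, code.size), dtype=np.int64)
                for bi, base in enumerate(_ALPHABET):
                    cnt[bi, code == ord(base)] += 1
                counts.append(cnt)
            else:
                entry = catalog[hit]
                if sid in entry.matched:
                    # a sample may contribute at most one locus per entry;
                    # keep the deeper of the two
                    if locus.depth <= entry.matched[sid].depth:
                        continue
                entry.matched[sid] = locus
                cnt = counts[hit]
                for bi, base in enumerate(_ALPHABET):
                    cnt[bi, code == ord(base)] += 1
                new_code = np.frombuffer(
                    "".join(_ALPHABET[i] for i in cnt.argmax(axis=0)).encode(),
                    dtype=np.uint8,
                ).copy()
                consensus_arr[hit] = new_code
                entry.consensus = new_code.tobytes().decode()
    return Catalog(catalog)


def match_to_catalog(
    sample_loci: dict[str, list[SampleLocus]], catalog: Catalog, n: int
) -> pd.DataFrame:
    """Re-match every sample locus to its nearest catalog entry within ``n``.

    Ties go to the lowest catalog id.  Returns the boolean occupancy matrix
    (samples x catalog loci); a sample occupies an entry when at least one
    of its loci matched it.
    """
    sample_ids = sorted(sample_loci)
    data = np.zeros((len(sample_ids), len(catalog)), dtype=bool)
    if len(catalog):
        stacked = np.vstack(
            [np.frombuffer(c.consensus.encode(), dtype=np.uint8) for c in catalog.loci]
        )
        for i, sid in enumerate(sample_ids):
            for locus in sample_loci[sid]:
                code = np.frombuffer(locus.consensus.encode(), dtype=np.uint8)
                dists = (stacked != code[None, :]).sum(axis=1)
                j = int(dists.argmin())  # argmin takes the lowest id on ties
                if dists[j] <= n:
                    data[i, j] = True
    col_ids = [f"C{locus.catalog_id:05d}" for locus in catalog.loci]
    return pd.DataFrame(data, index=sample_ids, columns=col_ids)
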