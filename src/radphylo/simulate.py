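"""Ground-truth simulation: Yule trees, restriction-site dropout, barcoded reads.

The generator emulates the structure of a single-enzyme RADseq experiment on
a recent radiation: a rooted ultrametric species tree from a pure-birth
(Yule) process, per-locus sequences evolved under Jukes-Cantor, and
single-end reads of the form ``barcode + cutsite remnant + locus sequence``.
The principal realistic feature is *locus dropout*: a sample loses a locus
whenever any substitution hits the restriction recognition site on the path
from the root to that sample, which is the mechanism that makes RADseq
matrices sparse and makes missing-data thresholds consequential.  Samples
are haploid (one sequence per sample per locus); indels, paired ends and
PCR duplicates are not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_species_tree",
    "simulate_loci",
    "generate_reads",
    "write_truth",
]

_ALPHABET = "ACGT"
_PHRED_OFFSET = 33


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RADseq world.

    Defaults emulate the study design this package targets: ~48 pooled
    samples on a recent radiation, 1x100 bp reads, and per-sample read
    counts spanning roughly two orders of magnitude (the study reports a
    944-662,231 spread).

    Parameters
    ----------
    n_taxa:
        Number of samples / tree leaves (>= 2).
    birth_rate:
        Yule speciation rate, events per lineage per unit time.
    n_loci:
        Number of restriction-site-anchored loci in the ancestral genome.
    locus_length:
        Length of each locus in bp, cutsite included (>= read_length).
    per_site_mutation_rate:
        Jukes-Cantor substitution rate, substitutions/site/unit time.  The
        default 4e-3 yields, on a 12-48 taxon Yule tree of unit birth rate,
        ~10-20% locus dropout per sample and a handful of variable sites
        per 100 bp window - the regime in which missing-data thresholds
        matter.
    cutsite:
        Recognition motif at the 5' end of every locus; a substitution in
        these bases on a sample's root-to-leaf path drops the locus for
        that sample.  The remnant (``cutsite[1:]``) is what reads show
        between barcode and payload.
    coverage_law:
        (low, high) bounds of the log-uniform distribution of per-sample
        mean depth.  Equal bounds give every present cell exactly that
        (rounded) depth; otherwise per-cell depths are Poisson around the
        sample mean.
    seq_error_rate:
        Per-base sequencing error probability.
    read_length:
        Read length in bp (reads are truncated/padded to this).
    seed:
        RNG seed; a fixed seed makes every output byte-identical.
    """

    n_taxa: int = 48
    birth_rate: float = 1.0
    n_loci: int = 1000
    locus_length: int = 120
    per_site_mutation_rate: float = 4e-3
    cutsite: str = "GAATTC"
    coverage_law: tuple[float, float] = (1.0, 100.0)
    seq_error_rate: float = 0.001
    read_length: int = 100
    seed: int = 0

    @property
    def remnant(self) -> str:
        return self.cutsite[1:]

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.locus_length < self.read_length:
            raise ValueError("locus_length must be >= read_length")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        for name in ("per_site_mutation_rate", "seq_error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        low, high = self.coverage_law
        if not (0 < low <= high):
            raise ValueError("coverage_law bounds must satisfy 0 < low <= high")
        if not set(self.cutsite) <= set(_ALPHABET):
            raise ValueError("cutsite must be over ACGT")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    def to_file(self, path) -> None:
        """Write as a flat key<TAB>value file."""
        with open(path, "w") as fh:
            for field in dataclasses.fields(self):
                value = getattr(self, field.name)
                if field.name == "coverage_law":
                    value = f"{value[0]},{value[1]}"
                fh.write(f"{field.name}\t{value}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                key, value = line.rstrip("\n").split("\t", 1)
                raw[key] = value
        kwargs: dict = {}
        for field in dataclasses.fields(cls):
            if field.name not in raw:
                continue
            value = raw[field.name]
            if field.name == "coverage_law":
                low, high = value.split(",")
                kwargs[field.name] = (float(low), float(high))
            elif field.name in ("n_taxa", "n_loci", "locus_length", "read_length", "seed"):
                kwargs[field.name] = int(value)
            elif field.name == "cutsite":
                kwargs[field.name] = value
            else:
                kwargs[field.name] = float(value)
        return cls(**kwargs)


@dataclass
class TruthSet:
    """The simulated ground truth downstream stages are judged against."""

    species_tree: dendropy.Tree
    sample_ids: list[str]
    locus_ids: list[str]
    locus_presence: pd.DataFrame  # bool, samples x loci
    alignments: np.ndarray  # uint8 codes, (n_samples, n_loci, locus_length)
    config: SimulationConfig

    def true_alignment(self, locus: int | str) -> dict[str, str]:
        """Per-sample sequence of one locus, restricted to present samples."""
        j = self.locus_ids.index(locus) if isinstance(locus, str) else locus
        out = {}
        for i, sid in enumerate(self.sample_ids):
            if self.locus_presence.iloc[i, j]:
                out[sid] = decode_seq(self.alignments[i, j])
        return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_ALPHABET[c] for c in codes)


def simulate_species_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Simulate a rooted, binary, ultrametric Yule tree with labelled leaves.

    Forward simulation: waiting times between speciation events are
    exponential with rate (birth_rate x current lineage count); after the
    n-th lineage appears the process runs for one further exponential
    waiting time, so terminal branches have positive length.  Leaves are
    labelled S01..Sn in order of appearance.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_times = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < cfg.n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (cfg.birth_rate * k))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        if parent is not root:  # the root edge carries no length
            parent.edge.length = t - birth_times[parent]
        for _ in range(2):
            child = parent.new_child()
            birth_times[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (cfg.birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.edge.length = t - birth_times[leaf]
        leaf.taxon = taxa.new_taxon(label=f"S{i + 1:02d}")
    tree.is_rooted = True
    return tree


def simulate_loci(tree: dendropy.Tree, cfg: SimulationConfig) -> TruthSet:
    """Evolve loci down the tree under Jukes-Cantor with cutsite dropout.

    Each locus starts as a random ancestral sequence whose first bases are
    the cutsite.  Substitution events per site per branch are Poisson with
    mean rate x branch length; each event replaces the base with one of the
    other three uniformly (the event-level description of Jukes-Cantor).  A
    sample's locus copy is absent iff >= 1 event hit a cutsite position
    anywhere on the root-to-leaf path, matching the dropout probability
    1 - exp(-mu x |cutsite| x path length).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_loci, length = cfg.n_loci, cfg.locus_length
    csite = np.array([_ALPHABET.index(b) for b in cfg.cutsite], dtype=np.uint8)
    ancestral = rng.integers(0, 4, size=(n_loci, length), dtype=np.uint8)
    ancestral[:, : len(csite)] = csite

    leaves: list[dendropy.Node] = []
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): ancestral}
    hits: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_loci, dtype=bool)}
    mu = cfg.per_site_mutation_rate
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        parent_hit = hits[id(node.parent_node)]
        blen = node.edge.length or 0.0
        seq = parent_seq.copy()
        hit = parent_hit.copy()
        if mu > 0 and blen > 0:
            events = rng.poisson(mu * blen, size=(n_loci, length))
            hit |= events[:, : len(csite)].any(axis=1)
            pending = events.copy()
            while True:
                rows, cols = np.nonzero(pending)
                if rows.size == 0:
                    break
                # one Jukes-Cantor jump: replace with a uniformly random
                # *different* base
                shift = rng.integers(1, 4, size=rows.size).astype(np.uint8)
                seq[rows, cols] = (seq[rows, cols] + shift) % 4
                pending[rows, cols] -= 1
        seqs[id(node)] = seq
        hits[id(node)] = hit
        if node.is_leaf():
            leaves.append(node)
    sample_ids = [leaf.taxon.label for leaf in leaves]
    order = np.argsort(sample_ids)
    leaves = [leaves[i] for i in order]
    sample_ids = [sample_ids[i] for i in order]
    alignments = np.stack([seqs[id(leaf)] for leaf in leaves])
    presence = np.stack([~hits[id(leaf)] for leaf in leaves])
    locus_ids = [f"L{j + 1:04d}" for j in range(n_loci)]
    return TruthSet(
        species_tree=tree,
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        locus_presence=pd.DataFrame(presence, index=sample_ids, columns=locus_ids),
        alignments=alignments,
        config=cfg,
    )


def generate_reads(
    truth: TruthSet,
    barcode_map: dict[str, str],
    cfg: SimulationConfig | None = None,
    fastq_path=None,
    bad_window_fraction: float = 0.0,
    bad_window_width: int = 15,
    bad_window_phred: int = 2,
) -> tuple[list, dict[str, int]]:
    """Emit barcoded single-end reads for every present (sample, locus) cell.

    Each read is ``barcode + cutsite remnant + locus payload`` truncated or
    padded (with N) to the configured read length, where the payload is the
    locus sequence after the cutsite.  Per-sample mean depth is drawn from
    the log-uniform coverage law (heterogeneous library sizes are the
    study's dominant nuisance); per-cell depths are Poisson around that
    mean unless the law is degenerate, in which case depth is exactly the
    constant.  Sequencing errors are uniform base flips.  Base qualities
    are constant phred 38 except for an optional injected low-quality
    window (``bad_window_fraction`` of reads) used to exercise the QC
    filter deterministically.

    Returns ``(reads, per_sample_counts)`` where reads is a list of
    ``(read_id, sequence, quality_string)``; if ``fastq_path`` is given the
    reads are also written there (phred+33).
    """
    cfg = cfg or truth.config
    missing = [sid for sid in truth.sample_ids if sid not in barcode_map]
    if missing:
        raise ValueError(f"no barcode assigned for samples: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    low, high = cfg.coverage_law
    n_samples = len(truth.sample_ids)
    if low == high:
        mean_depth = np.full(n_samples, float(low))
        constant = True
    else:
        mean_depth = np.exp(rng.uniform(np.log(low), np.log(high), size=n_samples))
        constant = False
    reads: list[tuple[str, str, str]] = []
    counts: dict[str, int] = {}
    remnant = cfg.remnant
    cut_len = len(cfg.cutsite)
    base_qual = "G" * cfg.read_length  # phred 38 at +33
    for i, sid in enumerate(truth.sample_ids):
        barcode = barcode_map[sid]
        prefix = barcode + remnant
        n_sample_reads = 0
        present = np.nonzero(truth.locus_presence.iloc[i].to_numpy())[0]
        if constant:
            depths = np.full(present.size, int(round(low)))
        else:
            depths = rng.poisson(mean_depth[i], size=present.size)
        for j, depth in zip(present, depths):
            if depth <= 0:
                continue
            payload = decode_seq(truth.alignments[i, j, cut_len:])
            template = (prefix + payload)[: cfg.read_length]
            if len(template) < cfg.read_length:
                template = template + "N" * (cfg.read_length - len(template))
            for copy in range(depth):
                seq = template
                if cfg.seq_error_rate > 0:
                    n_err = rng.binomial(cfg.read_length, cfg.seq_error_rate)
                    if n_err:
                        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                        pos = rng.choice(cfg.read_length, size=n_err, replace=False)
                        for p in pos:
                            cur = chr(arr[p])
                            options = [b for b in _ALPHABET if b != cur]
                            arr[p] = ord(options[int(rng.integers(3))])
                        seq = arr.tobytes().decode()
                qual = base_qual
                if bad_window_fraction > 0 and rng.random() < bad_window_fraction:
                    start = int(rng.integers(0, cfg.read_length - bad_window_width + 1))
                    bad = chr(bad_window_phred + _PHRED_OFFSET) * bad_window_width
                    qual = qual[:start] + bad + qual[start + bad_window_width :]
                read_id = f"{sid}:{truth.locus_ids[j]}:{copy}"
                reads.append((read_id, seq, qual))
                n_sample_reads += 1
        counts[sid] = n_sample_reads
    if fastq_path is not None:
        # plain text writer: the format is four fixed lines per record and
        # Bio.SeqIO record construction is the bottleneck at ~1e6 reads
        with open(fastq_path, "w") as fh:
            for read_id, seq, qual in reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
    return reads, counts


def write_truth(truth: TruthSet, tree_path, presence_path) -> None:
    """Write the true tree (newick) and presence matrix (tab-delimited 0/1)."""
    truth.species_tree.write(
        path=str(tree_path), schema="newick", suppress_rooting=True
    )
    truth.locus_presence.astype(int).to_csv(presence_path, sep="\t")
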