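"""Distance-tree estimation, bootstrap node support, and grid summaries.

The inference engine here is deliberately desk-scale: neighbor joining on
pairwise-deletion mismatch distances, with support from column resampling,
a 50% majority-rule consensus, and the "proportion of nodes with bootstrap
support >= 70%" summary statistic.  This preserves the analysis surface
that actually discriminates between assembly strategies (node support as a
function of SNP count and missing-data threshold) while remaining runnable
in seconds; the exported phylip matrices stay consumable by external
maximum-likelihood programs for full-scale runs.

Missing data are handled by pairwise deletion: the distance between two
samples is the mismatch proportion over sites where both have calls.  In
very sparse matrices (90% missing) two samples can share no sites at all;
such pairs get the maximum observed distance and a warning, which keeps
neighbor joining defined without inventing signal.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .supermatrix import MISSING, SNPMatrix

__all__ = [
    "SupportedTree",
    "RunResult",
    "snp_distance_matrix",
    "estimate_tree",
    "bootstrap_support",
    "tally_support",
    "clade_recovery",
    "support_vs_snps",
]

SUPPORT_CUTOFF = 70.0


@dataclass
class SupportedTree:
    """An outgroup-rooted consensus topology with per-clade bootstrap support.

    ``clade_support`` maps each internal (non-root) clade - a frozenset of
    leaf labels - to the percentage of bootstrap replicates containing it.
    """

    tree: dendropy.Tree
    clade_support: dict[frozenset, float]
    outgroup: str

    @property
    def n_internal(self) -> int:
        return len(self.clade_support)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


@dataclass
class RunResult:
    """Per-(run, threshold) summary row of the experiment grid."""

    run_id: str
    threshold_p: float
    n_snps: int
    n_internal_nodes: int
    n_supported_nodes: int
    prop_supported: float
    extra: dict = field(default_factory=dict)


def _encode_sites(matrix: SNPMatrix) -> np.ndarray:
    codes = np.full(matrix.sites.shape, 255, dtype=np.uint8)
    for value, base in enumerate("ACGT"):
        codes[matrix.sites == base] = value
    codes[matrix.sites == MISSING] = 255
    return codes


def snp_distance_matrix(matrix: SNPMatrix) -> np.ndarray:
    """Pairwise-deletion mismatch proportions between samples.

    Pairs sharing zero called sites receive the maximum observed distance
    (or 1.0 if every pair is empty), with a warning.
    """
    codes = _encode_sites(matrix)
    valid = codes != 255
    n = codes.shape[0]
    dist = np.zeros((n, n))
    empty_pairs = []
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        mism = (codes[i] != codes[i + 1 :]) & both
        shared = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(shared > 0, mism.sum(axis=1) / np.maximum(shared, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        for off in np.nonzero(shared == 0)[0]:
            empty_pairs.append((matrix.sample_ids[i], matrix.sample_ids[i + 1 + off]))
    if empty_pairs:
        finite = dist[np.isfinite(dist)]
        fallback = float(finite.max()) if finite.size else 1.0
        dist = np.where(np.isnan(dist), fallback, dist)
        warnings.warn(
            f"{len(empty_pairs)} sample pair(s) share no called sites; "
            f"assigned the maximum observed distance {fallback:.3f} "
            f"(first such pair: {empty_pairs[0]})",
            stacklevel=2,
        )
    return dist


def _root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon and node.taxon.label == outgroup:
            leaf = node
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not found among tree leaves")
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def estimate_tree(matrix: SNPMatrix, outgroup: str) -> dendropy.Tree:
    """Neighbor-joining tree on the SNP matrix, rooted on the outgroup.

    Negative NJ branch lengths are clamped to zero.  Requires >= 3 samples
    and >= 1 site; the result is independent of input row order.
    """
    if outgroup not in matrix.sample_ids:
        raise ValueError(f"outgroup {outgroup!r} not in matrix samples")
    if len(matrix.sample_ids) < 3:
        raise ValueError("tree estimation requires >= 3 samples")
    if matrix.n_sites < 1:
        raise ValueError("tree estimation requires >= 1 site")
    # sort rows so the estimate cannot depend on the caller's row order
    order = np.argsort(matrix.sample_ids)
    ids = [matrix.sample_ids[i] for i in order]
    dist = snp_distance_matrix(
        SNPMatrix([matrix.sample_ids[i] for i in order], matrix.sites[order])
    )
    njt = nj(DistanceMatrix(dist, ids=ids))
    buf = io.StringIO()
    njt.write(buf)
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return _root_at_outgroup(tree, outgroup)


def _internal_clades(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf-label sets of internal non-root nodes of a rooted tree."""
    clades = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
    return clades


def bootstrap_support(
    matrix: SNPMatrix,
    outgroup: str,
    B: int = 100,
    seed: int = 0,
) -> SupportedTree:
    """Column-resampling bootstrap with 50% majority-rule consensus.

    ``B`` replicate matrices are drawn by resampling columns with
    replacement (replicate ``i`` uses seed ``seed + i``); a neighbor-joining
    tree is estimated per replicate and rooted on the outgroup.  The
    consensus keeps every clade present in >= 50% of replicates (clades at
    exactly 50% are admitted most-frequent-first, skipping incompatible
    ones); support is the percentage of replicates containing the clade.
    """
    counts: dict[frozenset, int] = {}
    n_sites = matrix.n_sites
    for b in range(B):
        rng = np.random.default_rng(seed + b)
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = SNPMatrix(matrix.sample_ids, matrix.sites[:, cols])
        tree = estimate_tree(rep, outgroup)
        for clade in _internal_clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    support = {clade: 100.0 * c / B for clade, c in counts.items()}
    threshold = 50.0
    admitted: list[frozenset] = []
    for clade in sorted(
        support,
        key=lambda c: (-support[c], -len(c), tuple(sorted(c))),
    ):
        if support[clade] < threshold:
            continue
        if all(
            clade <= other or other <= clade or not (clade & other)
            for other in admitted
        ):
            admitted.append(clade)
    tree = _build_clade_tree(
        sorted(matrix.sample_ids), admitted, support, outgroup
    )
    return SupportedTree(
        tree=tree,
        clade_support={c: support[c] for c in admitted},
        outgroup=outgroup,
    )


def _build_clade_tree(
    labels: list[str],
    clades: list[frozenset],
    support: dict[frozenset, float],
    outgroup: str,
) -> dendropy.Tree:
    """Assemble a rooted tree from a compatible set of clades."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root_set = frozenset(labels)
    nodes: dict[frozenset, dendropy.Node] = {root_set: tree.seed_node}
    for clade in sorted(clades, key=len, reverse=True):
        if clade == root_set:
            continue
        parent_set = min(
            (s for s in nodes if clade < s), key=len
        )
        node = nodes[parent_set].new_child()
        node.label = f"{support[clade]:g}"
        nodes[clade] = node
    for label in labels:
        singleton = frozenset([label])
        parent_set = min((s for s in nodes if singleton <= s and len(s) > 1), key=len)
        leaf = nodes[parent_set].new_child()
        leaf.taxon = taxa.get_taxon(label)
    return tree


def tally_support(
    supported: SupportedTree, cutoff: float = SUPPORT_CUTOFF
) -> tuple[int, int, float]:
    """(n_internal, n_supported, proportion) at a bootstrap cutoff.

    Internal non-root nodes of the outgroup-rooted consensus are counted;
    a node is supported when its bootstrap percentage >= cutoff.
    """
    n_internal = supported.n_internal
    n_supported = sum(1 for v in supported.clade_support.values() if v >= cutoff)
    prop = n_supported / n_internal if n_internal else 0.0
    return n_internal, n_supported, prop


def _unrooted_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical non-trivial bipartitions of a tree, ignoring rooting.

    Each split is the side not containing the alphabetically first leaf,
    so rooted and unrooted representations of one topology agree.
    """
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = labels[0]
    full = frozenset(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            splits.add(side)
    return splits


def clade_recovery(estimated: dendropy.Tree, truth: dendropy.Tree) -> float:
    """Fraction of the true tree's internal bipartitions found in the estimate.

    Compared as unrooted splits; 1.0 iff the topologies are identical, 0.0
    for a star estimate.
    """
    est_labels = sorted(l.taxon.label for l in estimated.leaf_node_iter())
    true_labels = sorted(l.taxon.label for l in truth.leaf_node_iter())
    if est_labels != true_labels:
        raise ValueError("leaf sets differ between estimated and true trees")
    true_splits = _unrooted_splits(truth)
    if not true_splits:
        return 1.0
    est_splits = _unrooted_splits(estimated)
    return len(true_splits & est_splits) / len(true_splits)


def support_vs_snps(
    results: list[RunResult], plot_path=None
) -> pd.DataFrame:
    """Table of supported-node counts against SNP counts, sorted by SNPs.

    No smoothing is applied; ties keep their input order (stable sort).
    Optionally writes a scatter/line plot.
    """
    rows = [
        {
            "run_id": r.run_id,
            "threshold_p": r.threshold_p,
            "n_snps": r.n_snps,
            "n_internal_nodes": r.n_internal_nodes,
            "n_supported_nodes": r.n_supported_nodes,
            "prop_supported": r.prop_supported,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values("n_snps", kind="stable").reset_index(drop=True)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for run_id, grp in table.groupby("run_id"):
            ax.plot(grp["n_snps"], grp["n_supported_nodes"], marker="o", label=run_id)
        ax.set_xlabel("number of SNPs")
        ax.set_ylabel("nodes with bootstrap support >= 70%")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table
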