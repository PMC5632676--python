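"""Missing-data-threshold whitelists and informative-site phylip matrices.

A missing-data threshold ``p`` is the maximum fraction of samples allowed
to lack data at a locus: a locus passes when at least ``ceil((1-p) x
n_samples)`` samples have data (so a "60% threshold" keeps loci covered by
at least 40% of samples - ceil semantics pin the worked 60/40 reading).
Raising ``p`` therefore only ever adds loci, which is what makes SNP counts
monotone in the threshold.

Oversized whitelists can be partitioned into contiguous near-equal parts,
exported part by part, and the resulting phylip files merged column-wise -
a faithful reimplementation of the split-and-recombine trick used to get
very large matrices through memory-bound export tools; the round trip is
lossless by construction.

"Informative" follows the source pipeline's usage: a site is exported when
>= 2 distinct non-missing bases occur across samples (variable, not
necessarily parsimony-informative); ``informative="parsimony"`` switches to
the strict reading (>= 2 states each in >= 2 samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Whitelist",
    "SNPMatrix",
    "make_whitelist",
    "partition_whitelist",
    "calls_from_catalog",
    "build_snp_matrix",
    "export_phylip",
    "merge_phylip",
    "parse_phylip",
]

MISSING = "N"


@dataclass
class Whitelist:
    """Loci passing a missing-data threshold, ordered by locus id."""

    threshold_p: float
    locus_ids: list[str]

    def __len__(self) -> int:
        return len(self.locus_ids)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for lid in self.locus_ids:
                fh.write(f"{lid}\n")

    @classmethod
    def read(cls, path, threshold_p: float = float("nan")) -> "Whitelist":
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(threshold_p, ids)


@dataclass
class SNPMatrix:
    """Samples x variable-sites base calls with explicit missing state."""

    sample_ids: list[str]
    sites: np.ndarray  # unicode '<U1', shape (n_samples, n_sites)
    site_locus: list[str] = field(default_factory=list)  # provenance per column

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def to_phylip(self) -> str:
        return _phylip_text(self.sample_ids, self.sites)


def make_whitelist(occupancy: pd.DataFrame, p: float) -> Whitelist:
    """Loci where at least ceil((1-p) x n_samples) samples have data."""
    if not 0 <= p < 1:
        raise ValueError(f"missing-data threshold p={p} must be in [0, 1)")
    n_samples = occupancy.shape[0]
    need = math.ceil((1.0 - p) * n_samples)
    counts = occupancy.to_numpy().sum(axis=0)
    loci = [lid for lid, c in zip(occupancy.columns, counts) if c >= need]
    return Whitelist(p, sorted(loci))


def partition_whitelist(wl: Whitelist, k: int = 10) -> list[Whitelist]:
    """Split into k contiguous, disjoint parts whose sizes differ by <= 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(wl.locus_ids)
    base, extra = divmod(n, k)
    parts = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        parts.append(Whitelist(wl.threshold_p, wl.locus_ids[start : start + size]))
        start += size
    return parts


def calls_from_catalog(catalog, sample_ids: list[str]) -> dict[str, dict[str, str]]:
    """Per-locus per-sample sequences from a catalog's matched sample loci.

    ``{catalog_locus_id: {sample_id: consensus}}``; a sample absent from a
    locus is simply missing from the inner dict.
    """
    calls: dict[str, dict[str, str]] = {}
    for locus in catalog.loci:
        lid = f"C{locus.catalog_id:05d}"
        calls[lid] = {
            sid: sl.consensus for sid, sl in locus.matched.items() if sid in set(sample_ids)
        }
    return calls


def build_snp_matrix(
    calls: dict[str, dict[str, str]],
    whitelist: Whitelist,
    sample_order: list[str],
    informative: str = "variable",
) -> SNPMatrix:
    """Concatenate each whitelisted locus's informative sites.

    A column is kept when >= 2 distinct non-missing bases occur across
    samples (``informative="variable"``), or when >= 2 states are each
    carried by >= 2 samples (``informative="parsimony"``).
    """
    if informative not in ("variable", "parsimony"):
        raise ValueError("informative must be 'variable' or 'parsimony'")
    columns: list[np.ndarray] = []
    provenance: list[str] = []
    for lid in whitelist.locus_ids:
        locus_calls = calls.get(lid)
        if not locus_calls:
            continue
        length = len(next(iter(locus_calls.values())))
        block = np.full((len(sample_order), length), MISSING, dtype="<U1")
        for i, sid in enumerate(sample_order):
            seq = locus_calls.get(sid)
            if seq is not None:
                if len(seq) != length:
                    raise ValueError(f"locus {lid}: unequal sequence lengths")
                block[i] = list(seq)
        for j in range(length):
            col = block[:, j]
            observed = col[col != MISSING]
            states, state_counts = np.unique(observed, return_counts=True)
            if informative == "variable":
                keep = states.size >= 2
            else:
                keep = (state_counts >= 2).sum() >= 2
            if keep:
                columns.append(col.copy())
                provenance.append(lid)
    if columns:
        sites = np.stack(columns, axis=1)
    else:
        sites = np.zeros((len(sample_order), 0), dtype="<U1")
    return SNPMatrix(list(sample_order), sites, provenance)


def _phylip_text(sample_ids: list[str], sites: np.ndarray) -> str:
    lines = [f"{len(sample_ids)} {sites.shape[1]}"]
    for i, sid in enumerate(sample_ids):
        if len(sid) > 50:
            raise ValueError(f"sample name {sid!r} exceeds 50 characters")
        lines.append(f"{sid} {''.join(sites[i])}")
    return "\n".join(lines) + "\n"


def export_phylip(
    calls: dict[str, dict[str, str]],
    whitelist: Whitelist,
    sample_order: list[str],
    informative: str = "variable",
) -> str:
    """Relaxed phylip text of the informative sites of a whitelist (part).

    Emits a header of 0 columns (with a warning) when nothing is variable.
    """
    matrix = build_snp_matrix(calls, whitelist, sample_order, informative)
    if matrix.n_sites == 0:
        import warnings

        warnings.warn(
            f"whitelist at p={whitelist.threshold_p} exported zero informative sites",
            stacklevel=2,
        )
    return matrix.to_phylip()


def parse_phylip(text: str) -> tuple[list[str], np.ndarray]:
    """Parse relaxed phylip (name space-separated from sequence)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    n_samples, n_sites = int(header[0]), int(header[1])
    if len(lines) - 1 != n_samples:
        raise ValueError(
            f"phylip header claims {n_samples} samples, found {len(lines) - 1}"
        )
    names, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        name = parts[0]
        seq = parts[1].replace(" ", "") if len(parts) > 1 else ""
        if len(seq) != n_sites:
            raise ValueError(
                f"phylip row {name!r} has {len(seq)} sites, header says {n_sites}"
            )
        names.append(name)
        rows.append(list(seq))
    sites = (
        np.array(rows, dtype="<U1") if rows else np.zeros((0, n_sites), dtype="<U1")
    )
    return names, sites


def merge_phylip(parts: list[str]) -> str:
    """Column-wise concatenation of phylip parts sharing one sample order."""
    if not parts:
        raise ValueError("nothing to merge")
    ref_names, blocks = None, []
    for idx, text in enumerate(parts):
        names, sites = parse_phylip(text)
        if ref_names is None:
            ref_names = names
        elif names != ref_names:
            raise ValueError(
                f"part {idx}: sample set or order differs from part 0 "
                f"({names[:3]}... vs {ref_names[:3]}...)"
            )
        blocks.append(sites)
    merged = np.concatenate(blocks, axis=1)
    return _phylip_text(ref_names, merged)
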