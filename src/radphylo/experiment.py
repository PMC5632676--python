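"""Factorial experiment driver: assembly-parameter runs x missing-data thresholds.

The grid reproduces the study design this package reimplements: 18 de novo
assembly runs that vary one of the four parameters at a time around the
default (m=2, M=2, max_locus_stacks=3, n=3), plus one reference-based run,
each evaluated at nine missing-data thresholds - 171 datasets in all.  The
thresholds are the grid's printed values (10, 21, 29, 40, 50, 60, 71, 79,
90 percent), not round deciles.

``run_pipeline`` executes one grid cell end to end - demultiplex, assemble
(de novo or reference-placed), catalog, match, whitelist, phylip export,
bootstrap trees - writing artifacts under a ``R{run}.m{percent}`` directory
per cell and returning one RunResult per threshold.  Whitelists at
thresholds >= 70% are exported in 10 partitions and the parts merged
column-wise, mirroring the memory-bound export workaround of the original
pipeline (the round trip is lossless, so this changes nothing downstream).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .assembly import (
    AssemblyParams,
    assemble_sample,
    build_catalog,
    map_to_reference,
    match_to_catalog,
)
from .demux import demultiplex
from .supermatrix import (
    SNPMatrix,
    Whitelist,
    build_snp_matrix,
    calls_from_catalog,
    make_whitelist,
    merge_phylip,
    parse_phylip,
    partition_whitelist,
)
from .trees import RunResult, bootstrap_support, support_vs_snps, tally_support

__all__ = [
    "THRESHOLDS",
    "RunGrid",
    "build_run_grid",
    "cell_name",
    "run_pipeline",
    "run_grid",
]

logger = logging.getLogger("radphylo.experiment")

#: The nine missing-data thresholds of the study grid (fractions).
THRESHOLDS: tuple[float, ...] = (0.10, 0.21, 0.29, 0.40, 0.50, 0.60, 0.71, 0.79, 0.90)

#: De novo runs 1-18: (m, M, max_locus_stacks, n), one knob varied at a time.
_DENOVO_ROWS: tuple[tuple[int, int, int, int], ...] = (
    (2, 2, 3, 3),
    (4, 2, 3, 3),
    (6, 2, 3, 3),
    (2, 4, 3, 3),
    (2, 6, 3, 3),
    (2, 8, 3, 3),
    (2, 2, 2, 3),
    (2, 2, 4, 3),
    (2, 2, 6, 3),
    (2, 2, 3, 0),
    (2, 2, 3, 2),
    (2, 2, 3, 4),
    (2, 2, 3, 6),
    (2, 2, 3, 8),
    (2, 2, 3, 10),
    (2, 2, 3, 12),
    (2, 2, 3, 14),
    (2, 2, 3, 16),
)


@dataclass
class RunGrid:
    """18 de novo parameter rows, one reference row, nine thresholds."""

    denovo_runs: dict[str, AssemblyParams]
    reference_run: dict[str, AssemblyParams]
    thresholds: tuple[float, ...]

    @property
    def n_datasets(self) -> int:
        return (len(self.denovo_runs) + len(self.reference_run)) * len(self.thresholds)

    def cells(self):
        """Yield (run_id, params, is_reference, threshold) for every dataset."""
        for run_id, params in self.denovo_runs.items():
            for p in self.thresholds:
                yield run_id, params, False, p
        for run_id, params in self.reference_run.items():
            for p in self.thresholds:
                yield run_id, params, True, p


def build_run_grid() -> RunGrid:
    """The exact factorial design: runs R1-R18 plus reference run RR."""
    denovo = {
        f"R{i + 1}": AssemblyParams(m=m, M=M, max_locus_stacks=mls, n=n)
        for i, (m, M, mls, n) in enumerate(_DENOVO_ROWS)
    }
    # reference mode fixes stack depth at 2 and has no M/mls analogue; the
    # catalog mismatch allowance stays at the default n=3
    reference = {"RR": AssemblyParams(m=2, M=0, max_locus_stacks=1, n=3)}
    return RunGrid(denovo, reference, THRESHOLDS)


def cell_name(run_id: str, threshold_p: float) -> str:
    """Directory name for a grid cell, e.g. R1.m90."""
    return f"{run_id}.m{round(threshold_p * 100):02d}"


def _matrix_for_threshold(
    calls: dict[str, dict[str, str]],
    occupancy: pd.DataFrame,
    p: float,
    sample_order: list[str],
    informative: str,
    n_partitions: int = 10,
) -> tuple[Whitelist, SNPMatrix]:
    """Whitelist then SNP matrix, via partition+merge at high thresholds."""
    wl = make_whitelist(occupancy, p)
    if p >= 0.70 and len(wl) >= n_partitions:
        parts = partition_whitelist(wl, n_partitions)
        texts = [
            build_snp_matrix(calls, part, sample_order, informative).to_phylip()
            for part in parts
        ]
        names, sites = parse_phylip(merge_phylip(texts))
        matrix = SNPMatrix(names, sites)
    else:
        matrix = build_snp_matrix(calls, wl, sample_order, informative)
    return wl, matrix


def run_pipeline(
    run_id: str,
    params: AssemblyParams,
    reads,
    barcode_map: dict[str, str],
    outgroup: str,
    thresholds: tuple[float, ...] = THRESHOLDS,
    reference_fasta=None,
    bootstrap_B: int = 100,
    seed: int = 0,
    out_dir=None,
    informative: str = "variable",
    remnant: str = "AATTC",
) -> list[RunResult]:
    """Execute one assembly run across all missing-data thresholds.

    Stage order: demultiplex/QC -> within-sample assembly (de novo stacks,
    or reference placement when ``reference_fasta`` is given) -> catalog ->
    match -> per-threshold whitelist -> informative-site matrix ->
    bootstrap trees -> support tally.  Cells that end up with no usable
    sites (or < 3 samples) produce a RunResult with zero SNPs and a reason
    in ``extra`` instead of raising.

    With a fixed seed the full result list is deterministic.
    """
    t0 = time.perf_counter()
    per_sample, report = demultiplex(reads, barcode_map, remnant=remnant)
    logger.info(
        "%s: demultiplexed %d reads (%d assigned, %d no-barcode, %d low-quality)",
        run_id,
        report.total,
        report.n_assigned,
        report.discarded_no_barcode,
        report.discarded_low_quality,
    )
    sample_loci = {}
    for sid in sorted(per_sample):
        if not per_sample[sid]:
            sample_loci[sid] = []
        elif reference_fasta is not None:
            loci, rate = map_to_reference(per_sample[sid], reference_fasta, sample_id=sid)
            logger.info("%s: %s aligned at rate %.2f", run_id, sid, rate)
            sample_loci[sid] = loci
        else:
            sample_loci[sid] = assemble_sample(per_sample[sid], params, sample_id=sid)
    catalog = build_catalog(sample_loci, params.n)
    occupancy = match_to_catalog(sample_loci, catalog, params.n)
    sample_order = sorted(per_sample)
    calls = calls_from_catalog(catalog, sample_order)
    logger.info(
        "%s: %d catalog loci from %d samples (%.1fs)",
        run_id,
        len(catalog),
        len(sample_order),
        time.perf_counter() - t0,
    )
    results: list[RunResult] = []
    for p in thresholds:
        t1 = time.perf_counter()
        wl, matrix = _matrix_for_threshold(calls, occupancy, p, sample_order, informative)
        cell_dir = None
        if out_dir is not None:
            cell_dir = Path(out_dir) / cell_name(run_id, p)
            cell_dir.mkdir(parents=True, exist_ok=True)
            wl.write(cell_dir / "whitelist.txt")
            (cell_dir / "matrix.phy").write_text(matrix.to_phylip())
        if matrix.n_sites == 0 or len(sample_order) < 3:
            reason = "no informative sites" if matrix.n_sites == 0 else "< 3 samples"
            results.append(
                RunResult(run_id, p, matrix.n_sites, 0, 0, 0.0, extra={"reason": reason})
            )
            logger.warning("%s %s: %s", run_id, cell_name(run_id, p), reason)
            continue
        supported = bootstrap_support(matrix, outgroup, B=bootstrap_B, seed=seed)
        n_internal, n_supported, prop = tally_support(supported)
        if cell_dir is not None:
            (cell_dir / "consensus.nwk").write_text(supported.newick())
        results.append(
            RunResult(
                run_id,
                p,
                matrix.n_sites,
                n_internal,
                n_supported,
                prop,
                extra={"n_whitelist_loci": len(wl)},
            )
        )
        logger.info(
            "%s %s: %d SNPs, %d/%d supported nodes (%.1fs)",
            run_id,
            cell_name(run_id, p),
            matrix.n_sites,
            n_supported,
            n_internal,
            time.perf_counter() - t1,
        )
    return results


def run_grid(
    reads,
    barcode_map: dict[str, str],
    outgroup: str,
    grid: RunGrid | None = None,
    reference_fasta=None,
    bootstrap_B: int = 100,
    seed: int = 0,
    out_dir=None,
    table_path=None,
) -> pd.DataFrame:
    """Run every grid cell and return the master results table.

    The reference run is skipped (with a log message) when no reference
    FASTA is supplied.  A failure in one run is recorded and does not stop
    the others.
    """
    grid = grid or build_run_grid()
    all_results: list[RunResult] = []
    for run_id, params in grid.denovo_runs.items():
        try:
            all_results.extend(
                run_pipeline(
                    run_id,
                    params,
                    reads,
                    barcode_map,
                    outgroup,
                    thresholds=grid.thresholds,
                    bootstrap_B=bootstrap_B,
                    seed=seed,
                    out_dir=out_dir,
                )
            )
        except Exception:
            logger.exception("run %s failed; continuing with remaining runs", run_id)
    if reference_fasta is not None:
        for run_id, params in grid.reference_run.items():
            try:
                all_results.extend(
                    run_pipeline(
                        run_id,
                        params,
                        reads,
                        barcode_map,
                        outgroup,
                        thresholds=grid.thresholds,
                        reference_fasta=reference_fasta,
                        bootstrap_B=bootstrap_B,
                        seed=seed,
                        out_dir=out_dir,
                    )
                )
            except Exception:
                logger.exception("reference run %s failed", run_id)
    else:
        logger.info("no reference FASTA supplied; reference run skipped")
    table = support_vs_snps(all_results)
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)
    return table
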