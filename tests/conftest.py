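"""Shared fixtures: a small error-free synthetic world and a barcode panel."""

from __future__ import annotations

import numpy as np
import pytest

import radphylo as rp

_BASES = "ACGT"


def make_panel(sample_ids, lengths=(7, 8, 9, 10)) -> dict[str, str]:
    """Distinct variable-length barcodes for up to 256 samples.

    The first four bases encode the sample index in base 4 (so no two
    barcodes share a 4-bp prefix); the tail pads to the requested length,
    cycling through the lengths tuple.
    """
    panel = {}
    for i, sid in enumerate(sorted(sample_ids)):
        head = _BASES[i % 4] + _BASES[(i // 4) % 4] + _BASES[(i // 16) % 4] + _BASES[(i // 64) % 4]
        length = lengths[i % len(lengths)]
        panel[sid] = (head + "TGCATGCTGG")[:length]
    return panel


def reads_to_records(reads) -> list[rp.ReadRecord]:
    return [
        rp.ReadRecord(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in reads
    ]


@pytest.fixture(scope="session")
def small_world():
    """12 taxa, 300 error-free loci, constant depth 2, mixed barcode lengths."""
    cfg = rp.SimulationConfig(
        n_taxa=12,
        n_loci=300,
        per_site_mutation_rate=4e-3,
        coverage_law=(2.0, 2.0),
        seq_error_rate=0.0,
        seed=11,
    )
    tree = rp.simulate_species_tree(cfg)
    truth = rp.simulate_loci(tree, cfg)
    panel = make_panel(truth.sample_ids)
    reads, counts = rp.generate_reads(truth, panel, cfg)
    return {
        "cfg": cfg,
        "tree": tree,
        "truth": truth,
        "panel": panel,
        "reads": reads,
        "counts": counts,
        "records": reads_to_records(reads),
    }


@pytest.fixture(scope="session")
def assembled_world(small_world):
    """The small world taken through demux -> assembly -> catalog once."""
    panel = small_world["panel"]
    per_sample, report = rp.demultiplex(small_world["records"], panel)
    params = rp.AssemblyParams(m=1, M=0, max_locus_stacks=3, n=3)
    sample_loci = {
        sid: rp.assemble_sample(per_sample[sid], params, sample_id=sid)
        for sid in sorted(per_sample)
    }
    catalog = rp.build_catalog(sample_loci, params.n)
    occupancy = rp.match_to_catalog(sample_loci, catalog, params.n)
    calls = rp.calls_from_catalog(catalog, sorted(per_sample))
    return {
        "per_sample": per_sample,
        "report": report,
        "params": params,
        "sample_loci": sample_loci,
        "catalog": catalog,
        "occupancy": occupancy,
        "calls": calls,
        "sample_order": sorted(per_sample),
    }


def manual_truth(tree_newick: str, presence, seqs: dict[str, list[str]], cfg):
    """Hand-built TruthSet: ``seqs`` maps sample -> list of per-locus strings."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    sample_ids = sorted(seqs)
    locus_ids = list(presence.columns)
    arr = np.zeros((len(sample_ids), len(locus_ids), cfg.locus_length), dtype=np.uint8)
    code = {b: i for i, b in enumerate("ACGT")}
    for i, sid in enumerate(sample_ids):
        for j, seq in enumerate(seqs[sid]):
            arr[i, j] = [code[b] for b in seq]
    return rp.TruthSet(tree, sample_ids, locus_ids, presence, arr, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20170830)
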