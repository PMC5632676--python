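"""Missing-data thresholds, phylip export, bootstrap trees, node support.

Runs one assembly at three thresholds, shows SNP counts rising with the
threshold, and summarises bootstrap node support of each consensus tree.
"""

import radphylo as rp
from radphylo.demux import ReadRecord
from radphylo.experiment import run_pipeline

cfg = rp.SimulationConfig(n_taxa=12, n_loci=400, per_site_mutation_rate=8e-3,
                          coverage_law=(1.0, 60.0), seq_error_rate=0.0, seed=9)
tree = rp.simulate_species_tree(cfg)
truth = rp.simulate_loci(tree, cfg)
panel = {sid: bc for sid, bc in zip(truth.sample_ids, [
    "GATTACA", "CATTAGA", "TGCCAAG", "AGGTCTC",
    "GATTACAT", "CCGGTATA", "TTACGGCA", "AAGCTGGT",
    "GATTACATT", "CGCATTAGG", "TGGACCATA", "ATCGGCTAA",
])}
reads, _ = rp.generate_reads(truth, panel, cfg)
records = [ReadRecord(r, s, [ord(c) - 33 for c in q]) for r, s, q in reads]

results = run_pipeline(
    "R1", rp.AssemblyParams(m=2, M=2, max_locus_stacks=3, n=3),
    records, panel, outgroup="S01",
    thresholds=(0.1, 0.5, 0.9), bootstrap_B=100, seed=1,
)
print("threshold  SNPs  supported/internal  proportion")
for r in results:
    print(f"  p={r.threshold_p:.1f}   {r.n_snps:5d}        "
          f"{r.n_supported_nodes}/{r.n_internal_nodes}          "
          f"{r.prop_supported:.2f}")
print("  -> higher thresholds admit sparser loci, multiplying SNPs; node")
print("     support (bootstrap >= 70%) typically rises with them")
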