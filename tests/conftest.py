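from types import SimpleNamespace

import pytest

from phasekit.io import RunConfig
from phasekit.preprocess import assign_rpm, filter_rrna, map_reads
from phasekit.phasing import call_phas_loci, scan_windows
from phasekit.annotate import classify_locus, merge_by_gene
from phasekit.simulate import SimConfig, make_library


def analyze(sim_cfg: SimConfig, run_24nt: bool = False) -> SimpleNamespace:
    """Run the core analysis (clean → map → phase → annotate) in memory."""
    sim = make_library(sim_cfg)
    cleaned = filter_rrna(sim.reads, sim.rrna_refs)
    assign_rpm(cleaned)
    rc = RunConfig()
    alignments = map_reads(cleaned, sim.genome, rc.max_hits)
    windows = scan_windows(alignments, sim.ref_lengths, rc)
    loci21 = call_phas_loci(windows, rc)
    loci24 = []
    if run_24nt:
        rc24 = rc.replace(register_len=24)
        loci24 = call_phas_loci(scan_windows(alignments, sim.ref_lengths, rc24), rc24)
    for loc in loci21 + loci24:
        classify_locus(loc, sim.models)
    loci21 = merge_by_gene(loci21)
    return SimpleNamespace(
        sim=sim, cleaned=cleaned, alignments=alignments, windows=windows,
        loci21=loci21, loci24=loci24, rc=rc,
    )


@pytest.fixture(scope="session")
def default_analysis() -> SimpleNamespace:
    """The default study conditions: 200-kb genome, 30 planted 21-nt loci in
    all four genomic classes plus two 24-nt loci, fidelity 0.9, seed 42."""
    return analyze(SimConfig(), run_24nt=True)


@pytest.fixture(scope="session")
def noisefree_analysis() -> SimpleNamespace:
    """A compact noise-free dataset (fidelity 1.0, no background, no rRNA)
    with a gene-family host among the exonic loci."""
    cfg = SimConfig(
        genome_len=60_000, n_genes=6, n_phas_exonic=2, n_phas_intronic=1,
        n_phas_junction=1, n_phas_intergenic=1, n_phas_24nt=0,
        noise_reads=0, rrna_fraction=0.0, phasing_fidelity=1.0, seed=11,
    )
    return analyze(cfg)


@pytest.fixture
def small_sim_cfg() -> SimConfig:
    return SimConfig(
        genome_len=60_000, n_genes=6, n_phas_exonic=2, n_phas_intronic=1,
        n_phas_junction=1, n_phas_intergenic=2, n_phas_24nt=1,
        noise_reads=80, seed=7,
    )
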