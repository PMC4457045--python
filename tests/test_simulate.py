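import numpy as np
import pytest

from phasekit.io import RunConfig
from phasekit.phasing import PhasLocus, register_position
from phasekit.preprocess import assign_rpm, filter_rrna, map_reads
from phasekit.simulate import SimConfig, make_genome, make_library, score_recovery

from conftest import analyze


SMALL = dict(
    genome_len=60_000, n_genes=6, n_phas_exonic=2, n_phas_intronic=1,
    n_phas_junction=1, n_phas_intergenic=2, n_phas_24nt=1, noise_reads=80,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        a = make_library(SimConfig(**SMALL, seed=5))
        b = make_library(SimConfig(**SMALL, seed=5))
        assert a.genome[0].seq == b.genome[0].seq
        assert [(r.seq, r.count) for r in a.reads] == [(r.seq, r.count) for r in b.reads]
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in pa:
            assert open(pa[key]).read() == open(pb[key]).read()

    def test_different_seed_differs(self):
        a = make_library(SimConfig(**SMALL, seed=5))
        b = make_library(SimConfig(**SMALL, seed=6))
        assert a.genome[0].seq != b.genome[0].seq


class TestContracts:
    def test_genic_loci_require_genes(self):
        with pytest.raises(ValueError, match="n_genes"):
            make_genome(SimConfig(n_genes=0, n_phas_exonic=1))

    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="genome too small"):
            make_genome(SimConfig(genome_len=5_000, n_genes=24))

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            SimConfig(phasing_fidelity=1.5)

    def test_gene_structure_introns(self):
        build = make_genome(SimConfig(**SMALL, seed=1))
        for m in build.models:
            assert len(m.introns) == len(m.exons) - 1
            assert all(s < e for s, e in m.exons)

    def test_truth_table_lists_every_locus(self):
        sim = make_library(SimConfig(**SMALL, seed=2))
        assert len(sim.truth) == 7
        assert sim.truth_frame().shape[0] == 7
        by_class = {t.genomic_class for t in sim.truth}
        assert by_class == {"exon", "intron", "exon_intron", "intergenic"}

    def test_family_duplicate_shares_family(self):
        sim = make_library(SimConfig(**SMALL, seed=2))
        fams = {}
        for g, f in sim.family_map.items():
            fams.setdefault(f, []).append(g)
        assert len(fams["FAM1"]) == 2


class TestPlantedGeometry:
    def test_full_fidelity_reads_share_one_register(self):
        cfg = SimConfig(**{**SMALL, "n_phas_24nt": 0, "noise_reads": 0},
                        phasing_fidelity=1.0, rrna_fraction=0.0, seed=3)
        sim = make_library(cfg)
        cleaned = filter_rrna(sim.reads, sim.rrna_refs)
        assign_rpm(cleaned)
        alns = map_reads(cleaned, sim.genome, 6)
        for t in sim.truth:
            inside = [
                a for a in alns
                if sim.read_provenance.get(a.read.seq) == "phased"
                and t.start - 2 <= a.start < t.end
            ]
            assert inside, t.locus_id
            assert all(
                register_position(a) % t.register_len == t.phase_offset for a in inside
            )

    def test_antisense_partner_two_nt_upstream(self):
        # the +2 offset restores the sense register for the duplex partner
        cfg = SimConfig(**{**SMALL, "n_phas_24nt": 0, "noise_reads": 0},
                        phasing_fidelity=1.0, rrna_fraction=0.0, seed=3)
        sim = make_library(cfg)
        cleaned = filter_rrna(sim.reads, sim.rrna_refs)
        alns = map_reads(cleaned, sim.genome, 6)
        t = sim.truth[0]
        minus = [
            a for a in alns
            if a.strand == "-" and sim.read_provenance.get(a.read.seq) == "phased"
            and t.start - 2 <= a.start < t.end
        ]
        assert minus and all((a.start + 2 - t.start) % 21 == 0 for a in minus)


class TestRrnaContamination:
    def test_binomial_fraction_at_depth(self):
        cfg = SimConfig(**SMALL, rrna_fraction=0.1, library_depth=1_000_000, seed=9)
        sim = make_library(cfg)
        rrna_count = sum(
            r.count for r in sim.reads if sim.read_provenance[r.seq] == "rrna"
        )
        # binomial(1e6, 0.1): 3 sigma is ~900 reads
        sd = np.sqrt(1e6 * 0.1 * 0.9)
        assert abs(rrna_count - 1e5) <= 3 * sd

    def test_rrna_reads_are_removed_by_filter(self):
        sim = make_library(SimConfig(**SMALL, seed=2))
        cleaned = filter_rrna(sim.reads, sim.rrna_refs)
        assert all(sim.read_provenance[r.seq] != "rrna" for r in cleaned)


def _locus(start, end, reg=21):
    return PhasLocus(
        ref_id="chr1", start=start, end=end, register_len=reg, phase_offset=start % reg,
        best_pvalue=1e-6, best_phasing_score=20.0, window_count=1,
        locus_id=f"chr1:{start}-{end}",
    )


class TestScoreRecovery:
    def truth(self, n=30):
        sim = make_library(SimConfig(seed=1))
        return [t for t in sim.truth if t.register_len == 21][: n]

    def test_perfect_calls(self):
        truth = self.truth(5)
        called = [_locus(t.start - 20, t.end + 30) for t in truth]
        rep = score_recovery(called, truth)
        assert rep.sensitivity == 1.0 and rep.precision == 1.0

    def test_no_calls(self):
        truth = self.truth(5)
        rep = score_recovery([], truth)
        assert rep.sensitivity == 0.0 and rep.precision == 1.0

    def test_one_spurious_call(self):
        truth = self.truth(30)
        called = [_locus(t.start, t.end) for t in truth] + [_locus(199_000, 199_210)]
        rep = score_recovery(called, truth)
        assert rep.precision == pytest.approx(30 / 31)
        assert rep.false_positives == ["chr1:199000-199210"]


class TestFidelityMonotonicity:
    def test_mean_sensitivity_nondecreasing(self):
        cfg0 = {**SMALL, "n_phas_24nt": 0}
        means = []
        for fid in (0.2, 0.6, 1.0):
            vals = []
            for seed in (10, 11, 12, 13):
                ns = analyze(SimConfig(**cfg0, phasing_fidelity=fid, seed=seed))
                vals.append(
                    score_recovery(ns.loci21, ns.sim.truth, register_len=21).sensitivity
                )
            means.append(float(np.mean(vals)))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]  # and the effect is real, not flat
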