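# phasekit

Discovery of phased-siRNA (PHAS) loci from plant small-RNA sequencing
libraries: from collapsed reads to called 21-/24-nt loci, their genomic
classes, their miRNA/siRNA triggers, their predicted targets, and
differential phasiRNA production between libraries — plus a deterministic
synthetic-data generator with truth tables so the whole pipeline is testable
without any real dataset.

## Who it is for

Plant small-RNA researchers who want a transparent, scriptable
reimplementation of the classical phasing analysis (tasiRNA/phasiRNA
detection) with every threshold explicit and auditable, and methods
developers who need a desk-scale truth-set simulator to validate phasing
statistics.

## The method in brief

phasiRNAs are diced head-to-tail from a dsRNA precursor anchored at a
trigger cleavage site, so their 5' ends share one residue class modulo the
register length r (21 or 24). After exact read placement (0 mismatches,
≤ 6 genomic hits) and a +2 correction of minus-strand reads (the duplex 2-nt
3' overhang), a sliding window of m = 9 register cycles (189 nt, step 63 nt)
tallies each of the r candidate phase registers. An eligible window (≥ 10
unique reads, more than half register-length, ≥ 3 in the best phase) is
scored by the hypergeometric tail

    p(k) = Σ_{X=k}^{min(n,m)} C((r−1)m, n−X) C(m, X) / C(rm, n)

with n the unique register-length reads in the window and k the occupied
cycle slots of the dominant register; 21-nt windows are positive at
p < 0.001. 24-nt windows are instead called by the phasing score

    score = (occupied − 2) · ln(1 + 10·ΣP/(1 + ΣU)) ≥ 15.

Positive windows sharing a phase register merge into loci, which are then
classified against gene models (exon / intron / exon–intron junction /
intergenic), consolidated per gene, searched for 21/22-nt triggers (duplex
score ≤ 4 in the 200-nt flanks, cleavage in phase, one-hit-22 vs two-hit
model), and used for phasiRNA target prediction (score ≤ 3, stringent ≤ 1.5;
cis / same-family / trans). Two libraries are compared per locus by a plain
five-fold RPM rule with PHAS-status transitions (gained/lost) reported.
See `docs/methods.md` for the full model, parameter table and limitations.

## Worked example

Simulate a 60-kb dataset with seven planted loci, then run the full
pipeline:

```bash
cat > sim.yaml <<EOF
genome_len: 60000
n_genes: 6
n_phas_exonic: 2
n_phas_intronic: 1
n_phas_junction: 1
n_phas_intergenic: 2
n_phas_24nt: 1
noise_reads: 80
seed: 7
EOF

phasekit simulate --config sim.yaml --out sim
phasekit run --genome sim/genome.fa --reads sim/reads.fa \
    --gff sim/annotation.gff3 --rrna sim/rrna.fa \
    --degradome sim/degradome.fa --out run
```

which prints `7 PHAS loci; manifest: run/manifest.json`. The class summary
(`run/summary.tsv`) reproduces the planted composition — two exonic, one
intronic, one junction and two intergenic 21-nt loci, and one 24-nt locus:

```
register_len  exon  intron  exon_intron  genic  intergenic  total
21            2     1       1            4      2           6
24            0     0       0            0      1           1
```

`run/phas.loci.tsv` holds one row per locus with its extent, phase residue,
P-value and phasing score, e.g.

```
locus_id            start  end    register_len  phase_offset  pvalue    phasing_score
chr1:3087-3402/21   3087   3402   21            5             1.3e-10   70.07
```

— a locus whose in-phase reads sit at residue 5 (mod 21), far beyond the
p < 0.001 calling threshold. `run/triggers.tsv` shows its planted trigger
recovered at duplex score 0.0 on the 5' flank with an in-phase cleavage
site, classified `two_hit` and validated by the degradome library:

```
locus              srna                   length score end    phase_relation model   degradome
chr1:3087-3402/21  CGGTCGCATCGTCGGACTTCG  21     0.0   5prime in_phase       two_hit validated
```

`run/targets.tsv` lists each abundant phasiRNA's predicted targets with
their cis / same-family / trans relation, and `phasekit compare` produces
the per-locus fold-change verdicts between two runs.

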