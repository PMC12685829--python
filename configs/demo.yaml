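# Demonstration run: two drifted populations with planted sweeps and
# planted autozygous tracts on a small three-chromosome genome.
seed: 1
output_dir: scratch/demo
window_size: 100000
window_step: 10000
reference_pop: pop2
target_pop: pop1
tails: [0.01, 0.05]
island_tail: 0.01
simulate:
  n_pops: 2
  samples_per_pop: 20
  snp_spacing_mean: 1000
  divergence_F: 0.2
  chromosomes:
    - {name: chr1, length: 5000000}
    - {name: chr2, length: 5000000}
    - {name: chr3, length: 5000000}
  sweeps:
    - {pop: pop1, chrom: chr1, start: 1000000, end: 1400000, intensity: 0.9}
    - {pop: pop1, chrom: chr2, start: 3000000, end: 3500000, intensity: 1.0}
  roh:
    - {sample: pop1_s01, chrom: chr3, start: 500000, end: 1500000}
    - {sample: pop1_s01, chrom: chr3, start: 2500000, end: 3000000}
    - {sample: pop2_s05, chrom: chr1, start: 2500000, end: 3200000}
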