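# Three-deme serial-founder chain: simulate, filter, spectra, statistics, IBD.
seed: 11
output_dir: chain_out
input:
  scenario:
    preset: serial_founder
    n_demes: 3
    founder_fraction: 0.1
    interval: 0.25
    samples_per_deme: 10
    n_loci: 3000
    theta: 1.0
    missing_rate: 0.05
filters:
  call_rate: 0.75
  maf: 0.05
  thin_bp: 10000
sfs:
  pops: [A, B]
  projection: [10, 10]
stats:
  n_perm: 1000
ibd:
  distance: edwards
  n_perm: 999
fit:
  enabled: false
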