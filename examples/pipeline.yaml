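# Self-contained synthetic pipeline config: no input files needed.
# Run with:  coilspect pipeline examples/pipeline.yaml --out-dir out/
seed: 1
synthetic:
  r0: 5.8            # superhelical radius, Angstrom
  pitch: 153.0       # superhelical pitch, Angstrom
  n_res: 168
  orientations: [U, D, U, D]
  noise_sd: 0.0
synthetic_crosslinks:
  n_links: 50
  decoy_fraction: 0.25
cutoffs:
  xlms: 30.0
  salt_bridge: 4.0
  kih: 7.0
melt:
  tm: 63.0
  width: 2.0
  noise_frac: 0.02
cd:
  ratios: [0.8, 0.95]
assembly:
  F1: 1.0
  F2: 1.2
  F3: 1.0
  F4: 1.2
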