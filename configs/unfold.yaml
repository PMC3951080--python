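# Bragg-basis build + NNLS spectrum unfold round trip
# (reduced basis: 20-80 MeV in 5 MeV steps, 1 mm voxels).
kind: unfold
histories_per_energy: 10000
seed: 1
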