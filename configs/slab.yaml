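# Minimal smoke scenario: monoenergetic parallel protons on a water slab.
kind: slab
material: water
size: 10.0
voxel: 0.2
energy: 50.0
histories: 5000
seed: 1
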