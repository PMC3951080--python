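# SPE proton irradiation of the digital minipig (54 cm crown-rump) in its
# PMMA enclosure, 70% opposed-lateral / 30% opposed-AP angle weighting,
# DVHs for skin / lungs / BFO / eyes.
kind: animal
crown_rump: 54.0
voxel: 0.4
histories: 20000
batches: 2
seed: 1
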