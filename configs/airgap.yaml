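# Air-gap sensitivity study: 6 MeV electrons, 5 mm PMMA wall,
# gaps 0-100 mm in front of the 20 cm solid-water phantom.
kind: airgap
histories: 200000
seed: 1
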