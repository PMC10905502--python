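# Title terms indicating non-human study subjects.
mice
mouse
murine
rat
rats
macaque
macaques
rhesus
bovine
porcine
ovine
equine
canine
zebrafish
drosophila
rabbit
rabbits
hamster
hamsters
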