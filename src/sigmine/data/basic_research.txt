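# Keywords marking laboratory (basic) research when no clinical
# publication type is present.
gene expression
mrna
transcriptome
proteomic
proteomics
western blot
immunohistochemistry
cell culture
cultured cells
granulosa cells
cumulus cells
signaling pathway
signalling pathway
knockdown
knockout
in vitro maturation
dna methylation
epigenetic
oxidative stress
mitochondrial
receptor expression
protein expression
polymerase chain reaction
rt-pcr
flow cytometry
apoptosis assay
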