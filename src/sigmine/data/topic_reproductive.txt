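# Reproductive-medicine topic keywords (title + abstract).
# Approximation of a fertility-subject search strategy; edit to taste.
infertility
fertility
in vitro fertilization
in vitro fertilisation
ivf
icsi
intracytoplasmic sperm injection
embryo transfer
embryo
blastocyst
oocyte
ovarian stimulation
ovulation induction
ovarian reserve
endometriosis
polycystic ovary
pcos
sperm
semen
assisted reproduction
assisted reproductive
intrauterine insemination
live birth
implantation
miscarriage
pregnancy rate
gamete
fertilization
fertilisation
luteal phase
gonadotropin
clomiphene
letrozole
frozen embryo
preimplantation
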