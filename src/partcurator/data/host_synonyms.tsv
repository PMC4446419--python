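# synonym	canonical
e. coli	Escherichia coli
e.coli	Escherichia coli
ecoli	Escherichia coli
escherichia coli	Escherichia coli
mammalian	Mammalian Cells
mammalian cells	Mammalian Cells
mammalian cell	Mammalian Cells
b. subtilis	Bacillus subtilis
b.subtilis	Bacillus subtilis
bacillus subtilis	Bacillus subtilis
gram-negative	Gram-negative bacteria
gram negative	Gram-negative bacteria
gram-negative bacteria	Gram-negative bacteria
gram negative bacteria	Gram-negative bacteria
drosophila	Drosophila melanogaster
d. melanogaster	Drosophila melanogaster
drosophila melanogaster	Drosophila melanogaster
yeast	Saccharomyces cerevisiae
s. cerevisiae	Saccharomyces cerevisiae
s.cerevisiae	Saccharomyces cerevisiae
saccharomyces cerevisiae	Saccharomyces cerevisiae
insect	Insect Cells
insect cells	Insect Cells
insect cell	Insect Cells
sf9	Insect Cells
plant	Plant Cells
plant cells	Plant Cells
plant cell	Plant Cells
s. pombe	Schizosaccharomyces pombe
s.pombe	Schizosaccharomyces pombe
schizosaccharomyces pombe	Schizosaccharomyces pombe
fission yeast	Schizosaccharomyces pombe
p. pastoris	Pichia pastoris
p.pastoris	Pichia pastoris
pichia pastoris	Pichia pastoris
a. nidulans	Aspergillus nidulans
a.nidulans	Aspergillus nidulans
aspergillus nidulans	Aspergillus nidulans
k. lactis	Kluyveromyces lactis
k.lactis	Kluyveromyces lactis
kluyveromyces lactis	Kluyveromyces lactis
unspecified	Unspecified
unknown	Unspecified
n/a	Unspecified
none	Unspecified
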