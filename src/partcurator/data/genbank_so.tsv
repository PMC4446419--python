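# genbank_key	so_term	so_name
CDS	SO:0000316	CDS
promoter	SO:0000167	promoter
terminator	SO:0000141	terminator
rep_origin	SO:0000296	origin_of_replication
misc_feature	SO:0000110	sequence_feature
primer_bind	SO:0005850	primer_binding_site
RBS	SO:0000139	ribosome_entry_site
enhancer	SO:0000165	enhancer
polyA_signal	SO:0000551	polyA_signal_sequence
polyA_site	SO:0000553	polyA_site
LTR	SO:0000286	long_terminal_repeat
misc_recomb	SO:0000298	recombination_feature
protein_bind	SO:0000410	protein_binding_site
misc_binding	SO:0000409	binding_site
oriT	SO:0000724	oriT
sig_peptide	SO:0000418	signal_peptide
misc_signal	SO:0005836	regulatory_region
regulatory	SO:0005836	regulatory_region
intron	SO:0000188	intron
exon	SO:0000147	exon
5'UTR	SO:0000204	five_prime_UTR
3'UTR	SO:0000205	three_prime_UTR
mRNA	SO:0000234	mRNA
misc_RNA	SO:0000673	transcript
ncRNA	SO:0000655	ncRNA
tRNA	SO:0000253	tRNA
rRNA	SO:0000252	rRNA
repeat_region	SO:0000657	repeat_region
stem_loop	SO:0000313	stem_loop
mobile_element	SO:0001037	mobile_genetic_element
# START codon SO accession: SO:0000318 (a commonly seen typo adds a zero; the
# shipped table uses the valid accession).
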