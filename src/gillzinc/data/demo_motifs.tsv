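# Demonstration binding-site consensi, SYNTHETIC fixtures for examples and
# simulations only.  Curated binding-site collections (e.g. Transfac) are
# proprietary and are not shipped; supply your own motif file in production.
# Format: name<TAB>IUPAC consensus.
MRE_fixture	TGCRCNC
Foxl1_fixture	RYMAAYA
Hnf4a_fixture	GGNCAAAGKTCA
Specific_fixture	TGCACGTCAT
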