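# Convenience tract map over the six canonical core regions.
#
# This is a schematic, hand-written adjacency reflecting textbook
# projection/association fiber anatomy (thalamo-cortical radiations,
# cerebello-thalamic peduncles, cortico-striatal and fronto-motor
# association fibers).  It is a convenience fixture for demonstrations,
# NOT tractography-derived ground truth; supply your own map for real
# analyses.
tracts:
  - [Tha, BG]
  - [Tha, Cere]
  - [Tha, PFC]
  - [Tha, VC]
  - [BG, SMA]
  - [PFC, SMA]
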