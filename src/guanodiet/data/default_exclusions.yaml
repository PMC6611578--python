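# Default non-target taxa removed by the exclusion stage.
# Categories are fixed; taxon lists are editable. Matching is
# case-insensitive against any rank of a MOTU's taxonomic path.
non_animal:
  - Bacteria
  - Enterobacteriaceae
  - Algae
  - Fungi
  - Rotifera
guano_fauna:
  - Acari
  - Machilidae
  - Anobiidae
  - Dermestidae
secondary_prey:
  - Gastropoda
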