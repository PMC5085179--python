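# Role map template for externally deposited SBML models.
#
# Species naming in deposited files cannot be assumed, so the mapping of the
# named roles used throughout the package to the file's species ids must be
# supplied by the user (pass the edited file via --role-map, or as
# key_species_map in a RunConfig).  The species mapped to tnf_input is
# clamped as the sustained stimulus.
#
# Replace the right-hand sides with the ids found in your model file
# (e.g. via `grep '<species' model.xml`).

tnf_input: TNF
complex1: ComplexI
complex2: ComplexII
nfkb_active: NFkB_active
caspase8_active: Caspase8_active
caspase3_active: Caspase3_active
caspase6_active: Caspase6_active
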