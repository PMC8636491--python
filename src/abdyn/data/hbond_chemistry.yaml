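# Hydrogen-bond chemistry rules (editable).
# Donors are N/O heavy atoms carrying a covalently bound hydrogen; acceptors
# are N/O heavy atoms.  The D-H covalent bond is resolved geometrically in
# the first frame with the distance below (nm).
donor_elements: [N, O]
acceptor_elements: [N, O]
dh_bond_max: 0.125
# Atoms never acting as acceptors (backbone amide N accepts poorly).
acceptor_exclude_names: []
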