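group,fluid,treatment,n_animals,cells_brain1,cells_brain2,cells_brain3,cells_brain4,cells_brain5,total_cells_printed
H2O_VEH,H2O,VEH,4,9,5,6,9,,29
H2O_CNO,H2O,CNO,5,5,7,5,6,13,36
EtOH_VEH,EtOH,VEH,4,6,10,5,8,,29
EtOH_CNO,EtOH,CNO,4,6,5,6,6,,23
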