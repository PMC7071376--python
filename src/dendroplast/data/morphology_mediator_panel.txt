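# Curated panel of genes with literature support for mediating neuronal
# structure and dendritic plasticity (neurotrophin signaling, Wiskott-
# Aldrich actin regulators, postsynaptic scaffolds, NMDA receptor
# subunits, CaMK/PAK kinases, CREB-driven microRNA); see Russo et al. 2010,
# Arikkath 2012 and Uys et al. 2016 for the supporting literature.
# The published structural-mediator panel comprises 57 genes; the 11 core
# members named in the accompanying analyses are listed below.  Additional
# members can be appended, one gene symbol per line.
Ntrk2
Wasf2
Dlg4
Grin2b
Grin2a
Was
Actl6a
Mir132
Mef2d
Camk2g
Pak1
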