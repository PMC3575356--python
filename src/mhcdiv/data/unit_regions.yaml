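# Conservation/management unit -> region grouping for regional averages.
# The small Kii-Hanto (KH) and Shikoku (SK) units are grouped with the
# western population.
eastern: [CS, GAI, SO, EM, SA, NCA, HO]
western: [NK, EC, WC, KH, SK]
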