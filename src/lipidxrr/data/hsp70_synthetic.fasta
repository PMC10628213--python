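>HSP70_SYNTHETIC synthetic 641-aa Hsp70-like sequence (NOT the real HSPA1A sequence); amino-acid composition chosen to emulate human Hsp70: ~70 kDa, residue volume ~84,300 A^3, electron density ~0.445 e-/A^3
MDETLVRATVGLKFAVNVDEDEFEYDPDEKGELVVNDQTLGEVVAKIDYIKLNKIHSIDA
ISALGSAIIPESKSGEVFAFVQGARNTRNFLDEATNEKLSREDGSQCKSKSYVRLGPRLR
QKLNGNPGVRIEISAYGYPSNMHATDFALQSMTVKNVYASNFWGMNVFEQSSEESNDNPN
ACIIVAKEDSVKLLALAALLLIEERKTAPKKDARLTILTSIVARDMVILTIQTNYGEQTK
LGNEQDASQKNMQAEEIDVTRADQGIDAFMVPLLTKESGITFLTKRQSKYRGDSMFRTVG
SGESPLRGKESFSETALEAKNDLTVKQHTVKVSAPPPGTKIYLCFQDNVLDVAKVPGGLE
DHATKAIVCHEMYGHIHKNKIRLLETPGMATGGAILQPTLAFAEVGFFMFAWKALDEPGQ
GDNKDGDEEGLIINGAEQGQKTVADQLASVEAGAVGITDLDTAICTNEGGPEKVHTYAGG
QKKHPNAMDTEVRRPTFDKPATGRSITQKLQKHRELADDRGVESSFTESVDFSQRKYKPS
GNRVEVELNSRREDKELLTDKFVRGATNKGRVLTIDVYAGADLRGLIGKDQLKIGQAEFK
LLIKKTDFPFDEQVGGDADVKPSGKGLKVAAEAQSVKNLYP
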