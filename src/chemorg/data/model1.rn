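# Full spindle-assembly-checkpoint network (Model 1): 14 species, 21 reactions.
#
# Transcription of the complete SAC reaction scheme: Mad2 template activation
# at unattached kinetochores, mitotic-checkpoint-complex (MCC) assembly,
# APC/C activation by Cdc20 and its inhibition by the MCC, BubR1-mediated
# extraction of Cdc20, and checkpoint silencing at attached kinetochores
# (Mad2 release from APC/C-bound MCC).  The complex written Cdc20:C-Mad2 is
# also known as Cdc20:Mad2 / C-Mad2:Cdc20.  Validated against the published
# organization counts: 16 organizations; 64 for the short-timescale variant
# without kinetochore attachment and O-Mad2 decay.
species: KinU KinA O-Mad2 C-Mad2 Cdc20 BubR1:Bub3 MCC Cdc20:C-Mad2 Cdc20:BubR1:Bub3 APC/C APC/C:Cdc20 APC/C:MCC APC/C:Cdc20:C-Mad2 APC/C:Cdc20:BubR1:Bub3

# kinetochore attachment (the long-timescale reaction)
KinU -> KinA ; 0.02 ; attachment

# Mad2 template cycle at unattached kinetochores
KinU + O-Mad2 -> KinU + C-Mad2 ; 0.2 ; mad2_activation
C-Mad2 -> O-Mad2 ; 0.1 ; mad2_relaxation
O-Mad2 -> ; 0.01 ; omad2_decay

# MCC assembly from closed Mad2, Cdc20 and BubR1:Bub3
C-Mad2 + Cdc20 -> Cdc20:C-Mad2 ; 1.0 ; cc_bind
Cdc20:C-Mad2 -> C-Mad2 + Cdc20 ; 0.1 ; cc_release
Cdc20:C-Mad2 -> O-Mad2 + Cdc20 ; 0.05 ; cc_release_open
Cdc20:C-Mad2 + BubR1:Bub3 -> MCC ; 1.0 ; mcc_assembly
MCC -> Cdc20:C-Mad2 + BubR1:Bub3 ; 0.1 ; mcc_disassembly

# APC/C activation and deactivation
APC/C + Cdc20 -> APC/C:Cdc20 ; 1.0 ; apc_activation
APC/C:Cdc20 -> APC/C + Cdc20 ; 0.1 ; apc_deactivation

# APC/C inhibition by the MCC
APC/C + MCC -> APC/C:MCC ; 1.0 ; amcc_bind
APC/C:MCC -> APC/C + MCC ; 0.1 ; amcc_release
Cdc20 + APC/C:MCC -> APC/C:Cdc20 + MCC ; 0.2 ; apc_exchange

# closed Mad2 capturing the Cdc20 on active APC/C
APC/C:Cdc20 + C-Mad2 -> APC/C:Cdc20:C-Mad2 ; 1.0 ; acc_bind
APC/C:Cdc20:C-Mad2 -> APC/C:Cdc20 + C-Mad2 ; 0.1 ; acc_release
APC/C:Cdc20:C-Mad2 -> APC/C:Cdc20 + O-Mad2 ; 0.05 ; acc_release_open

# BubR1:Bub3 extracting Cdc20 from the active APC/C
APC/C:Cdc20 + BubR1:Bub3 -> APC/C + Cdc20:BubR1:Bub3 ; 0.5 ; cdc20_extraction
Cdc20:BubR1:Bub3 -> Cdc20 + BubR1:Bub3 ; 0.1 ; cb_release

# checkpoint silencing at attached kinetochores: Mad2 leaves APC/C-bound MCC
KinA + APC/C:MCC -> KinA + APC/C:Cdc20:BubR1:Bub3 + O-Mad2 ; 0.2 ; kina_silencing
APC/C:Cdc20:BubR1:Bub3 -> APC/C:Cdc20 + BubR1:Bub3 ; 0.1 ; acbb_dissociation
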