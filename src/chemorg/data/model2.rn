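# Reduced spindle-assembly-checkpoint network (Model 2).
# Seven lumped species: kinetochores (KinU/KinA), Activator (free Cdc20),
# Promotor (APC/C), Promotor_A (active APC/C:Cdc20), Inhibitor (the Mad2 /
# BubR1:Bub3 / MCC pool) and Promotor_I (APC/C bound by inhibitor complexes).
# Transcribed from the lumping of the full model; validated against the
# published organization counts (8 organizations; 16 without attachment).
species: KinU KinA Activator Promotor Promotor_A Inhibitor Promotor_I
KinU -> KinA ; 0.01 ; attachment
Activator + KinU -> KinU + Inhibitor ; 1.0 ; inhibition
Inhibitor -> Activator ; 0.1 ; relaxation
Activator + Promotor -> Promotor_A ; 1.0 ; activation
Promotor_A -> Activator + Promotor ; 0.1 ; deactivation
Inhibitor + Promotor -> Promotor_I ; 1.0 ; sequestration
Promotor_I -> Inhibitor + Promotor ; 0.1 ; release
Inhibitor + Promotor_A -> Promotor_I + Activator ; 1.0 ; capture
Activator + Promotor_I -> Promotor_A + Inhibitor ; 0.1 ; exchange
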