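# Coarsest spindle-assembly-checkpoint network (Model 3).
# Four species: unattached/attached kinetochore (KinU/KinA), checkpoint
# Activator and Inhibitor.  Rate constants are per-time-unit defaults chosen
# to display the switching behaviour (structural analyses are rate-free).
species: KinU KinA Activator Inhibitor
KinU -> KinA ; 0.01 ; attachment
Activator + KinU -> KinU + Inhibitor ; 1.0 ; inhibition
Inhibitor -> Activator ; 0.1 ; relaxation
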