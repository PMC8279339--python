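# Link-segment inertial parameters (Dempster mass fractions; geometric
# CoM / radius-of-gyration fractions).  Fractions of body mass / segment
# length; com measured from the proximal end; gyration about the CoM
# transverse (medio-lateral) axis.
segment,mass_fraction,com_fraction,gyration_fraction
foot,0.0145,0.50,0.475
shank,0.0465,0.433,0.302
thigh,0.100,0.433,0.323
pelvis,0.142,0.50,0.31
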