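# Coda pelvis hip-joint-centre regression: offsets of each hip centre from
# the mid-ASIS point as fractions of the inter-ASIS distance, in the pelvis
# frame (lateral toward the side of the hip, posterior, inferior).
offset,fraction
lateral,0.36
posterior,0.19
inferior,0.30
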