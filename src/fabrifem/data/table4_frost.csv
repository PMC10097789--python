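threshold,strain_lo_ustrain,strain_hi_ustrain,stress_lo_MPa,stress_hi_MPa,sed_lo_MPa,sed_hi_MPa
MESr,50,100,1,2,2.8e-5,11.25e-5
MESm,1000,1500,20,,0.01125,0.02531
MESp,3000,,60,,0.10125,
Fx,25000,,120,,1.5,
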