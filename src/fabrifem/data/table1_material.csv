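E0_MPa,nu0,G0_MPa,k,l
22500.0,0.3,8650.0,1.9,0.99
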