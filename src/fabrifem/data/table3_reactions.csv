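config,nx,ny,nz,magnitude_N
1,-0.153,-0.942,0.298,1383.005
2,-0.288,-0.789,0.541,773.691
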