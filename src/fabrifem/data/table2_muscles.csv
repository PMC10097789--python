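muscle,config,nx,ny,nz,magnitude_N
Glut_max1,1,-0.481,0.851,-0.208,21.547
Glut_max2,1,0.473,0.852,0.221,4.851
Glut_max3,1,-0.454,0.719,-0.525,3.017
Glut_med1,1,0.398,0.885,-0.238,240.442
Glut_med2,1,0.050,0.858,-0.510,135.955
Glut_med3,1,-0.205,0.701,-0.682,119.839
Glut_min1,1,0.333,0.802,-0.495,36.459
Glut_min2,1,0.173,0.810,-0.559,39.606
Glut_min3,1,-0.011,0.746,-0.664,37.537
Iliacus,1,0.892,0.331,-0.305,114.663
Pect,1,0.346,0.719,-0.601,2.423
Perif,1,-0.424,0.466,-0.776,24.329
Psoas,1,0.877,0.387,-0.283,130.575
Quadfem,1,0.002,-0.182,-0.983,3.729
Gem,1,-0.401,-0.231,-0.886,1.778
Glut_max1,2,-0.082,0.145,0.986,3.450
Glut_max2,2,0.473,0.852,0.221,5.516
Glut_max3,2,-0.454,0.719,-0.525,4.722
Glut_med1,2,0.336,0.928,-0.155,7.113
Glut_med2,2,-0.049,0.899,-0.433,6.153
Glut_med3,2,-0.309,0.705,-0.637,163.206
Glut_min1,2,0.277,0.851,-0.445,2.540
Glut_min2,2,0.106,0.851,-0.512,2.767
Glut_min3,2,-0.093,0.774,-0.626,10.013
Iliacus,2,0.892,0.331,-0.305,228.926
Pect,2,0.323,0.747,-0.580,10.798
Perif,2,-0.504,0.431,-0.748,38.924
Psoas,2,0.877,0.387,-0.283,261.665
Quadfem,2,0.076,-0.181,-0.980,111.287
Gem,2,-0.360,-0.282,-0.888,15.389
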