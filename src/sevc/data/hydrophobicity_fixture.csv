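scale_id,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
KD,1.8,-4.5,-3.5,-3.5,2.5,-3.5,-3.5,-0.4,-3.2,4.5,3.8,-3.9,1.9,2.8,-1.6,-0.8,-0.7,-0.9,-1.3,4.2
HW,-0.5,3.0,0.2,3.0,-1.0,0.2,3.0,0.0,-0.5,-1.8,-1.8,3.0,-1.3,-2.5,0.0,0.3,-0.4,-3.4,-2.3,-1.5
EISEN,0.62,-2.53,-0.78,-0.90,0.29,-0.85,-0.74,0.48,-0.40,1.38,1.06,-1.50,0.64,1.19,0.12,-0.18,-0.05,0.81,0.26,1.08
FP,0.31,-1.01,-0.60,-0.77,1.54,-0.22,-0.64,0.00,0.13,1.80,1.70,-0.99,1.23,1.79,0.72,-0.04,0.26,2.25,0.96,1.22
GES,1.6,-12.3,-4.8,-9.2,2.0,-4.1,-8.2,1.0,-3.0,3.1,2.8,-8.8,3.4,3.7,-0.2,0.6,1.2,1.9,-0.7,2.6
JANIN,0.3,-1.4,-0.5,-0.6,0.9,-0.7,-0.7,0.3,-0.1,0.7,0.5,-1.8,0.4,0.5,-0.3,-0.1,-0.2,0.3,-0.4,0.6
ROSE,0.74,0.64,0.63,0.62,0.91,0.62,0.62,0.72,0.78,0.88,0.85,0.52,0.85,0.88,0.64,0.66,0.70,0.85,0.76,0.86
WWIF,0.17,0.81,0.42,1.23,-0.24,0.58,2.02,0.01,0.96,-0.31,-0.56,0.99,-0.23,-1.13,0.45,0.13,0.14,-1.85,-0.94,0.07
HESSA,0.11,2.58,2.05,3.49,-0.13,2.36,2.68,0.74,2.06,-0.60,-0.55,2.71,-0.10,-0.32,2.23,0.84,0.52,0.30,0.68,-0.31
MONERA,41,-14,-28,-55,49,-10,-31,0,8,99,97,-23,74,100,-46,-5,13,97,63,76
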