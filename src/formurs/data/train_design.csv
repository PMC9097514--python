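# 17-run face-centered central composite training set for propranolol-loaded
# chitosan/TPP nanogels: CC = chitosan concentration (% w/v), CT = chitosan/TPP
# mass ratio, CP = chitosan/propranolol mass ratio. Measured responses: size (nm),
# ZP (mV), PDI (dimensionless), EE (percent as assayed; loaders convert to fraction).
run_id,CC,CT,CP,size,ZP,PDI,EE
1,0.2,3,0.375,135.3,23.45,0.243,23.3
2,0.2,5,0.25,135.6,29.53,0.367,40.6
3,0.2,5,0.375,132.3,28.01,0.378,11.7
4,0.2,5,0.375,138.6,29.95,0.352,18.6
5,0.1,5,0.375,65.6,24.57,0.288,30.7
6,0.1,3,0.5,69.8,25.73,0.233,35.1
7,0.3,5,0.375,208.1,26.49,0.481,18.7
8,0.2,5,0.375,135.2,30.59,0.327,16.5
9,0.2,5,0.5,146.4,29.62,0.323,20.9
10,0.1,7,0.25,59.4,18.67,0.342,19.7
11,0.3,3,0.25,194.4,24.38,0.343,21.7
12,0.3,7,0.25,198.6,31.58,0.498,14.5
13,0.3,7,0.5,206.2,31.02,0.507,16.4
14,0.2,7,0.375,132.0,32.23,0.461,18.0
15,0.1,3,0.25,65.0,18.11,0.217,26.7
16,0.3,3,0.5,190.8,24.69,0.345,19.6
17,0.1,7,0.5,56.8,25.25,0.313,25.8
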