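# 13-run independent test set (randomly generated settings inside the design
# cube) with measured responses, used to gauge out-of-sample predictivity (Q2).
# Columns as in train_design.csv; EE in percent.
run_id,CC,CT,CP,size,ZP,PDI,EE
1,0.15,4,0.25,114.4,27.4,0.268,14.9
2,0.25,4,0.375,138.1,25.4,0.283,15.4
3,0.25,6,0.25,131.1,25.1,0.318,9.5
4,0.1,4,0.5,98.9,29.5,0.156,19.6
5,0.15,3,0.375,118.1,26.0,0.245,15.4
6,0.3,6,0.5,179.8,29.4,0.422,8.5
7,0.15,3,0.25,119.3,26.3,0.253,31.4
8,0.2,4,0.5,113.0,23.1,0.268,9.7
9,0.2,6,0.375,107.6,24.0,0.289,25.2
10,0.1,6,0.5,60.7,24.8,0.146,18.5
11,0.15,7,0.375,115.8,26.1,0.355,13.8
12,0.25,3,0.25,133.8,25.0,0.263,18.3
13,0.3,4,0.5,194.4,28.4,0.397,18.8
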