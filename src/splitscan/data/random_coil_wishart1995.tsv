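aa	CA	CB	N	HN
A	52.5	19.1	123.8	8.24
R	56.0	30.9	120.5	8.23
N	53.1	38.9	118.7	8.40
D	54.2	41.1	120.4	8.34
C	58.2	28.0	118.8	8.32
Q	55.7	29.4	119.8	8.32
E	56.6	29.9	120.2	8.42
G	45.1	NA	108.8	8.33
H	55.0	29.0	118.2	8.42
I	61.1	38.8	119.9	8.00
L	55.1	42.4	121.8	8.16
K	56.2	33.1	120.4	8.29
M	55.4	32.9	119.6	8.28
F	58.0	39.0	120.3	8.30
P	63.3	31.7	136.5	NA
S	58.3	63.8	115.7	8.31
T	61.8	69.8	113.6	8.15
W	57.5	29.6	121.3	8.25
Y	58.1	38.8	120.3	8.12
V	62.2	32.9	119.2	8.03
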