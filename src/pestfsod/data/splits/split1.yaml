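# Published PestDet20 few-shot class split 1 (15 base / 5 novel).
all: [15, 76, 24, 39, 14, 67, 16, 95, 25, 3, 66, 0, 101, 99, 37, 70, 26, 50, 48, 21]
base: [15, 76, 24, 39, 14, 67, 16, 95, 25, 3, 66, 0, 101, 99, 37]
novel: [70, 26, 50, 48, 21]
seed: null
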