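# Published PestDet20 few-shot class split 3 (15 base / 5 novel).
all: [0, 48, 14, 99, 3, 21, 39, 66, 16, 37, 50, 26, 25, 70, 24, 67, 101, 76, 15, 95]
base: [0, 48, 14, 99, 3, 21, 39, 66, 16, 37, 50, 26, 25, 70, 24]
novel: [67, 101, 76, 15, 95]
seed: null
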