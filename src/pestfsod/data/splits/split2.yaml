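# Published PestDet20 few-shot class split 2 (15 base / 5 novel).
all: [101, 14, 48, 15, 3, 67, 39, 66, 76, 50, 95, 26, 37, 24, 0, 16, 21, 99, 70, 25]
base: [101, 14, 48, 15, 3, 67, 39, 66, 76, 50, 95, 26, 37, 24, 0]
novel: [16, 21, 99, 70, 25]
seed: null
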