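[[0.3, 0.6], [0.2, 0.8], [0.25, 0.5], [0.1, 0.9]]
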