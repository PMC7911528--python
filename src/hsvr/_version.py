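PACKAGE_VERSION = "0.1.0"
FORMAT_VERSION = 1
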