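class UniparentalError(Exception):
    """User-facing error: bad input data, bad configuration, impossible request."""
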