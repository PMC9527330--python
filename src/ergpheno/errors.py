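class ValidationError(ValueError):
    """Raised when an input table, trace, or configuration violates its schema."""
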