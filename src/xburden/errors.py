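"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration value violates its documented range or invariant."""


class SchemaError(ValueError):
    """An input file violates the expected schema (names the file/field)."""


class StructuralError(ValueError):
    """Cross-file references do not reconcile (orphan records, key mismatch)."""
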