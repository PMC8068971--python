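"""Exception types raised across the package."""


class PosmnaError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(PosmnaError):
    """A SMILES string or SDF record could not be parsed.

    Carries the offending record id (or line number) so batch readers can
    point at the failing input.
    """

    def __init__(self, message: str, record_id: str | None = None):
        self.record_id = record_id
        if record_id is not None:
            message = f"record {record_id!r}: {message}"
        super().__init__(message)


class MultiComponentError(PosmnaError):
    """A molecule has more than one connected component (e.g. a salt)."""

    def __init__(self, record_id: str | None, component_sizes: list[int]):
        self.record_id = record_id
        self.component_sizes = component_sizes
        who = f"record {record_id!r}" if record_id is not None else "input"
        super().__init__(
            f"{who} has {len(component_sizes)} components "
            f"(heavy-atom sizes {component_sizes}); pass strip_salts=True to "
            "keep the largest component"
        )


class DescriptorError(PosmnaError):
    """Descriptor generation failed (e.g. empty molecule or empty set)."""


class ModelError(PosmnaError):
    """Model fitting or prediction contract violation."""


class DataFormatError(PosmnaError):
    """A file did not conform to the expected on-disk format."""
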