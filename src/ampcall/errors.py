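"""Exception hierarchy.

Every fatal condition raised by the package derives from :class:`AmpcallError`
so the command-line wrapper can turn any of them into a single-line diagnostic
and a non-zero exit status.
"""


class AmpcallError(Exception):
    """Base class for all fatal ampcall errors."""


class PanelError(AmpcallError):
    """Malformed or inconsistent primer panel metadata (coords/sequences/reference)."""


class FastqError(AmpcallError):
    """Malformed FASTQ input or mismatched read-pair files."""


class ConfigError(AmpcallError):
    """Invalid run configuration (thresholds, prefix length, geometry...)."""
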