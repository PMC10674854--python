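"""Exception types shared across the package."""


class FingertapError(Exception):
    """Base class for all package errors."""


class ValidationError(FingertapError):
    """Structured input (keypoint file, config, feature table) is malformed."""


class UnusableRecordingError(FingertapError):
    """A recording cannot be analysed (no peaks, all-degenerate palm,
    pose dropout longer than the allowed gap). Mirrors the manual
    quality-exclusion step applied to clinical videos."""
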