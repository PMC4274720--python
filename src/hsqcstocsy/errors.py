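"""Exception hierarchy.

Every failure mode of the pipeline raises a named subclass of
:class:`HsqcStocsyError` so callers (and the CLI) can report the failing
stage precisely instead of catching bare ``ValueError``.
"""


class HsqcStocsyError(Exception):
    """Base class for all package errors."""


class MissingBrukerFileError(HsqcStocsyError, FileNotFoundError):
    """A required Bruker processed-data file (2rr, procs, proc2s) is absent."""


class MissingParameterError(HsqcStocsyError, KeyError):
    """A required key is missing from a procs/proc2s parameter file."""


class CorruptDataError(HsqcStocsyError):
    """Stored data is inconsistent with its own metadata (e.g. 2rr length vs SI)."""


class GridMismatchError(HsqcStocsyError):
    """Spectra expected to share one grid have differing ppm axes."""


class NoSignalError(HsqcStocsyError):
    """A noise threshold removed every column of the data matrix."""


class ZeroVarianceError(HsqcStocsyError):
    """The selected peak column has no variance across samples."""


class AllNoiseError(HsqcStocsyError):
    """No noise-surviving grid point exists inside the requested window."""


class ConfigError(HsqcStocsyError):
    """A run configuration failed validation."""
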