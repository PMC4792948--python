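"""Exception hierarchy.

``ConfigError`` covers invalid user-supplied configuration (bad site
definitions, indistinguishable anchors, out-of-range boundaries);
``DataError`` covers inputs that are structurally valid but unusable
(no reads retained, zero counts, zero denominators).  The CLI maps the
two classes to distinct exit codes.
"""


class XovermapError(Exception):
    """Base class for package errors."""


class ConfigError(XovermapError):
    """Invalid configuration; carries a list of problem descriptions."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class DataError(XovermapError):
    """Input data cannot support the requested computation."""


class CoordinateError(XovermapError, ValueError):
    """A position or boundary falls outside the valid range."""
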