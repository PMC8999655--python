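"""Exception hierarchy for the yBRCA1 pipeline.

Validation-type errors (bad input files, bad configuration) map to CLI
exit code 2; computation-type errors (degenerate statistics) to exit
code 3.
"""


class YBRCA1Error(Exception):
    """Base class for all pipeline errors."""


class PanelFormatError(YBRCA1Error):
    """Input table is structurally malformed (e.g. a required column is missing)."""


class PanelValidationError(YBRCA1Error):
    """Input table parsed but violates panel invariants (unknown token, duplicate row)."""


class ConsistencyError(YBRCA1Error):
    """Objects passed together do not describe the same variants/assays."""


class ConfigError(YBRCA1Error):
    """Invalid configuration value (non-positive fold, B < 100, ...)."""


class ComputationError(YBRCA1Error):
    """A statistic is undefined on the given input."""


class DegenerateControlError(ComputationError):
    """Control median is zero; fold-of-control normalization undefined."""


class UndefinedMetricError(ComputationError):
    """Classifier metric undefined (e.g. ROC on single-class input)."""


class FewReplicatesWarning(UserWarning):
    """Fewer replicates than the recommended minimum of five."""
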